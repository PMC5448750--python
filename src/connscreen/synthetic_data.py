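"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical shape of a developing-brain in situ
survey: a ~2000-gene × 7-age matrix of nonnegative expression densities in
[0, 1] with a small missing fraction, per-gene temporal archetypes (unimodal
bumps peaking at one age), per-gene protein-localisation evidence and
functional keyword flags whose category frequencies default to the marginals
of the real survey, and a weighted protein-similarity graph with planted
families.  Everything is deterministic given a seed.

The density model is a triangular bump at the archetype's peak age carrying
multiplicative log-normal noise, clipped to [0, 1].  This preserves
nonnegativity and the one-peak-per-cluster structure the clustering stage
assumes; it does not emulate spatial structure, probe-level artefacts, or
correlated missingness, so passing tests demonstrate recovery of temporal
archetypes under noise, not robustness to those real-data features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from connscreen.annotate import KEYWORD_PRIORITY, LocalisationEvidence
from connscreen.io_tables import DEFAULT_AGES, ExpressionTable
from connscreen.ortholog_screen import ProteinNode

#: localisation categories with the real survey's marginal counts (of 1996)
LOCALISATION_MARGINALS = {
    "nuclear": 907,
    "secreted": 293,
    "gpi_or_single_pass": 286,
    "cytoplasmic": 267,
    "multi_pass": 240,
    "unannotated": 3,
}

#: functional groups 1..6 with the real survey's marginal counts (of 1996)
FUNCTIONAL_MARGINALS = {1: 286, 2: 91, 3: 360, 4: 270, 5: 677, 6: 312}

#: size of the full atlas survey and its genes with no thalamic data at any age
ATLAS_SURVEY_N_GENES = 2002
ATLAS_NO_DATA_GENES = ("Chrna1", "Hoxd9", "Lef1", "Nrp2", "Pbx1", "Rnd2")


def _default_archetypes() -> list[tuple[int, float]]:
    # one archetype peaking at each of the 7 ages, equal mixing
    return [(i, 1.0 / 7.0) for i in range(7)]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic survey.

    ``archetypes`` is a list of (peak age index, mixing proportion).  ``noise``
    is the log-normal sigma of the multiplicative noise; 0.3 gives realistic
    within-archetype scatter while keeping archetypes separable.
    ``enrichment`` maps (archetype index, category-or-group) to an odds
    multiplier for planting category enrichment in particular archetypes.
    """

    n_genes: int = 1996
    age_labels: tuple = DEFAULT_AGES
    archetypes: list = field(default_factory=_default_archetypes)
    noise: float = 0.3
    missing_rate: float = 0.01
    localisation_freqs: dict = field(default_factory=lambda: dict(LOCALISATION_MARGINALS))
    functional_freqs: dict = field(default_factory=lambda: dict(FUNCTIONAL_MARGINALS))
    enrichment: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(p for _, p in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype proportions sum to {total}, not 1")
        if self.noise < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for key, mult in self.enrichment.items():
            if mult <= 0:
                raise ValueError(f"enrichment factor for {key} must be > 0")


def _bump(peak: int, n_ages: int, lo: float = 0.05, hi: float = 0.5, width: float = 2.0) -> np.ndarray:
    t = np.arange(n_ages)
    return lo + (hi - lo) * np.clip(1.0 - np.abs(t - peak) / width, 0.0, 1.0)


def simulate_expression(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[ExpressionTable, np.ndarray]:
    """Draw a density table and return it with the true archetype labels.

    Gene g of archetype a gets d_{g,t} = bump_a(t) * exp(sigma * z_{g,t})
    clipped to [0, 1]; cells then go missing independently at
    ``missing_rate`` (a gene is never left fully missing).
    """
    rng = np.random.default_rng(seed)
    n_ages = len(spec.age_labels)
    props = np.array([p for _, p in spec.archetypes])
    labels = rng.choice(len(spec.archetypes), size=spec.n_genes, p=props)
    bases = np.stack([_bump(peak, n_ages) for peak, _ in spec.archetypes])
    noise = np.exp(spec.noise * rng.standard_normal((spec.n_genes, n_ages)))
    values = np.clip(bases[labels] * noise, 0.0, 1.0)
    if spec.missing_rate > 0:
        miss = rng.random((spec.n_genes, n_ages)) < spec.missing_rate
        full_rows = miss.all(axis=1)
        if full_rows.any():  # keep at least one observation per gene
            keep_col = rng.integers(0, n_ages, size=int(full_rows.sum()))
            miss[np.flatnonzero(full_rows), keep_col] = False
        values = np.where(miss, np.nan, values)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    df = pd.DataFrame(values, index=genes, columns=list(spec.age_labels))
    df.index.name = "gene_id"
    return ExpressionTable(df), labels


def simulate_full_survey(
    spec: SyntheticSpec | None = None, seed: int = 0
) -> tuple[ExpressionTable, np.ndarray]:
    """Synthetic stand-in for the full 2002-gene atlas survey table.

    The real survey covers 2002 genes of which six — Chrna1, Hoxd9, Lef1,
    Nrp2, Pbx1 and Rnd2 — have no thalamic density at any age.  This stand-in
    reproduces exactly that structure: the measured genes come from
    :func:`simulate_expression` and the six named genes are appended with
    every cell missing, shuffled into the gene order.  Returns the table and
    the archetype labels of the measured genes (in the order they appear in
    the returned table's measured subset).
    """
    spec = spec or SyntheticSpec()
    table, labels = simulate_expression(spec, seed)
    n_ages = len(spec.age_labels)
    empty = pd.DataFrame(
        np.full((len(ATLAS_NO_DATA_GENES), n_ages), np.nan),
        index=list(ATLAS_NO_DATA_GENES),
        columns=list(spec.age_labels),
    )
    df = pd.concat([table.data, empty])
    rng = np.random.default_rng(seed + 1)
    df = df.iloc[rng.permutation(len(df))]
    df.index.name = "gene_id"
    return ExpressionTable(df), labels


def _category_labels(
    rng: np.random.Generator,
    freqs: dict,
    archetype_labels: np.ndarray,
    enrichment: dict,
    allocation: str,
) -> list:
    cats = list(freqs)
    base = np.array([freqs[c] for c in cats], dtype=float)
    base = base / base.sum()
    n = len(archetype_labels)
    if allocation == "exact":
        if enrichment:
            raise ValueError("exact allocation requires a uniform (empty) enrichment map")
        # largest-remainder apportionment of the marginal counts, then shuffle
        raw = base * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
        pool = np.repeat(np.arange(len(cats)), counts)
        return [cats[i] for i in pool[rng.permutation(n)]]
    if allocation != "sample":
        raise ValueError(f"unknown allocation {allocation!r}")
    archetypes = np.unique(archetype_labels)
    probs = {}
    for a in archetypes:
        odds = base * np.array([enrichment.get((int(a), c), 1.0) for c in cats])
        probs[int(a)] = odds / odds.sum()
    # one inverse-CDF draw per gene, vectorised over the archetype groups
    u = rng.random(n)
    choice = np.empty(n, dtype=int)
    for a in archetypes:
        mask = archetype_labels == a
        cum = np.cumsum(probs[int(a)])
        choice[mask] = np.searchsorted(cum, u[mask], side="right")
    choice = np.minimum(choice, len(cats) - 1)
    return [cats[i] for i in choice]


def _evidence_for(rng: np.random.Generator, gene: str, category: str) -> LocalisationEvidence | None:
    """Predictor outputs consistent with the intended category (round-trips
    through the consensus decision table)."""
    if category == "unannotated":
        return None
    if category == "secreted":
        return LocalisationEvidence(gene, True, "none", "ext", 0, 0)
    if category == "gpi_or_single_pass":
        if rng.random() < 0.5:
            return LocalisationEvidence(gene, bool(rng.random() < 0.5), "P", "pla", 0, 0)
        return LocalisationEvidence(gene, True, "none", "pla", 1, 1)
    if category == "multi_pass":
        tm = int(rng.integers(2, 13))
        return LocalisationEvidence(gene, False, "none", "pla", tm, tm)
    if category == "cytoplasmic":
        comp = str(rng.choice(["cyt", "gol", "end", "mit", "per", "ves", "csk"]))
        return LocalisationEvidence(gene, False, "none", comp, 0, 0)
    if category == "nuclear":
        return LocalisationEvidence(gene, False, "none", "nuc", 0, 0)
    raise ValueError(f"unknown category {category!r}")


def simulate_annotations(
    spec: SyntheticSpec,
    gene_ids: list[str],
    archetype_labels: np.ndarray,
    seed: int = 0,
    allocation: str = "sample",
):
    """Draw localisation evidence and functional keyword flags per gene.

    Categories and groups are sampled from the spec's marginal frequencies
    with per-archetype odds multipliers from ``spec.enrichment`` (keys are
    ``(archetype, category_name)`` or ``(archetype, group_int)``).  With
    ``allocation="exact"`` (and no enrichment), category counts equal the
    marginal apportionment exactly and are assigned by random permutation —
    independent of the archetypes.

    Returns ``(evidence, keywords, truth)``: a gene → LocalisationEvidence
    (or None) dict, a boolean keyword-flag DataFrame, and a truth DataFrame
    with the drawn ``category`` and ``group`` per gene.
    """
    if len(gene_ids) != len(archetype_labels):
        raise ValueError("gene_ids and archetype_labels length mismatch")
    # distinct stream key: must not replay the expression generator's
    # uniforms when both are called with the same seed
    rng = np.random.default_rng([seed, 1])
    loc_enrich = {k: v for k, v in spec.enrichment.items() if isinstance(k[1], str)}
    grp_enrich = {k: v for k, v in spec.enrichment.items() if isinstance(k[1], int)}
    categories = _category_labels(rng, spec.localisation_freqs, archetype_labels,
                                  loc_enrich, allocation)
    groups = _category_labels(rng, spec.functional_freqs, archetype_labels,
                              grp_enrich, allocation)
    evidence = {g: _evidence_for(rng, g, c) for g, c in zip(gene_ids, categories)}
    n = len(gene_ids)
    grp_arr = np.asarray(groups)
    flag_arr = np.zeros((n, len(KEYWORD_PRIORITY)), dtype=bool)
    annotated = grp_arr <= 5
    flag_arr[np.flatnonzero(annotated), grp_arr[annotated] - 1] = True
    # occasionally add a lower-priority flag: priority must still win
    extra = annotated & (rng.random(n) < 0.3)
    extra_col = rng.integers(np.minimum(grp_arr, 5), 6, size=n)
    flag_arr[np.flatnonzero(extra), extra_col[extra]] = True
    # ~one third of group 6 carries a miscellaneous annotation
    misc = (grp_arr == 6) & (rng.random(n) < 107 / 312)
    flag_arr[misc, KEYWORD_PRIORITY.index("other_annotated")] = True
    flags = pd.DataFrame(flag_arr, index=gene_ids, columns=list(KEYWORD_PRIORITY))
    truth = pd.DataFrame({"category": categories, "group": groups,
                          "archetype": archetype_labels}, index=gene_ids)
    return evidence, flags, truth


_FAMILY_TAXA_CYCLE = ("mouse", "human", "fly", "worm")


def simulate_similarity_graph(
    n_families: int = 10,
    family_size: int = 8,
    p_intra: float = 0.9,
    p_inter: float = 0.02,
    intra_score: tuple[float, float] = (50.0, 100.0),
    inter_score: tuple[float, float] = (5.0, 15.0),
    seed: int = 0,
    templates: list[dict] | None = None,
) -> tuple[nx.Graph, dict[str, ProteinNode], dict[str, int]]:
    """Planted-partition similarity graph with per-family node annotations.

    Within-family node pairs are joined with probability ``p_intra`` and a
    high score; across families with probability ``p_inter`` and a low score.
    By default each family cycles through mouse/human/fly/worm taxa, is
    transmembrane, and carries an Ig motif; ``templates`` (one dict per
    family with optional ``taxa``, ``has_tm``, ``motifs``, ``family`` keys)
    overrides this to plant families that should fail the candidate filter.

    Returns the weighted graph, the node-annotation map, and the true
    node → family-index map.
    """
    if p_intra <= p_inter:
        raise ValueError("p_intra must exceed p_inter")
    if n_families < 1 or family_size < 1:
        raise ValueError("degenerate family layout")
    rng = np.random.default_rng([seed, 2])
    nodes: dict[str, ProteinNode] = {}
    families: dict[str, int] = {}
    members: list[list[str]] = []
    for f in range(n_families):
        tpl = (templates[f] if templates else {}) or {}
        taxa = tpl.get("taxa", _FAMILY_TAXA_CYCLE)
        has_tm = tpl.get("has_tm", True)
        motifs = frozenset(tpl.get("motifs", {"Ig"}))
        fam_name = tpl.get("family")
        ids = []
        for j in range(family_size):
            nid = f"f{f:02d}_p{j:02d}"
            nodes[nid] = ProteinNode(
                id=nid, taxon=taxa[j % len(taxa)], has_tm=has_tm,
                motifs=motifs, known_family=fam_name,
            )
            families[nid] = f
            ids.append(nid)
        members.append(ids)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for f, ids in enumerate(members):
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < p_intra:
                    g.add_edge(ids[i], ids[j], weight=float(rng.uniform(*intra_score)))
        for f2 in range(f + 1, n_families):
            for a in ids:
                for b in members[f2]:
                    if rng.random() < p_inter:
                        g.add_edge(a, b, weight=float(rng.uniform(*inter_score)))
    return g, nodes, families
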