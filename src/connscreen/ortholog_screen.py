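"""Orthology screen: Markov clustering of a protein-similarity graph.

All-against-all sequence comparison of the human, mouse, fly and worm
proteomes yields per-query ranked similarity hits.  Keeping each query's top
hits and symmetrising produces a weighted undirected graph whose dense
regions are protein families.  Markov clustering (MCL) finds those regions
deterministically by simulating random-walk flow: the column-stochastic
adjacency matrix is alternately *expanded* (matrix power, spreading flow) and
*inflated* (entrywise power then column renormalisation, sharpening flow)
until the flow matrix reaches a fixed point whose attractor structure defines
the partition.

Candidate families are then filtered for the profile of a conserved
connectivity label: the cluster must span mammals and invertebrates, contain
a mammalian transmembrane member carrying one of the extracellular motifs
characteristic of guidance/adhesion molecules (Ig, FN3, cadherin, LRR, EGF,
CUB, sema, plexin repeat), and must not belong to a family whose guidance
role is already established.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

TAXA = ("human", "mouse", "fly", "worm")
MAMMALS = frozenset({"human", "mouse"})
INVERTEBRATES = frozenset({"fly", "worm"})

#: extracellular motifs characteristic of known guidance/adhesion molecules
DEFAULT_MOTIF_WHITELIST = frozenset(
    {"Ig", "FN3", "cadherin", "LRR", "EGF", "CUB", "sema", "plexin_repeat"}
)

#: families with demonstrated guidance/connectivity roles, excluded as "known"
DEFAULT_FAMILY_BLACKLIST = frozenset({
    "DCC", "Neogenin", "Robo", "Slit", "L1CAM", "Contactin", "Eph-receptor",
    "Ephrin", "FGF", "FGFR", "RPTP", "Cadherin", "Protocadherin",
    "Semaphorin", "Plexin", "Integrin", "LRR-known",
})


@dataclass(frozen=True)
class ProteinNode:
    """One protein with the annotations the cluster filter consumes."""

    id: str
    taxon: str
    has_tm: bool = False
    motifs: frozenset = frozenset()
    known_family: str | None = None

    def __post_init__(self):
        if self.taxon not in TAXA:
            raise ValueError(f"{self.id}: taxon {self.taxon!r} not in {TAXA}")


@dataclass
class MclParams:
    """Markov-clustering parameters.

    ``inflation`` (> 1) controls granularity: higher values sharpen flow
    faster and give more, smaller clusters.  ``expansion`` (>= 2) is the
    matrix-power of the flow step.  Entries below ``prune`` are zeroed after
    each inflation to keep the matrix sparse in effect.
    """

    inflation: float = 2.0
    expansion: int = 2
    prune: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6
    self_loop: str = "max"  # "max" incident weight, or "one"

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.self_loop not in ("max", "one"):
            raise ValueError("self_loop policy must be 'max' or 'one'")


@dataclass
class ClusterSet:
    """Disjoint clusters covering all node ids; singletons allowed."""

    clusters: list[list[str]]
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        seen = [m for c in self.clusters for m in c]
        if len(seen) != len(set(seen)):
            raise ValueError("clusters overlap")

    def as_sets(self) -> list[frozenset]:
        return [frozenset(c) for c in self.clusters]

    def membership(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}


def top_n_edges(hits, n: int = 200) -> nx.Graph:
    """Build the undirected similarity graph from per-query ranked hits.

    ``hits`` is an iterable of ``(query, hit, score)`` records.  Each query
    keeps its ``n`` best-scoring hits; hits tied with the score at rank ``n``
    are all kept.  Self-hits are dropped.  Asymmetric pair scores are
    symmetrised by the maximum.
    """
    per_query: dict[str, list[tuple[float, str]]] = {}
    for query, hit, score in hits:
        score = float(score)
        if score < 0:
            raise ValueError(f"negative similarity score for ({query}, {hit})")
        if query == hit:
            continue
        per_query.setdefault(query, []).append((score, hit))
    g = nx.Graph()
    for query, scored in per_query.items():
        g.add_node(query)
        scored.sort(key=lambda t: (-t[0], t[1]))
        if len(scored) > n:
            cutoff = scored[n - 1][0]
            scored = [t for t in scored if t[0] >= cutoff]
        for score, hit in scored:
            prev = g.edges[query, hit]["weight"] if g.has_edge(query, hit) else -np.inf
            g.add_edge(query, hit, weight=max(prev, score))
    return g


def _flow_matrix(g: nx.Graph, nodes: list[str], params: MclParams) -> np.ndarray:
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    np.fill_diagonal(a, 0.0)
    if params.self_loop == "max":
        loops = a.max(axis=1)
        loops[loops == 0] = 1.0  # isolated node still needs a walk to stand on
    else:
        loops = np.ones(len(nodes))
    np.fill_diagonal(a, loops)
    return a / a.sum(axis=0, keepdims=True)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0, keepdims=True)
    sums[sums == 0] = 1.0
    return m / sums


def mcl(g: nx.Graph, params: MclParams | None = None) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Deterministic: no randomness anywhere.  Nodes reachable from several
    attractor systems are assigned to the system containing the lowest node
    id (in the graph's sorted node order).  Non-convergence within
    ``max_iter`` returns the current clustering with ``converged=False``.
    """
    params = params or MclParams()
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    m = _flow_matrix(g, nodes, params)
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.prune] = 0.0
        m = _normalize_columns(m)
        if np.abs(m - prev).max() < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", params.max_iter)
    return _interpret(m, nodes, converged, n_iter)


def _interpret(m: np.ndarray, nodes: list[str], converged: bool, n_iter: int) -> ClusterSet:
    n = len(nodes)
    eps = 1e-12
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:
        # pathological flow; fall back to one cluster per weakly-connected block
        comp = nx.connected_components(nx.from_numpy_array(m + m.T))
        clusters = sorted((sorted(nodes[i] for i in c) for c in comp), key=lambda c: c[0])
        return ClusterSet(clusters=clusters, converged=converged, n_iter=n_iter)
    # attractor systems: attractors linked by residual flow belong together
    sub = nx.Graph()
    sub.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > eps or m[j, i] > eps):
                sub.add_edge(i, j)
    systems = sorted((sorted(c) for c in nx.connected_components(sub)), key=lambda c: c[0])
    system_of = {a: s for s, comp in enumerate(systems) for a in comp}
    assignment: dict[int, int] = {}
    for j in range(n):
        pulls = sorted(i for i in attractors if m[i, j] > eps)
        if pulls:
            assignment[j] = system_of[pulls[0]]  # lowest attractor id wins
    next_singleton = len(systems)
    clusters_idx: dict[int, list[int]] = {}
    for j in range(n):
        s = assignment.get(j)
        if s is None:  # no attractor reaches it (pruned away): singleton
            s = next_singleton
            next_singleton += 1
        clusters_idx.setdefault(s, []).append(j)
    clusters = [sorted(nodes[j] for j in members) for members in clusters_idx.values()]
    clusters.sort(key=lambda c: c[0])
    return ClusterSet(clusters=clusters, converged=converged, n_iter=n_iter)


def filter_candidate_clusters(
    cs: ClusterSet,
    nodes: dict[str, ProteinNode],
    motif_whitelist: frozenset = DEFAULT_MOTIF_WHITELIST,
    family_blacklist: frozenset = DEFAULT_FAMILY_BLACKLIST,
    require_invertebrate_motif: bool = False,
) -> tuple[list[list[str]], dict[int, dict]]:
    """Keep clusters matching the conserved-connectivity-label profile.

    A cluster passes iff it has (a) a mammalian member, (b) an invertebrate
    member, (c) a mammalian member that is transmembrane AND carries a
    whitelisted motif (with ``require_invertebrate_motif`` an invertebrate
    member must carry a whitelisted motif too), and (d) no member of a
    blacklisted (already-characterised) family.  Returns the passing clusters
    and a per-cluster report of pass/fail reasons.
    """
    unannotated = [m for c in cs.clusters for m in c if m not in nodes]
    if unannotated:
        raise ValueError(f"unannotated node(s): {sorted(unannotated)}")
    passing = []
    report: dict[int, dict] = {}
    for idx, members in enumerate(cs.clusters):
        anns = [nodes[m] for m in members]
        has_mammal = any(a.taxon in MAMMALS for a in anns)
        has_invert = any(a.taxon in INVERTEBRATES for a in anns)
        mammal_tm_motif = any(
            a.taxon in MAMMALS and a.has_tm and (a.motifs & motif_whitelist) for a in anns
        )
        invert_motif = any(
            a.taxon in INVERTEBRATES and (a.motifs & motif_whitelist) for a in anns
        )
        blacklisted = sorted({a.known_family for a in anns
                              if a.known_family and a.known_family in family_blacklist})
        reasons = []
        if not has_mammal:
            reasons.append("no mammalian member")
        if not has_invert:
            reasons.append("no invertebrate member")
        if not mammal_tm_motif:
            reasons.append("no mammalian TM member with whitelisted motif")
        if require_invertebrate_motif and not invert_motif:
            reasons.append("no invertebrate member with whitelisted motif")
        if blacklisted:
            reasons.append(f"blacklisted family: {', '.join(blacklisted)}")
        ok = not reasons
        report[idx] = {"members": list(members), "passes": ok, "reasons": reasons}
        if ok:
            passing.append(list(members))
    return passing, report
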