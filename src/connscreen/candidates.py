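"""The candidate funnel: from clusters of interest to connectivity-label candidates.

Clusters enriched for GPI-anchored/single-pass surface proteins and for axon
guidance or synapse genes are the ones most likely to harbour unrecognised
connectivity labels.  The funnel intersects those clusters with the
extracellular localisation calls (secreted, GPI/single-pass or multi-pass)
and then drops genes flagged as uniformly expressed — spatial uniformity
cannot encode target-specific information.  The uniform/differential/
selective flags come from a visual screen of atlas images and therefore enter
as an external flag table; genes without a flag are retained as ``unknown``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from connscreen.annotate import EXTRACELLULAR_CATEGORIES

logger = logging.getLogger(__name__)

DIFFERENTIAL_FLAGS = ("selective", "differential", "uniform", "unknown")

#: columns expected in the per-gene annotation table the funnel consumes
ANNOTATION_COLUMNS = ("cluster", "localisation", "group")


@dataclass
class FunnelReport:
    """Counts and the candidate list produced by the funnel."""

    clusters_of_interest: set
    n_in_clusters: int
    n_extracellular: int
    candidates: pd.DataFrame  # gene_id index; cluster, localisation, group, differential_flag
    flag_source: str = "none"

    def to_dict(self) -> dict:
        return {
            "clusters_of_interest": sorted(self.clusters_of_interest),
            "n_in_clusters": self.n_in_clusters,
            "n_extracellular": self.n_extracellular,
            "n_candidates": int(len(self.candidates)),
            "candidates": list(self.candidates.index),
            "flag_source": self.flag_source,
        }


def select_clusters_of_interest(
    loc_profile: pd.DataFrame,
    fun_profile: pd.DataFrame,
    explicit: set | None = None,
    surface_category: str = "gpi_or_single_pass",
    guidance_groups: tuple = (1, 2),
) -> set:
    """Pick clusters enriched for surface proteins and for guidance/synapse genes.

    The default rule selects clusters whose observed/expected ratio for the
    GPI/single-pass category exceeds 1 AND whose ratio for functional group 1
    (axon guidance/adhesion) or group 2 (synapse) exceeds 1.  An explicit
    label set overrides the rule.  Both profiles must cover the same clusters.
    """
    if explicit is not None:
        return set(explicit)
    if list(loc_profile.index) != list(fun_profile.index):
        raise ValueError("profiles cover different clusters")
    chosen = set()
    for cluster in loc_profile.index:
        surface = loc_profile.loc[cluster, surface_category] > 1
        guidance = any(
            g in fun_profile.columns and fun_profile.loc[cluster, g] > 1
            for g in guidance_groups
        )
        if surface and guidance:
            chosen.add(cluster)
    if not chosen:
        logger.warning("no cluster passes the enrichment rule; funnel will be empty")
    return chosen


def funnel(annotations: pd.DataFrame, clusters_of_interest: set) -> FunnelReport:
    """Count and collect extracellular genes in the clusters of interest.

    ``annotations`` is indexed by gene id with columns ``cluster``,
    ``localisation``, ``group`` and optionally ``differential_flag``.
    Candidates are the extracellular genes of the selected clusters minus any
    flagged ``uniform``.
    """
    for col in ANNOTATION_COLUMNS:
        if col not in annotations.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    known = set(annotations["cluster"].unique())
    unknown = set(clusters_of_interest) - known
    if unknown:
        raise ValueError(f"unknown cluster label(s) in selection: {sorted(unknown)}")
    sub = annotations[annotations["cluster"].isin(clusters_of_interest)]
    extra = sub[sub["localisation"].isin(EXTRACELLULAR_CATEGORIES)].copy()
    if "differential_flag" not in extra.columns:
        extra["differential_flag"] = "unknown"
    extra["differential_flag"] = extra["differential_flag"].fillna("unknown")
    candidates = extra[extra["differential_flag"] != "uniform"]
    return FunnelReport(
        clusters_of_interest=set(clusters_of_interest),
        n_in_clusters=int(len(sub)),
        n_extracellular=int(len(extra)),
        candidates=candidates,
    )


def apply_differential_flags(
    report: FunnelReport,
    flags: pd.Series | dict,
    source: str = "external flag table",
) -> FunnelReport:
    """Re-filter the candidate list with an external uniform/differential screen.

    Genes missing from ``flags`` keep flag ``unknown`` and are retained;
    ``uniform`` genes are removed.  Idempotent for a fixed flag table.
    """
    flags = pd.Series(flags) if not isinstance(flags, pd.Series) else flags
    updated = report.candidates.copy()
    bad = set(flags.dropna().unique()) - set(DIFFERENTIAL_FLAGS)
    if bad:
        raise ValueError(f"unknown differential flag(s): {sorted(bad)}")
    updated["differential_flag"] = flags.reindex(updated.index).fillna("unknown")
    kept = updated[updated["differential_flag"] != "uniform"]
    return FunnelReport(
        clusters_of_interest=report.clusters_of_interest,
        n_in_clusters=report.n_in_clusters,
        n_extracellular=report.n_extracellular,
        candidates=kept,
        flag_source=source,
    )


def load_candidate_label_lists() -> pd.DataFrame:
    """The two published candidate-label lists the dual screen produced.

    Returns a two-column frame (``screen`` in {conserved, atlas}, ``gene``):
    the conserved-proteome screen's list and the atlas temporal screen's
    list.  A few genes were found by both screens, so the union of unique
    genes is smaller than the row count.
    """
    path = resources.files("connscreen").joinpath("data/candidate_connectivity_labels.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def candidate_label_union(lists: pd.DataFrame | None = None) -> tuple[set, set]:
    """Unique candidate genes across both screens and the shared subset."""
    lists = load_candidate_label_lists() if lists is None else lists
    conserved = set(lists.loc[lists["screen"] == "conserved", "gene"])
    atlas = set(lists.loc[lists["screen"] == "atlas", "gene"])
    return conserved | atlas, conserved & atlas
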