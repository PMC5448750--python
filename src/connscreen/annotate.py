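"""Consensus protein localisation calls and functional grouping.

Localisation evidence comes from four external predictors run upstream and
supplied as a table: a signal-peptide call, a GPI-modification-site quality
(P = predicted site, S = second predicted site), a compartment prediction with
its transmembrane-helix count, and an independent transmembrane-helix count
from a dedicated TM predictor.  The consensus combines them into one of five
categories — secreted, GPI-anchored/single-pass, multi-pass, cytoplasmic
(including organelles) or nuclear — plus ``unannotated`` when no evidence
exists.  Any extracellular hint (signal peptide, GPI site, or an
extracellular/plasma-membrane compartment) marks the protein as extracellular;
proteins whose two TM counts disagree (other than both being >= 2, which is
simply multi-pass) are resolved deterministically from the larger count and
flagged ``needs_curation`` so a curator's override file can reproduce any
hand-curated table exactly.

Functional grouping assigns each gene the highest-priority group among six:
(1) axon guidance and cell adhesion, (2) synapse, (3) receptor tyrosine
kinases/ligands and patterning, (4) neurotransmission, (5) chromatin and
transcription-factor activity, (6) other/unannotated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

PSORT_COMPARTMENTS = ("gol", "cyt", "csk", "end", "ext", "mit", "nuc", "per", "pla", "ves")
ORGANELLE_COMPARTMENTS = frozenset({"gol", "end", "mit", "per", "ves", "csk"})

LOCALISATION_CATEGORIES = (
    "secreted", "gpi_or_single_pass", "multi_pass", "cytoplasmic", "nuclear", "unannotated",
)
EXTRACELLULAR_CATEGORIES = frozenset({"secreted", "gpi_or_single_pass", "multi_pass"})

#: keyword flags in group-priority order (group = position + 1)
KEYWORD_PRIORITY = (
    "axon_guidance_or_adhesion",
    "synapse",
    "rtk_ligand_or_patterning",
    "neurotransmission",
    "chromatin_or_tf",
    "other_annotated",
)


@dataclass(frozen=True)
class LocalisationEvidence:
    """Raw predictor outputs for one gene product."""

    gene_id: str
    signal_peptide: bool
    gpi_quality: str  # "P", "S" or "none"
    psort_compartment: str
    psort_tm_count: int
    tmhmm_tm_count: int
    psort_probability: float = 1.0

    def __post_init__(self):
        if self.gpi_quality not in ("P", "S", "none"):
            raise ValueError(f"{self.gene_id}: gpi_quality {self.gpi_quality!r}")
        if self.psort_compartment not in PSORT_COMPARTMENTS:
            raise ValueError(f"{self.gene_id}: psort compartment {self.psort_compartment!r}")
        if self.psort_tm_count < 0 or self.tmhmm_tm_count < 0:
            raise ValueError(f"{self.gene_id}: negative TM count")


@dataclass(frozen=True)
class LocalisationCall:
    """Five-way consensus category plus the extracellular flag."""

    category: str
    extracellular: bool
    needs_curation: bool = False

    def __post_init__(self):
        if self.category not in LOCALISATION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.extracellular != (self.category in EXTRACELLULAR_CATEGORIES):
            raise ValueError("extracellular flag inconsistent with category")


def call_localisation(e: LocalisationEvidence | None) -> LocalisationCall:
    """Apply the consensus decision table to one evidence row.

    Total and deterministic; ``None`` (no evidence at all) yields
    ``unannotated``.
    """
    if e is None:
        return LocalisationCall("unannotated", extracellular=False)
    has_gpi = e.gpi_quality in ("P", "S")
    extracellular_evidence = (
        e.signal_peptide or has_gpi or e.psort_compartment in ("ext", "pla")
    )
    tms = (e.psort_tm_count, e.tmhmm_tm_count)
    disagree = e.psort_tm_count != e.tmhmm_tm_count
    if min(tms) >= 2:
        # both predictors find a multi-spanner; count disagreement is moot
        return _call("multi_pass", needs_curation=False)
    if (not disagree and e.psort_tm_count == 1) or has_gpi:
        return _call("gpi_or_single_pass", needs_curation=disagree)
    if disagree:
        return _call("gpi_or_single_pass" if max(tms) == 1 else "multi_pass",
                     needs_curation=True)
    # counts agree at 0, no GPI
    if extracellular_evidence:
        return _call("secreted", needs_curation=False)
    if e.psort_compartment == "nuc":
        return _call("nuclear", needs_curation=False)
    return _call("cytoplasmic", needs_curation=False)


def _call(category: str, needs_curation: bool) -> LocalisationCall:
    return LocalisationCall(category, extracellular=category in EXTRACELLULAR_CATEGORIES,
                            needs_curation=needs_curation)


def apply_overrides(
    calls: Mapping[str, LocalisationCall], overrides: Mapping[str, str]
) -> dict[str, LocalisationCall]:
    """Replace categories per a curator's gene → category override table."""
    out = dict(calls)
    for gene, category in overrides.items():
        out[gene] = LocalisationCall(
            category, extracellular=category in EXTRACELLULAR_CATEGORIES, needs_curation=False
        )
    return out


def assign_group(keywords: Mapping[str, bool]) -> int:
    """First true flag in priority order wins; no flag at all is Group 6.

    A gene involved in both axon guidance (group 1) and receptor-tyrosine-
    kinase signalling (group 3) is counted once, in group 1.
    """
    for i, flag in enumerate(KEYWORD_PRIORITY):
        if keywords.get(flag, False):
            return i + 1
    return 6


def tabulate_categories(
    values: Iterable, order: tuple | None = None
) -> pd.Series:
    """Count category (or group) occurrences over a gene set.

    Counts sum to the number of records; categories listed in ``order`` appear
    even when absent (count 0).
    """
    counts = Counter(values)
    if order is None:
        order = tuple(sorted(counts))
    for key in counts:
        if key not in order:
            order = order + (key,)
    return pd.Series({k: counts.get(k, 0) for k in order}, dtype=int)
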