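"""Per-gene normalisation of expression densities to relative temporal profiles.

Absolute densities are not comparable across genes (probe efficiency and
expression level differ), so each gene's values are divided by that gene's
mean density over its *present* ages.  A normalised value of 1 therefore means
"this gene at its own average level"; values below/above 1 mean below/above
average.  This keeps temporal shape and discards overall level, which is what
the downstream clustering compares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from connscreen.io_tables import ExpressionTable

logger = logging.getLogger(__name__)

POLICIES = ("fill-with-one", "drop-gene")


@dataclass
class NormalizedTable:
    """Gene × age matrix of per-gene relative profiles.

    ``data`` has the same shape and missingness as the source densities;
    ``gene_means`` stores each gene's mean density over present ages (needed
    to undo the normalisation); ``zero_mean_genes`` lists genes whose present
    values are all zero — they carry no temporal shape, are kept unscaled, and
    are excluded from clustering.
    """

    data: pd.DataFrame
    gene_means: pd.Series
    zero_mean_genes: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def age_labels(self) -> list[str]:
        return list(self.data.columns)


def normalize_per_gene(table: ExpressionTable) -> NormalizedTable:
    """Divide each gene's densities by its mean over present ages.

    Genes with every age missing are a hard error (run
    :func:`connscreen.io_tables.filter_all_missing` first).  Genes whose
    present values are all zero have no defined relative profile; they are
    left as-is, recorded in ``zero_mean_genes``, and skipped by
    :func:`impute_for_clustering`.
    """
    df = table.data
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        bad = list(df.index[all_missing])
        raise ValueError(
            f"genes with all ages missing: {bad}; apply filter_all_missing before normalizing"
        )
    means = df.mean(axis=1, skipna=True)
    zero = means == 0
    zero_genes = list(df.index[zero])
    if zero_genes:
        logger.warning("%d genes have all-zero present values; excluded from clustering: %s",
                       len(zero_genes), ", ".join(zero_genes))
    safe_means = means.where(~zero, 1.0)
    out = df.div(safe_means, axis=0)
    return NormalizedTable(data=out, gene_means=means, zero_mean_genes=zero_genes)


def impute_for_clustering(
    nt: NormalizedTable, policy: str = "fill-with-one"
) -> tuple[np.ndarray, list[str]]:
    """Produce a dense matrix for k-means from a normalised table.

    ``fill-with-one`` replaces missing cells with 1.0 — the gene's own average
    level, neutral under Euclidean distance on relative profiles.
    ``drop-gene`` removes any gene with a missing value.  Zero-mean genes are
    excluded under either policy.  Returns the matrix and the retained gene
    ids, in table order.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    df = nt.data.drop(index=nt.zero_mean_genes)
    if policy == "drop-gene":
        has_missing = df.isna().any(axis=1)
        dropped = list(df.index[has_missing])
        if dropped:
            logger.info("drop-gene policy removed %d genes with missing ages", len(dropped))
        df = df.loc[~has_missing]
    else:
        df = df.fillna(1.0)
    return df.to_numpy(dtype=float), list(df.index)
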