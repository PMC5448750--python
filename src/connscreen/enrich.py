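"""Cluster × category enrichment statistics.

Given a cluster assignment and a per-gene category (protein localisation or
functional group), the question is whether categories distribute across
clusters as the margins would predict.  The test is the plain Pearson
chi-square on the cluster × category contingency table: expected counts are
the marginal products E_ij = row_i * col_j / N, the statistic is
sum (O - E)^2 / E over cells with E > 0, df = (rows-1)(cols-1), and the
p-value is the upper tail of the chi-square distribution.  No continuity
correction is applied.  Single-category follow-up tests collapse the table to
category-vs-rest (10 × 2) and are Bonferroni-corrected: the family-wise
threshold is alpha divided by the number of category tests.

The per-cell observed/expected ratio is the enrichment profile: 1 means the
cluster holds exactly its expected share of the category, above 1 enrichment,
below 1 depletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Observed cluster × category counts with recomputable margins."""

    observed: pd.DataFrame  # rows = clusters, columns = categories, int counts

    def __post_init__(self):
        arr = self.observed.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative cell count")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer cell count")
            self.observed = self.observed.astype(int)

    @property
    def row_totals(self) -> pd.Series:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.observed.to_numpy().sum())

    def expected(self) -> pd.DataFrame:
        """Independence expectations E_ij = row_i * col_j / N."""
        n = self.grand_total
        if n == 0:
            raise ValueError("empty contingency table")
        e = np.outer(self.row_totals.to_numpy(), self.col_totals.to_numpy()) / n
        return pd.DataFrame(e, index=self.observed.index, columns=self.observed.columns)


@dataclass
class ChiSquareResult:
    """Pearson chi-square outcome with its multiple-testing context."""

    statistic: float
    df: int
    p_value: float
    alpha: float = 0.05
    n_tests: int = 1
    bonferroni_applied: bool = False

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests if self.bonferroni_applied else self.alpha

    @property
    def enriched(self) -> bool:
        return self.p_value <= self.threshold

    @property
    def conclusion(self) -> str:
        return "enriched" if self.enriched else "not"

    def p_band(self) -> str:
        """Human-readable p-value band (report style)."""
        for cut in (0.0001, 0.001, 0.005, 0.01, 0.05):
            if self.p_value < cut:
                return f"< {cut}"
        return "> 0.05" if self.p_value <= 0.1 else "> 0.1"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "alpha": self.alpha,
            "m": self.n_tests,
            "threshold": self.threshold,
            "bonferroni_applied": self.bonferroni_applied,
            "conclusion": self.conclusion,
        }


def build_contingency(
    assignments: Mapping[str, int] | pd.Series,
    categories: Mapping[str, str] | pd.Series,
    exclude: Iterable[str] = ("unannotated",),
) -> ContingencyTable:
    """Count genes per (cluster, category), dropping excluded categories.

    Every assigned gene must carry a category; offenders are listed in the
    error.  By default the ``unannotated`` category is excluded, so the tested
    population is the annotated genes only.
    """
    assignments = pd.Series(dict(assignments)) if not isinstance(assignments, pd.Series) else assignments
    categories = pd.Series(dict(categories)) if not isinstance(categories, pd.Series) else categories
    missing = sorted(set(assignments.index) - set(categories.index))
    if missing:
        raise ValueError(f"genes with a cluster but no category: {missing}")
    cats = categories.loc[assignments.index]
    keep = ~cats.isin(set(exclude))
    table = pd.crosstab(assignments[keep], cats[keep])
    table.index.name = "cluster"
    table.columns.name = "category"
    return ContingencyTable(table)


def chi_square(
    ct: ContingencyTable,
    alpha: float = 0.05,
    n_tests: int = 1,
    bonferroni: bool = False,
) -> ChiSquareResult:
    """Plain Pearson chi-square test of independence on the table.

    Zero row or column margins are degenerate (the corresponding cluster or
    category carries no genes) and are a hard error rather than silently
    dropped.
    """
    obs = ct.observed
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    if (ct.row_totals == 0).any() or (ct.col_totals == 0).any():
        raise ValueError("zero row/column margin: degenerate table")
    e = ct.expected().to_numpy()
    o = obs.to_numpy()
    mask = e > 0
    statistic = float((((o - e) ** 2)[mask] / e[mask]).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic=statistic, df=df, p_value=p, alpha=alpha,
                           n_tests=n_tests, bonferroni_applied=bonferroni)


def category_vs_rest(ct: ContingencyTable, category: str) -> ContingencyTable:
    """Collapse to a two-column table: the focus category vs all others summed.

    "Rest" is the other columns of the supplied table, so any categories
    excluded when the table was built stay excluded.  A table that already has
    exactly two columns, one of which is the focus, is returned unchanged.
    """
    if category not in ct.observed.columns:
        raise KeyError(f"unknown category {category!r}")
    if ct.observed.shape[1] == 2:
        return ContingencyTable(ct.observed.copy())
    focus = ct.observed[category]
    rest = ct.observed.drop(columns=[category]).sum(axis=1)
    out = pd.DataFrame({category: focus, "rest": rest})
    out.index.name = ct.observed.index.name
    return ContingencyTable(out)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m, unrounded."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def observed_over_expected(ct: ContingencyTable) -> pd.DataFrame:
    """Per-cell enrichment ratios O / E; undefined cells (E = 0) become NaN."""
    e = ct.expected().to_numpy()
    o = ct.observed.to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(e > 0, o / np.where(e > 0, e, 1.0), np.nan)
    if (e <= 0).any():
        logger.warning("zero expected count in %d cells; ratios reported as missing",
                       int((e <= 0).sum()))
    return pd.DataFrame(ratio, index=ct.observed.index, columns=ct.observed.columns)
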