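"""Superior-inferior asymmetry statistics over the 8x8 grid.

For every inferior cell ``a`` and its corresponding superior cell
``corresponding_cell(a)`` (row ``9 - r``, same column), the asymmetry of one
eye is the signed difference

    d(a) = thickness(a) - thickness(corresponding_cell(a))      [microns]

i.e. *inferior minus superior* — positive values mean the inferior hemisphere
is thicker.  This sign convention is fixed package-wide (the RNFL, which is
thicker inferiorly in healthy eyes, therefore shows positive asymmetries) and
is stated in every output header rather than being configurable.

Cohort-level inference uses the paired Student t-test on the per-eye
differences of each pair, and the empirical 2.5th/97.5th percentiles of those
differences define the normal reference range.  Normality screening with the
one-sample Kolmogorov-Smirnov test is advisory only: results are reported but
the pipeline never switches to a nonparametric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grid import (
    INFERIOR_ADDRESSES,
    CellAddress,
    Cohort,
    EyeRecord,
    corresponding_cell,
    validate_layer,
)

__all__ = [
    "PairedTestResult",
    "PercentileRange",
    "PairDifferenceSummary",
    "HemisphereSummary",
    "cell_pair_differences",
    "difference_matrix",
    "paired_t_test",
    "ks_normality",
    "percentile_range",
    "hemisphere_summary",
    "pairwise_summary_table",
    "adjust_p_values",
    "summaries_to_frame",
]

#: Fixed two-sided significance level.
DEFAULT_ALPHA = 0.05

#: Reference-range percentiles (central 95%).
LOWER_Q = 2.5
UPPER_Q = 97.5


@dataclass(frozen=True)
class PairedTestResult:
    """Paired Student t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


@dataclass(frozen=True)
class PercentileRange:
    """Central 95% reference range: 2.5th and 97.5th percentiles, microns."""

    p2_5: float
    p97_5: float

    def __post_init__(self) -> None:
        if self.p2_5 > self.p97_5:
            raise ValueError(f"p2_5 ({self.p2_5}) exceeds p97_5 ({self.p97_5})")

    def contains(self, value: float) -> bool:
        """Inclusive containment: boundary values count as within range."""
        return self.p2_5 <= value <= self.p97_5


@dataclass(frozen=True)
class PairDifferenceSummary:
    """Cohort asymmetry statistics for one corresponding cell pair.

    ``mean_diff``/``sd_diff`` describe the per-eye inferior-minus-superior
    differences; ``significant`` applies the two-sided paired t-test at the
    stated alpha (after any multiplicity adjustment requested upstream).
    """

    layer: str
    inferior_cell: CellAddress
    superior_cell: CellAddress
    n: int
    mean_diff: float
    sd_diff: float
    test: PairedTestResult
    range: PercentileRange
    significant: bool


@dataclass(frozen=True)
class HemisphereSummary:
    """Pooled thickness of one hemisphere (32 cells) over a cohort.

    ``per_eye_means`` holds each eye's unweighted mean of its 32 hemisphere
    cells.  ``pooled_mean`` equals the mean over all eyes x 32 cell values,
    which (equal weights) is also the mean of ``per_eye_means``.  ``pooled_sd``
    is the sample SD over all eyes x 32 cell values, i.e. it pools spatial
    variation across cells with between-subject variation.
    """

    layer: str
    hemisphere: str
    pooled_mean: float
    pooled_sd: float
    per_eye_means: tuple[float, ...]


def cell_pair_differences(eye: EyeRecord, layer: str) -> dict[CellAddress, float]:
    """Per-pair asymmetry of one eye: inferior minus superior, 32 entries.

    Keys are the 32 inferior-hemisphere addresses in row-major order.
    """
    grid = eye.grid_for(layer)
    return {
        a: grid.value_at(a) - grid.value_at(corresponding_cell(a))
        for a in INFERIOR_ADDRESSES
    }


def difference_matrix(cohort: Cohort, layer: str) -> np.ndarray:
    """Stack per-eye pair differences into an (n_eyes, 32) array.

    Column ``j`` corresponds to ``INFERIOR_ADDRESSES[j]``.
    """
    layer = validate_layer(layer)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cohort.require_layer(layer)
    rows = []
    for eye in cohort:
        vals = eye.grid_for(layer).values
        # inferior rows 1..4 minus superior rows 8..5 (same columns)
        rows.append((vals[:4] - vals[4:][::-1]).ravel())
    return np.asarray(rows)


def paired_t_test(differences) -> PairedTestResult:
    """Two-sided paired Student t-test on precomputed paired differences.

    Degenerate inputs: an all-equal sample with zero mean is a tie (t = 0,
    p = 1); an all-equal nonzero sample has no sampling variability to test
    against and is rejected.
    """
    d = np.asarray(differences, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs at least 2 observations, got {n}")
    if not np.all(np.isfinite(d)):
        raise ValueError("paired differences contain non-finite values")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(n, 0.0, 0.0, 0.0, df, 1.0)
        raise ValueError(
            "degenerate sample: zero variance with nonzero mean difference"
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTestResult(n, mean, sd, t, df, min(p, 1.0))


def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Plug-in parameters make the test anticonservative (no Lilliefors
    correction); it is used as an advisory screen only.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError(f"KS normality screen needs at least 5 values, got {x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("KS normality screen is undefined for a constant sample")
    res = sps.kstest(x, "norm", args=(float(x.mean()), sd))
    return float(res.statistic), float(res.pvalue)


def percentile_range(values) -> PercentileRange:
    """Empirical 2.5th/97.5th percentiles by linear rank interpolation.

    Uses interpolation between closest order statistics at rank
    ``1 + q (n - 1)`` (the "linear" method), e.g. 1..100 gives 3.475 and
    97.525.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"percentile range needs at least 2 values, got {x.size}")
    lo, hi = np.percentile(x, [LOWER_Q, UPPER_Q], method="linear")
    return PercentileRange(float(lo), float(hi))


def hemisphere_summary(
    cohort: Cohort, layer: str
) -> tuple[HemisphereSummary, HemisphereSummary]:
    """Pooled inferior and superior hemisphere thickness for one layer.

    Returns ``(inferior, superior)`` summaries.
    """
    layer = validate_layer(layer)
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cohort.require_layer(layer)
    inf_cells, sup_cells = [], []
    for eye in cohort:
        vals = eye.grid_for(layer).values
        inf_cells.append(vals[:4].ravel())
        sup_cells.append(vals[4:].ravel())
    out = []
    for name, stacked in (("inferior", inf_cells), ("superior", sup_cells)):
        arr = np.asarray(stacked)  # (n_eyes, 32)
        pooled = arr.ravel()
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        out.append(
            HemisphereSummary(
                layer=layer,
                hemisphere=name,
                pooled_mean=float(pooled.mean()),
                pooled_sd=sd,
                per_eye_means=tuple(float(m) for m in arr.mean(axis=1)),
            )
        )
    return out[0], out[1]


def adjust_p_values(p_values, method: str = "none") -> np.ndarray:
    """Optional multiplicity adjustment over a family of p-values.

    ``method`` is one of ``none`` (default — mirrors the reference analysis,
    which corrects nowhere across its 32 x 10 tests), ``holm`` or ``bh``
    (Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}; use none, holm or bh")
    return multipletests(p, method=key)[1]


def pairwise_summary_table(
    cohort: Cohort,
    layer: str,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "none",
) -> list[PairDifferenceSummary]:
    """Cohort asymmetry statistics for all 32 corresponding cell pairs.

    One record per inferior cell (row-major order): mean +/- SD of the
    per-eye differences, paired t-test, and the 2.5th/97.5th percentile
    reference range.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    layer = validate_layer(layer)
    diffs = difference_matrix(cohort, layer)
    tests = [paired_t_test(diffs[:, j]) for j in range(diffs.shape[1])]
    adj_p = adjust_p_values([t.p_value for t in tests], adjust)
    summaries = []
    for j, a in enumerate(INFERIOR_ADDRESSES):
        t = tests[j]
        summaries.append(
            PairDifferenceSummary(
                layer=layer,
                inferior_cell=a,
                superior_cell=corresponding_cell(a),
                n=t.n,
                mean_diff=t.mean_diff,
                sd_diff=t.sd_diff,
                test=t,
                range=percentile_range(diffs[:, j]),
                significant=bool(adj_p[j] < alpha),
            )
        )
    return summaries


def summaries_to_frame(summaries) -> "pandas.DataFrame":  # noqa: F821
    """Flatten pair summaries into the documented CSV layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "layer": [s.layer for s in summaries],
            "inf_row": [s.inferior_cell.row for s in summaries],
            "inf_col": [s.inferior_cell.col for s in summaries],
            "sup_row": [s.superior_cell.row for s in summaries],
            "sup_col": [s.superior_cell.col for s in summaries],
            "n": [s.n for s in summaries],
            "mean_diff_um": [s.mean_diff for s in summaries],
            "sd_diff_um": [s.sd_diff for s in summaries],
            "t": [s.test.t_statistic for s in summaries],
            "df": [s.test.degrees_of_freedom for s in summaries],
            "p": [s.test.p_value for s in summaries],
            "p2_5_um": [s.range.p2_5 for s in summaries],
            "p97_5_um": [s.range.p97_5 for s in summaries],
            "significant": [s.significant for s in summaries],
        }
    )
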