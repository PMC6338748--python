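"""Group-comparison statistics: chi-square, t-tests, proportion intervals.

Mirrors the descriptive/comparative analysis layer of the study: Pearson
chi-square on 2x2 contingency tables (uncorrected by default), unpaired
two-sample t-tests computable either from raw data or from printed
mean/SD/n summaries, Wilson score intervals for prevalences, and the
baseline-characteristics comparison tables by frailty or vital status.

A small helper reconstructs 2x2 counts from printed group percentages
and sizes, verifying against a printed margin before use — the route by
which published chi-square statistics can be recomputed exactly even
though the underlying data are not deposited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


class MarginError(ValueError):
    """A contingency table has a zero row or column margin."""


class ReconstructionWarning(UserWarning):
    """Counts reconstructed from percentages mismatch a printed margin."""


@dataclass(frozen=True)
class SummaryStats:
    """Printed-style summary of one group: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def pearson_chi2(
    table: Sequence[Sequence[float]] | np.ndarray,
    continuity_correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    Returns ``(statistic, df, p)``.  The continuity (Yates) correction is
    off by default.  Zero row/column margins make the expected counts
    undefined and raise :class:`MarginError`.
    """
    obs = np.asarray(table, float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() < 1:
        raise MarginError("empty table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise MarginError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(
        obs, correction=continuity_correction
    )
    return float(chi2), int(dof), float(p)


def two_sample_t_from_summary(
    a: SummaryStats, b: SummaryStats, pooled: bool = True
) -> tuple[float, float, float]:
    """Unpaired two-sample t-test from group summaries.

    Pooled-variance by default (df = n_a + n_b - 2); ``pooled=False``
    gives the Welch test.  Sign convention: a - b.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("t undefined: zero variance and equal means")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    df = a.n + b.n - 2 if pooled else _welch_df(a, b)
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_df(a: SummaryStats, b: SummaryStats) -> float:
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    return (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))


def two_sample_t(
    x: np.ndarray, y: np.ndarray, pooled: bool = True
) -> tuple[float, float, float]:
    """Unpaired t-test from raw samples (same conventions as the summary form)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    return two_sample_t_from_summary(
        SummaryStats(float(x.mean()), float(x.std(ddof=1)), len(x)),
        SummaryStats(float(y.mean()), float(y.std(ddof=1)), len(y)),
        pooled=pooled,
    )


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion k/n.

    ``wilson`` (default) inverts the score test and always contains k/n;
    ``wald`` is the normal approximation with bounds clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    sm_method = {"wilson": "wilson", "wald": "normal"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def counts_from_percentages(
    pct_a: float, n_a: int, pct_b: float, n_b: int,
    expected_margin: Optional[int] = None,
) -> np.ndarray:
    """Rebuild a 2x2 count table from printed group percentages and sizes.

    Row i is ``[round(pct_i/100 * n_i), n_i - that]``.  When the printed
    first-column margin is known, a mismatch after rounding emits a
    :class:`ReconstructionWarning` (the table is still returned).
    """
    k_a = round(pct_a / 100 * n_a)
    k_b = round(pct_b / 100 * n_b)
    if expected_margin is not None and k_a + k_b != expected_margin:
        warnings.warn(
            f"reconstructed margin {k_a + k_b} != printed {expected_margin}",
            ReconstructionWarning,
            stacklevel=2,
        )
    return np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=int)


# ---------------------------------------------------------------------------
# baseline-characteristics tables
# ---------------------------------------------------------------------------

#: Default layout of the comparison report: (column, kind) in table order.
DEFAULT_TABLE_LAYOUT: list[tuple[str, str]] = [
    ("age", "continuous"),
    ("sex", "categorical"),
    ("smoking", "categorical"),
    ("alcohol", "categorical"),
    ("exercise", "categorical"),
    ("hypertension", "categorical"),
    ("cardiovascular_disease", "categorical"),
    ("cerebrovascular_disease", "categorical"),
    ("diabetes", "categorical"),
    ("respiratory_disease", "categorical"),
    ("digestive_disease", "categorical"),
    ("chronic_renal_disease", "categorical"),
    ("osteoarthritis", "categorical"),
    ("fi", "continuous"),
]


def build_group_table(
    cohort: pd.DataFrame,
    grouping: str,
    layout: Optional[list[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Baseline-characteristics comparison between the two grouping levels.

    ``grouping`` is typically ``"frail"`` or ``"event"`` (vital status).
    Continuous rows report mean ± SD per group and a pooled t-test;
    categorical rows report the positive fraction per group and an
    uncorrected chi-square.  Significance flagged at 0.05 (*) and
    0.01 (**).
    """
    if grouping not in cohort.columns:
        raise ValueError(f"grouping column {grouping!r} absent")
    gvals = pd.to_numeric(cohort[grouping], errors="coerce") \
        if cohort[grouping].dtype != object else cohort[grouping]
    levels = sorted(pd.unique(gvals.dropna()))
    if len(levels) != 2:
        raise ValueError(
            f"grouping {grouping!r} must have exactly 2 levels, "
            f"got {levels}"
        )
    g0 = cohort[gvals == levels[0]]
    g1 = cohort[gvals == levels[1]]
    layout = layout if layout is not None else [
        (c, k) for c, k in DEFAULT_TABLE_LAYOUT
        if c in cohort.columns and c != grouping
    ]
    rows = []
    for col, kind in layout:
        if kind == "continuous":
            x = pd.to_numeric(g0[col], errors="coerce").dropna()
            y = pd.to_numeric(g1[col], errors="coerce").dropna()
            t, _, p = two_sample_t(x.to_numpy(), y.to_numpy())
            row = {
                "variable": col, "kind": kind,
                "group0": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                "group1": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                "statistic": t, "p": p,
            }
        else:
            if col == "sex":
                a = (g0[col].astype(str) == "female").astype(int)
                b = (g1[col].astype(str) == "female").astype(int)
            else:
                a = pd.to_numeric(g0[col], errors="coerce").dropna().astype(int)
                b = pd.to_numeric(g1[col], errors="coerce").dropna().astype(int)
            table = np.array(
                [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            )
            try:
                chi2, _, p = pearson_chi2(table)
            except MarginError:
                chi2, p = np.nan, np.nan
            row = {
                "variable": col, "kind": kind,
                "group0": f"{100 * a.mean():.1f}%",
                "group1": f"{100 * b.mean():.1f}%",
                "statistic": chi2, "p": p,
            }
        row["sig"] = ("**" if row["p"] < 0.01 else
                      "*" if row["p"] < 0.05 else "")
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["grouping"] = grouping
    out.attrs["levels"] = levels
    out.attrs["n0"], out.attrs["n1"] = len(g0), len(g1)
    return out


def render_group_table(report: pd.DataFrame) -> str:
    """Fixed-width plain-text rendering of a comparison report."""
    grouping = report.attrs.get("grouping", "group")
    n0 = report.attrs.get("n0", "?")
    n1 = report.attrs.get("n1", "?")
    lines = [
        f"Characteristics by {grouping} "
        f"(level 0: n={n0}; level 1: n={n1})",
        f"{'variable':<26}{'level 0':>16}{'level 1':>16}"
        f"{'stat':>10}{'p':>10}  sig",
        "-" * 82,
    ]
    for r in report.itertuples(index=False):
        stat = f"{r.statistic:.2f}" if np.isfinite(r.statistic) else "NA"
        p = f"{r.p:.3f}" if np.isfinite(r.p) else "NA"
        lines.append(
            f"{r.variable:<26}{r.group0:>16}{r.group1:>16}"
            f"{stat:>10}{p:>10}  {r.sig}"
        )
    return "\n".join(lines)
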