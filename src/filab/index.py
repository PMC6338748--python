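"""FI-LAB scoring: deficit ratio, completeness rule, frailty cut-point.

The frailty index is the number of deficits a subject presents divided by
the number of deficits considered for that subject.  Here the considered
items are the non-missing variables of the lab panel, and a score is only
regarded as valid when at least 70% of panel variables were measured
(the completeness rule).  Subjects at or above the 0.21 cut-point are
classified frail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Published frailty cut-point: FI-LAB >= 0.21 is frail.
DEFAULT_CUTPOINT = 0.21
#: Minimum fraction of panel variables that must be non-missing.
DEFAULT_COMPLETENESS = 0.70


class EmptyCohortError(ValueError):
    """Raised when a summary is requested over zero valid scores."""


@dataclass(frozen=True)
class FIResult:
    """One subject's frailty-index score and classification."""

    subject_id: object
    fi: Optional[float]          # None when invalid
    n_deficits: int
    n_considered: int            # non-missing panel variables
    completeness: float          # n_considered / panel size
    valid: bool
    frail: Optional[bool]        # defined only when valid


@dataclass(frozen=True)
class FIDistributionSummary:
    """Cohort-level distribution of valid FI-LAB scores."""

    mean: float
    sd: float
    median: float
    maximum: float
    p99: float
    prevalence_frail: float
    n_valid: int


def compute_fi(
    codes: Union[Mapping[str, Optional[int]], Sequence[Optional[int]]],
    completeness_threshold: float = DEFAULT_COMPLETENESS,
    cutpoint: float = DEFAULT_CUTPOINT,
    subject_id: object = None,
) -> FIResult:
    """Score one subject's deficit vector.

    The denominator is the count of non-missing codes; the score is
    invalid (``fi`` and ``frail`` undefined) when fewer than
    ``completeness_threshold`` of the panel variables are non-missing.
    An all-missing vector yields an invalid result, never a division
    by zero.
    """
    if not 0 < completeness_threshold <= 1:
        raise ValueError("completeness_threshold must be in (0, 1]")
    values = list(codes.values()) if isinstance(codes, Mapping) else list(codes)
    if len(values) == 0:
        raise ValueError("empty deficit vector")
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    n_considered = int(np.sum(~np.isnan(arr)))
    n_deficits = int(np.nansum(arr)) if n_considered else 0
    completeness = n_considered / len(arr)
    valid = completeness >= completeness_threshold
    fi = n_deficits / n_considered if valid else None
    frail = classify_frailty(fi, cutpoint) if valid else None
    return FIResult(
        subject_id=subject_id,
        fi=fi,
        n_deficits=n_deficits,
        n_considered=n_considered,
        completeness=completeness,
        valid=valid,
        frail=frail,
    )


def classify_frailty(fi: float, cutpoint: float = DEFAULT_CUTPOINT) -> bool:
    """Frail iff fi >= cutpoint (the cut-point is inclusive)."""
    if not 0 <= fi <= 1:
        raise ValueError(f"FI must lie in [0, 1], got {fi}")
    return fi >= cutpoint


def score_cohort(
    deficits: pd.DataFrame,
    completeness_threshold: float = DEFAULT_COMPLETENESS,
    cutpoint: float = DEFAULT_CUTPOINT,
) -> pd.DataFrame:
    """Vectorised scoring of a deficit matrix (rows = subjects).

    ``deficits`` holds 0.0/1.0/NaN codes, one column per panel variable.
    Returns a DataFrame indexed like ``deficits`` with columns
    ``fi, n_deficits, n_considered, completeness, valid, frail``
    (``fi``/``frail`` are NaN where invalid).
    """
    arr = deficits.to_numpy(float)
    n_panel = arr.shape[1]
    n_considered = np.sum(~np.isnan(arr), axis=1)
    n_deficits = np.nansum(arr, axis=1)
    completeness = n_considered / n_panel
    valid = completeness >= completeness_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.where(valid & (n_considered > 0),
                      n_deficits / np.maximum(n_considered, 1), np.nan)
    frail = np.where(valid, (fi >= cutpoint).astype(float), np.nan)
    return pd.DataFrame(
        {
            "fi": fi,
            "n_deficits": n_deficits.astype(int),
            "n_considered": n_considered.astype(int),
            "completeness": completeness,
            "valid": valid,
            "frail": frail,
        },
        index=deficits.index,
    )


def summarise_fi(
    results: Union[Iterable[FIResult], pd.DataFrame],
    cutpoint: float = DEFAULT_CUTPOINT,
) -> FIDistributionSummary:
    """Distribution summary over the *valid* scores of a cohort.

    Accepts either an iterable of :class:`FIResult` or the DataFrame
    produced by :func:`score_cohort`.  The SD uses the n-1 denominator;
    percentiles use linear interpolation between order statistics.
    Prevalence is the frail fraction among valid subjects.
    """
    if isinstance(results, pd.DataFrame):
        fis = results.loc[results["valid"].astype(bool), "fi"].to_numpy(float)
    else:
        fis = np.array([r.fi for r in results if r.valid], dtype=float)
    if fis.size == 0:
        raise EmptyCohortError("no valid FI scores to summarise")
    sd = float(np.std(fis, ddof=1)) if fis.size > 1 else 0.0
    return FIDistributionSummary(
        mean=float(np.mean(fis)),
        sd=sd,
        median=float(np.median(fis)),
        maximum=float(np.max(fis)),
        p99=float(np.percentile(fis, 99)),
        prevalence_frail=float(np.mean(fis >= cutpoint)),
        n_valid=int(fis.size),
    )
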