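"""Reference-range panels and deficit coding for routine blood variables.

A laboratory frailty index counts how many of a subject's routine blood
tests fall outside their clinical reference range.  This module holds the
panel definition — one :class:`ReferenceRange` per (variable, sex) — and
the coding rules that turn a raw lab value into a deficit code:

* ``0`` — the value is within the normal range (or satisfies the cut-off),
* ``1`` — the value is outside it (a deficit),
* ``None`` — the value is missing.

Two panels ship with the package.  ``panel_table3`` carries the published
reference bounds for the 22-variable panel verbatim, including a female
MCV lower bound of 32.6 fL that is almost certainly a misprint of 82.6;
``panel_table3_mcv82`` is the same panel with that one bound corrected.
The default is the verbatim panel: fidelity first, plausibility opt-in.

Coding conventions (configurable per entry via ``bound_style``):

* ``closed_interval`` — normal iff ``lower <= value <= upper`` (endpoints
  inclusive: a value exactly at a two-sided bound is not a deficit);
* ``upper_only`` — printed as "< x": normal iff ``value < x`` (so a value
  exactly at the cut-off *is* a deficit);
* ``lower_only`` — printed as ">= x": normal iff ``value >= x``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BOUND_STYLES = ("closed_interval", "upper_only", "lower_only")
SEXES = ("male", "female", "any")

#: Names of the bundled panel files (without extension).
BUNDLED_PANELS = ("panel_table3", "panel_table3_mcv82")


class PanelConfigError(ValueError):
    """Raised when a reference-panel configuration is invalid."""


class DataError(ValueError):
    """Raised when subject data cannot be coded (bad sex, non-numeric lab)."""


@dataclass(frozen=True)
class ReferenceRange:
    """One lab variable's normality interval or one-sided cut-off.

    Parameters
    ----------
    variable : str
        Panel variable name (e.g. ``"wbc"``).
    sex : str
        ``"male"``, ``"female"`` or ``"any"`` for sex-independent ranges.
    lower, upper : float or None
        Bounds; at least one must be present and ``lower < upper`` when
        both are.
    style : str
        One of ``closed_interval``, ``upper_only``, ``lower_only``.
    units : str
        Carried as metadata only; no unit conversion is attempted.
    """

    variable: str
    sex: str
    lower: Optional[float]
    upper: Optional[float]
    style: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PanelConfigError(f"{self.variable}: unknown sex {self.sex!r}")
        if self.style not in BOUND_STYLES:
            raise PanelConfigError(
                f"{self.variable}: unknown bound style {self.style!r}"
            )
        if self.lower is None and self.upper is None:
            raise PanelConfigError(f"{self.variable}: no bounds given")
        if self.style == "closed_interval":
            if self.lower is None or self.upper is None:
                raise PanelConfigError(
                    f"{self.variable}: closed interval needs both bounds"
                )
            if not self.lower < self.upper:
                raise PanelConfigError(
                    f"{self.variable}: lower bound {self.lower} not below "
                    f"upper bound {self.upper}"
                )
        elif self.style == "upper_only" and self.upper is None:
            raise PanelConfigError(f"{self.variable}: upper_only needs upper bound")
        elif self.style == "lower_only" and self.lower is None:
            raise PanelConfigError(f"{self.variable}: lower_only needs lower bound")


Panel = list  # list[ReferenceRange]; a read-only alias used in signatures


def load_reference_panel(
    source: Union[str, "pd.DataFrame", None] = None,
) -> list[ReferenceRange]:
    """Load a reference panel from a CSV path, DataFrame, or bundled name.

    ``source=None`` loads the default bundled panel (``panel_table3``).
    A string naming a bundled panel loads that panel; any other string is
    treated as a filesystem path to a CSV with columns
    ``variable,sex,lower,upper,style,units``.

    Raises
    ------
    PanelConfigError
        On duplicate (variable, sex) entries, an empty panel, or invalid
        bounds.
    """
    if source is None:
        source = "panel_table3"
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif source in BUNDLED_PANELS:
        ref = resources.files("filab.data") / f"{source}.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)

    required = {"variable", "sex", "lower", "upper", "style"}
    missing = required - set(df.columns)
    if missing:
        raise PanelConfigError(f"panel config lacks columns: {sorted(missing)}")
    if len(df) == 0:
        raise PanelConfigError("empty reference panel")

    panel: list[ReferenceRange] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (str(row.variable), str(row.sex))
        if key in seen:
            raise PanelConfigError(f"duplicate panel entry for {key}")
        seen.add(key)
        panel.append(
            ReferenceRange(
                variable=str(row.variable),
                sex=str(row.sex),
                lower=None if pd.isna(row.lower) else float(row.lower),
                upper=None if pd.isna(row.upper) else float(row.upper),
                style=str(row.style),
                units="" if not hasattr(row, "units") or pd.isna(row.units)
                else str(row.units),
            )
        )
    # every (variable, sex) a subject can present must resolve uniquely:
    # a variable may not mix an "any" entry with sex-specific ones
    for var in {r.variable for r in panel}:
        sexes = {r.sex for r in panel if r.variable == var}
        if "any" in sexes and len(sexes) > 1:
            raise PanelConfigError(
                f"{var}: 'any' entry conflicts with sex-specific entries"
            )
    logger.info(
        "loaded reference panel: %d variables, %d entries",
        len({r.variable for r in panel}), len(panel),
    )
    return panel


def panel_variables(panel: Iterable[ReferenceRange]) -> list[str]:
    """Ordered unique variable names of a panel (order of first appearance)."""
    seen: dict[str, None] = {}
    for r in panel:
        seen.setdefault(r.variable, None)
    return list(seen)


def resolve_range(
    panel: Iterable[ReferenceRange], variable: str, sex: str
) -> ReferenceRange:
    """Return the unique range applying to (variable, sex)."""
    if sex not in ("male", "female"):
        raise DataError(f"sex must be 'male' or 'female', got {sex!r}")
    for r in panel:
        if r.variable == variable and r.sex in (sex, "any"):
            return r
    raise PanelConfigError(f"no range for variable {variable!r}, sex {sex!r}")


def code_value(
    value: Optional[float], range_: ReferenceRange
) -> Optional[int]:
    """Code one lab value against one reference range.

    Returns 0 (normal), 1 (deficit) or None (missing input).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise DataError(
            f"{range_.variable}: non-numeric lab value {value!r}"
        ) from exc
    if np.isnan(v):
        return None
    if range_.style == "closed_interval":
        normal = range_.lower <= v <= range_.upper
    elif range_.style == "upper_only":
        normal = v < range_.upper
    else:  # lower_only
        normal = v >= range_.lower
    return 0 if normal else 1


def code_subject(
    labs: Mapping[str, Optional[float]],
    sex: str,
    panel: Iterable[ReferenceRange],
) -> dict[str, Optional[int]]:
    """Code all panel variables for one subject.

    Returns an ordered mapping variable -> {0, 1, None} over the full
    panel; lab keys absent from ``labs`` code as missing.  Keys in
    ``labs`` that are not panel variables are logged and ignored.
    """
    panel = list(panel)
    variables = panel_variables(panel)
    unknown = set(labs) - set(variables)
    if unknown:
        logger.warning("ignoring %d unknown lab keys: %s",
                       len(unknown), sorted(unknown))
    codes: dict[str, Optional[int]] = {}
    for var in variables:
        r = resolve_range(panel, var, sex)
        codes[var] = code_value(labs.get(var), r)
    return codes


def code_cohort(
    cohort: pd.DataFrame,
    panel: Iterable[ReferenceRange],
    sex_column: str = "sex",
) -> pd.DataFrame:
    """Vectorised deficit coding of a whole cohort table.

    ``cohort`` must carry a sex column with values male/female and one
    column per panel variable (absent columns code as missing for all
    subjects).  Returns a float DataFrame (0.0, 1.0, NaN) indexed like
    ``cohort``, one column per panel variable in panel order.
    """
    panel = list(panel)
    variables = panel_variables(panel)
    if sex_column not in cohort.columns:
        raise DataError(f"cohort lacks {sex_column!r} column")
    sex = cohort[sex_column].astype(str)
    bad_sex = ~sex.isin(["male", "female"])
    if bad_sex.any():
        raise DataError(
            f"{int(bad_sex.sum())} subjects with sex not in {{male, female}}"
        )
    out = pd.DataFrame(np.nan, index=cohort.index, columns=variables)
    for var in variables:
        if var not in cohort.columns:
            continue
        values = pd.to_numeric(cohort[var], errors="coerce").to_numpy(float)
        codes = np.full(len(cohort), np.nan)
        for r in (r for r in panel if r.variable == var):
            mask = np.ones(len(cohort), bool) if r.sex == "any" \
                else (sex == r.sex).to_numpy()
            v = values[mask]
            if r.style == "closed_interval":
                normal = (v >= r.lower) & (v <= r.upper)
            elif r.style == "upper_only":
                normal = v < r.upper
            else:
                normal = v >= r.lower
            c = np.where(np.isnan(v), np.nan, (~normal).astype(float))
            codes[mask] = c
        out[var] = codes
    return out
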