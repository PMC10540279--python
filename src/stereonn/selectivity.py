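"""Selectivity encodings and the Boltzmann relation between er and free energy.

Enantioselectivity for a reaction under Curtin-Hammett control can be written
five equivalent ways: enantiomeric excess (ee), enantiomeric ratio (er),
ln(er), the S percentage, or the R percentage.  The er is linked to the free
energy difference between the two diastereomeric transition states by

    ddG = R * T * ln(major / minor),      er_major = K / (1 + K),  K = exp(ddG / R T)

so that a 90:10 er corresponds to about 1.3 kcal/mol at 298.15 K.  All
conversions here are exact and mutually inverse.

er strings are read as "R:S" by default (the convention under which an
S-selective ligand prints its minor component first, e.g. "11:89"); this can
be overridden per call.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL

__all__ = [
    "Metric",
    "MajorLabel",
    "SelectivityRecord",
    "ThermoContext",
    "parse_er",
    "format_er",
    "to_metric",
    "from_metric",
    "er_to_ddg",
    "ddg_to_er",
    "signed_ddg",
]


class Metric(str, enum.Enum):
    ee = "ee"
    er_ratio = "er_ratio"
    ln_er = "ln_er"
    s_select = "s_select"
    r_select = "r_select"


class MajorLabel(str, enum.Enum):
    R = "R"
    S = "S"


@dataclass(frozen=True)
class SelectivityRecord:
    """Enantiomer percentages; strictly inside (0, 100) so every metric is finite."""

    s_percent: float
    r_percent: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s_percent < 100.0 and 0.0 < self.r_percent < 100.0):
            raise ValueError(
                f"percentages must lie strictly in (0, 100): got "
                f"S={self.s_percent}, R={self.r_percent}"
            )
        if abs(self.s_percent + self.r_percent - 100.0) > 1e-9:
            raise ValueError("S and R percentages must sum to 100")

    @property
    def major_percent(self) -> float:
        return max(self.s_percent, self.r_percent)

    @property
    def minor_percent(self) -> float:
        return min(self.s_percent, self.r_percent)

    @property
    def major_label(self) -> MajorLabel:
        return MajorLabel.S if self.s_percent >= self.r_percent else MajorLabel.R


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant for er <-> ddG conversions."""

    temperature_K: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL  # kcal mol^-1 K^-1

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature_K


def parse_er(
    text: str,
    *,
    order: str = "rs",
    major_is_S: bool | None = None,
    clamp: bool = False,
) -> SelectivityRecord:
    """Parse an "X:Y" er string into a :class:`SelectivityRecord`.

    Parameters
    ----------
    order:
        ``"rs"`` (default) reads the first field as the R percentage, ``"sr"``
        the reverse.
    major_is_S:
        If set, overrides ``order``: the larger component is assigned to S
        (True) or to R (False) regardless of field order.
    clamp:
        If True, a 100:0 input is clamped to 99.95:0.05 instead of raising
        (ratio and log metrics are otherwise infinite).
    """
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"er must be two numbers separated by ':', got {text!r}")
    try:
        a, b = (float(p) for p in parts)
    except ValueError:
        raise ValueError(f"non-numeric er component in {text!r}") from None
    if a < 0 or b < 0 or a + b <= 0:
        raise ValueError(f"er components must be positive: {text!r}")
    a, b = 100.0 * a / (a + b), 100.0 * b / (a + b)
    if min(a, b) <= 0.0:
        if not clamp:
            raise ValueError(
                f"er {text!r} has a zero component; ratio/log metrics would be "
                "infinite (pass clamp=True to clamp to 99.95:0.05)"
            )
        a, b = (99.95, 0.05) if a > b else (0.05, 99.95)
    if major_is_S is not None:
        major, minor = max(a, b), min(a, b)
        s, r = (major, minor) if major_is_S else (minor, major)
    elif order == "rs":
        r, s = a, b
    elif order == "sr":
        s, r = a, b
    else:
        raise ValueError("order must be 'rs' or 'sr'")
    return SelectivityRecord(s_percent=s, r_percent=r)


def format_er(rec: SelectivityRecord, *, order: str = "rs", decimals: int = 1) -> str:
    """Render a record back to "X:Y" text (one decimal by default)."""
    first, second = (
        (rec.r_percent, rec.s_percent) if order == "rs" else (rec.s_percent, rec.r_percent)
    )
    return f"{first:.{decimals}f}:{second:.{decimals}f}"


def to_metric(rec: SelectivityRecord, metric: Metric | str) -> float:
    """Project a record onto one of the five selectivity encodings."""
    metric = Metric(metric)
    if metric is Metric.ee:
        return abs(rec.s_percent - rec.r_percent)
    if metric is Metric.er_ratio:
        return rec.major_percent / rec.minor_percent
    if metric is Metric.ln_er:
        return math.log(rec.major_percent / rec.minor_percent)
    if metric is Metric.s_select:
        return rec.s_percent
    if metric is Metric.r_select:
        return rec.r_percent
    raise AssertionError(metric)


def from_metric(
    value: float,
    metric: Metric | str,
    major_label: MajorLabel | str = MajorLabel.S,
) -> SelectivityRecord:
    """Invert :func:`to_metric`.

    ``ee``, ``er_ratio`` and ``ln_er`` do not identify which enantiomer is the
    major one, so ``major_label`` resolves the ambiguity (default S, matching
    the S-selective system the package targets).
    """
    metric = Metric(metric)
    major_label = MajorLabel(major_label)
    if metric is Metric.s_select:
        if not (0.0 < value < 100.0):
            raise ValueError(f"s_select must lie in (0, 100), got {value}")
        return SelectivityRecord(s_percent=value, r_percent=100.0 - value)
    if metric is Metric.r_select:
        if not (0.0 < value < 100.0):
            raise ValueError(f"r_select must lie in (0, 100), got {value}")
        return SelectivityRecord(s_percent=100.0 - value, r_percent=value)
    if metric is Metric.ee:
        if not (0.0 <= value < 100.0):
            raise ValueError(f"ee must lie in [0, 100), got {value}")
        major = 50.0 + value / 2.0
    elif metric is Metric.er_ratio:
        if value <= 0.0:
            raise ValueError(f"er_ratio must be positive, got {value}")
        major = 100.0 * value / (1.0 + value)
    elif metric is Metric.ln_er:
        k = math.exp(value)
        major = 100.0 * k / (1.0 + k)
    else:
        raise AssertionError(metric)
    minor = 100.0 - major
    if major_label is MajorLabel.S:
        return SelectivityRecord(s_percent=major, r_percent=minor)
    return SelectivityRecord(s_percent=minor, r_percent=major)


def signed_ddg(rec: SelectivityRecord, ctx: ThermoContext | None = None) -> float:
    """Signed free-energy gap R T ln(S/R) in kcal/mol: positive when S is the
    major enantiomer, negative when R is."""
    ctx = ctx or ThermoContext()
    return ctx.rt * math.log(rec.s_percent / rec.r_percent)


def er_to_ddg(rec: SelectivityRecord, ctx: ThermoContext | None = None) -> float:
    """Free-energy gap (kcal/mol) between the diastereomeric transition states.

    ddG = R T ln(major/minor); non-negative, zero for a racemate.
    """
    ctx = ctx or ThermoContext()
    return ctx.rt * math.log(rec.major_percent / rec.minor_percent)


def ddg_to_er(
    ddg: float,
    major_label: MajorLabel | str = MajorLabel.S,
    ctx: ThermoContext | None = None,
) -> SelectivityRecord:
    """Invert :func:`er_to_ddg`: major fraction K/(1+K) with K = exp(ddG/RT).

    ``ddg`` must be non-negative; a negative gap means the other enantiomer is
    the major one -- swap ``major_label`` instead.
    """
    if ddg < 0:
        raise ValueError("ddg must be non-negative; swap major_label for the reverse")
    ctx = ctx or ThermoContext()
    k = math.exp(ddg / ctx.rt)
    major = 100.0 * k / (1.0 + k)
    minor = 100.0 - major
    if MajorLabel(major_label) is MajorLabel.S:
        return SelectivityRecord(s_percent=major, r_percent=minor)
    return SelectivityRecord(s_percent=minor, r_percent=major)
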