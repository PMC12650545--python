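"""Ratiometric phenol-red pH: absorbance ratio, apparent-pKa calibration and
pH computation.

The method chains three relations.  The absorbance ratio

    R = A(560 nm) / A(430 nm)

is concentration- and path-length-independent because both bands scale with
the same dye amount.  A modified Henderson–Hasselbalch calibration converts
the stock medium (manufacturer pH) plus two saturating reference samples —
one titrated below pH 6.8 (fully protonated indicator) and one above pH 8.2
(fully deprotonated) — into an apparent pKa:

    pKa_app = pH_stock − log10( (A430_stock − A_acid) / (A_base − A560_stock) )

with A_acid the acid extreme read at 430 nm and A_base the base extreme read
at 560 nm.  Sample pH then follows from

    pH = pKa_app + log10( (R − R_min) / (R_max − R) )

where R_min and R_max are the ratios of the acid and base extremes.

Sign handling: with a two-state indicator the acid extreme *maximizes* the
430-nm absorbance, so the numerator A430_stock − A_acid is negative for any
stock between the extremes and the printed formula has no real logarithm.
``sign_mode="magnitude"`` (default) takes absolute values of both
differences; ``sign_mode="as_printed"`` keeps the literal form and raises a
domain error explaining the sign problem.  See ``calibrate`` for an optional
self-consistent one-point alternative (``method="stock_ratio"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import DegenerateCalibrationError, DomainError, ValidationError
from .spectra import INDICATOR_CEILING, INDICATOR_FLOOR, band_absorbance

ACID_BAND_NM = 430.0
BASE_BAND_NM = 560.0


@dataclass(frozen=True)
class RatioReading:
    """A single ratiometric reading: band absorbances and their ratio."""

    a430: float
    a560: float

    def __post_init__(self) -> None:
        if not self.a430 > 0:
            raise DomainError(
                f"acid band absorbance non-positive (A430 = {self.a430})"
            )
        if not math.isfinite(self.a560 / self.a430):
            raise DomainError("absorbance ratio is not finite")

    @property
    def ratio(self) -> float:
        return self.a560 / self.a430


def absorbance_ratio(a430: float, a560: float) -> float:
    """R = A560 / A430 (dimensionless); requires A430 > 0."""
    return RatioReading(a430=a430, a560=a560).ratio


@dataclass(frozen=True)
class CalibrationSet:
    """Everything the pH formula needs, derived from stock + extreme samples.

    ``a430_base`` (the base extreme read at 430 nm) is retained beyond the
    minimal parameter set so the exact ratiometric correction term
    log10(A430_acid / A430_base) is available to ``ph_from_ratio``'s
    ``corrected`` mode.
    """

    ph_stock: float
    a430_stock: float
    a560_stock: float
    a_acid: float  # acid extreme at 430 nm
    a_base: float  # base extreme at 560 nm
    r_min: float
    r_max: float
    pka_app: float
    sign_mode: str = "magnitude"
    method: str = "two_point"
    a430_base: float | None = None

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValidationError(
                f"R_min ({self.r_min:.4g}) must be < R_max ({self.r_max:.4g}); "
                "are the acid and base traces swapped?"
            )
        if not math.isfinite(self.pka_app):
            raise ValidationError("apparent pKa is not finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSet":
        return cls(**d)


@dataclass(frozen=True)
class PhResult:
    """A computed pH with its indication-range flag.

    ``in_range`` is True iff 6.8 <= pH <= 8.2; outside that window the
    indicator is saturated and the value is reported but unreliable.
    """

    ph: float
    in_range: bool
    r_used: float


def calibrate(
    wavelengths: Sequence[float],
    stock_trace: Sequence[float],
    acid_trace: Sequence[float],
    base_trace: Sequence[float],
    ph_stock: float,
    sign_mode: str = "magnitude",
    method: str = "two_point",
    band_mode: str = "at_nearest",
    half_window: float = 10.0,
) -> CalibrationSet:
    """Build a :class:`CalibrationSet` from stock, acid- and base-extreme traces.

    ``method="two_point"`` (default) computes pKa_app from the stock/extreme
    absorbance differences as printed above, honouring ``sign_mode``.
    ``method="stock_ratio"`` instead inverts the pH formula at the stock point,
    pKa_app = pH_stock − log10((R_stock − R_min)/(R_max − R_stock)); this
    one-point form is exactly self-consistent with the pH computation and is
    offered for users who prioritise absolute accuracy over fidelity to the
    two-point difference formula.
    """

    def bands(trace) -> tuple[float, float]:
        a430 = band_absorbance(wavelengths, trace, ACID_BAND_NM, band_mode, half_window)
        a560 = band_absorbance(wavelengths, trace, BASE_BAND_NM, band_mode, half_window)
        return a430, a560

    a430_stock, a560_stock = bands(stock_trace)
    a430_acid, a560_acid = bands(acid_trace)
    a430_base, a560_base = bands(base_trace)

    a_acid = a430_acid
    a_base = a560_base
    r_min = absorbance_ratio(a430_acid, a560_acid)
    r_max = absorbance_ratio(a430_base, a560_base)
    if not r_min < r_max:
        raise ValidationError(
            f"R_min ({r_min:.4g}) >= R_max ({r_max:.4g}); "
            "are the acid and base traces swapped?"
        )

    if method == "stock_ratio":
        r_stock = absorbance_ratio(a430_stock, a560_stock)
        if not r_min < r_stock < r_max:
            raise DegenerateCalibrationError(
                f"stock ratio {r_stock:.4g} outside (R_min, R_max)"
            )
        pka_app = ph_stock - math.log10((r_stock - r_min) / (r_max - r_stock))
    elif method == "two_point":
        num = a430_stock - a_acid
        den = a_base - a560_stock
        if den == 0.0:
            raise DegenerateCalibrationError(
                "A_base equals the stock 560-nm absorbance; the base extreme "
                "does not saturate the indicator"
            )
        if sign_mode == "as_printed":
            arg = num / den
            if arg <= 0:
                raise DomainError(
                    "the literal difference quotient (A430_stock - A_acid)/"
                    f"(A_base - A560_stock) = {arg:.4g} is non-positive: the "
                    "acid extreme maximizes the 430-nm band, so the numerator "
                    "is negative for any stock between the extremes. Use "
                    "sign_mode='magnitude'."
                )
        elif sign_mode == "magnitude":
            arg = abs(num) / abs(den)
            if arg == 0.0:
                raise DegenerateCalibrationError(
                    "stock and acid extreme coincide at 430 nm"
                )
        else:
            raise ValueError(f"unknown sign_mode {sign_mode!r}")
        pka_app = ph_stock - math.log10(arg)
    else:
        raise ValueError(f"unknown calibration method {method!r}")

    return CalibrationSet(
        ph_stock=ph_stock,
        a430_stock=a430_stock,
        a560_stock=a560_stock,
        a_acid=a_acid,
        a_base=a_base,
        r_min=r_min,
        r_max=r_max,
        pka_app=pka_app,
        sign_mode=sign_mode,
        method=method,
        a430_base=a430_base,
    )


def _effective_pka(cal: CalibrationSet, mode: str) -> float:
    if mode == "paper":
        return cal.pka_app
    if mode == "corrected":
        if cal.a430_base is None or cal.a430_base <= 0:
            raise DegenerateCalibrationError(
                "corrected mode needs the base extreme's 430-nm absorbance"
            )
        return cal.pka_app + math.log10(cal.a_acid / cal.a430_base)
    raise ValueError(f"unknown ph mode {mode!r}")


def ph_from_ratio(r: float, cal: CalibrationSet, mode: str = "paper") -> PhResult:
    """pH from a ratio via pH = pKa_app + log10((R − R_min)/(R_max − R)).

    Requires R strictly inside (R_min, R_max).  Results outside the 6.8–8.2
    indication window are returned with ``in_range=False`` rather than
    clipped, so saturated titration anchors remain plottable.  ``corrected``
    mode adds the extinction-ratio term log10(A430_acid/A430_base) of the
    exact ratiometric closed form.
    """
    if r <= cal.r_min:
        raise DomainError(
            f"below indicator floor: R = {r:.4g} <= R_min = {cal.r_min:.4g} "
            f"(R_max = {cal.r_max:.4g})"
        )
    if r >= cal.r_max:
        raise DomainError(
            f"above indicator ceiling: R = {r:.4g} >= R_max = {cal.r_max:.4g} "
            f"(R_min = {cal.r_min:.4g})"
        )
    ph = _effective_pka(cal, mode) + math.log10((r - cal.r_min) / (cal.r_max - r))
    return PhResult(
        ph=ph,
        in_range=INDICATOR_FLOOR <= ph <= INDICATOR_CEILING,
        r_used=r,
    )


def ratio_from_ph(ph: float, cal: CalibrationSet, mode: str = "paper") -> float:
    """Inverse of :func:`ph_from_ratio`: R = (R_min + R_max·k)/(1 + k) with
    k = 10^(pH − pKa_app).  Total on all finite pH; strictly increasing with
    asymptotes R_min and R_max."""
    k = 10.0 ** (ph - _effective_pka(cal, mode))
    if math.isinf(k):
        return cal.r_max
    return (cal.r_min + cal.r_max * k) / (1.0 + k)
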