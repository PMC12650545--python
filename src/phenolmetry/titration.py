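"""Titration series assembly and measured-vs-calculated agreement.

Each replicate group of a plate becomes one titration step: the group's
traces are averaged, band absorbances extracted, the ratio converted to a
calculated pH, and the glass-probe reference pH (if any) carried alongside.
Agreement between the two is summarised by an ordinary least-squares fit of
calculated on measured pH — the reference instrument on the x-axis, the
standard method-comparison convention — reporting slope, intercept and R².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, DomainError, InsufficientDataError
from .ratiometric import (
    ACID_BAND_NM,
    BASE_BAND_NM,
    CalibrationSet,
    absorbance_ratio,
    ph_from_ratio,
)
from .spectra import PlateSpectra, Titrant, average_replicates, band_absorbance


@dataclass(frozen=True)
class TitrationStep:
    """One pH step of a titration series.

    ``calculated_ph`` is absent when the group's ratio falls outside
    (R_min, R_max) — the indicator is saturated (``saturated=True``) and no
    pH can be assigned.  ``in_range`` mirrors the 6.8–8.2 indication window.
    """

    group: str
    titrant: Titrant | None
    cumulative_volume_ul: float
    measured_ph: float | None
    calculated_ph: float | None
    in_range: bool
    saturated: bool = False
    a430: float | None = None
    a560: float | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.cumulative_volume_ul < 0:
            raise ValueError("cumulative volume must be >= 0")
        if self.measured_ph is None and self.calculated_ph is None:
            raise ValueError("a step needs at least one of measured/calculated pH")


@dataclass(frozen=True)
class AgreementStats:
    """OLS summary of calculated (y) on measured (x) pH."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a reported fit needs n >= 3")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


def build_series(
    plate: PlateSpectra,
    cal: CalibrationSet,
    band_mode: str = "at_nearest",
    half_window: float = 10.0,
    ph_mode: str = "paper",
    include_blanks: bool = False,
) -> list[TitrationStep]:
    """One :class:`TitrationStep` per replicate group, ordered by cumulative
    titrant volume then group label (deterministic in well order).

    Groups whose ratio saturates the indicator are emitted with
    ``calculated_ph=None`` and ``saturated=True`` rather than failing.
    """
    steps: list[TitrationStep] = []
    for group, wells in plate.groups().items():
        metas = [plate.metadata[w] for w in wells]
        if metas[0].role == "blank" and not include_blanks:
            continue
        trace = average_replicates(plate, group)
        a430 = band_absorbance(plate.wavelengths, trace, ACID_BAND_NM, band_mode, half_window)
        a560 = band_absorbance(plate.wavelengths, trace, BASE_BAND_NM, band_mode, half_window)
        ratio = absorbance_ratio(a430, a560)
        refs = [m.reference_ph for m in metas if m.reference_ph is not None]
        measured = float(np.mean(refs)) if refs else None
        titrants = [m.titrant for m in metas if m.titrant is not None]
        titrant = titrants[0] if titrants else None
        volume = max((t.volume_ul for t in titrants), default=0.0)
        try:
            res = ph_from_ratio(ratio, cal, mode=ph_mode)
            calculated, in_range, saturated = res.ph, res.in_range, False
        except DomainError:
            calculated, in_range, saturated = None, False, True
        steps.append(
            TitrationStep(
                group=group,
                titrant=titrant,
                cumulative_volume_ul=volume,
                measured_ph=measured,
                calculated_ph=calculated,
                in_range=in_range,
                saturated=saturated,
                a430=a430,
                a560=a560,
                ratio=ratio,
            )
        )
    steps.sort(key=lambda s: (s.cumulative_volume_ul, s.group))
    return steps


def agreement(
    series: Iterable[TitrationStep],
    include_saturated: bool = False,
    in_range_only: bool = True,
) -> AgreementStats:
    """OLS of calculated on measured pH across a titration series.

    Saturated steps (no calculated pH) and, by default, steps whose
    calculated pH falls outside the 6.8–8.2 indication window are excluded:
    the indicator is uninformative there.
    """
    xs, ys = [], []
    for step in series:
        if step.measured_ph is None or step.calculated_ph is None:
            if not include_saturated or step.calculated_ph is None:
                continue
        if in_range_only and not step.in_range:
            continue
        xs.append(step.measured_ph)
        ys.append(step.calculated_ph)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"only {len(xs)} usable steps with both measured and calculated pH; "
            "need >= 3"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in measured pH")
    fit = stats.linregress(x, y)
    return AgreementStats(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(xs),
    )
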