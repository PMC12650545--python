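"""Synthetic phenol-red spectra from a two-state Beer–Lambert band model.

Each protonation state contributes one Gaussian band: the protonated (acid,
yellow) form centred at 430 nm and the deprotonated (base, red/purple) form
at 560 nm.  Henderson–Hasselbalch speciation mixes the two:

    A(λ) = s · [ (1 − α)·a_acid·g(λ; 430, σ_a) + α·a_base·g(λ; 560, σ_b) ]
           + baseline + ε(λ),     α = 1 / (1 + 10^(pKa − pH))

with g a unit-height Gaussian, s a dye-amount/path-length surrogate and ε
i.i.d. additive instrument noise.  The base-band amplitude default is pinned
so the two bands cross at exactly 480.0 nm, giving the model a true
isosbestic point there; the resulting acid:base amplitude ratio (~1:2.22) is
consistent with phenol red's stronger basic band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .spectra import (
    INDICATOR_CEILING,
    INDICATOR_FLOOR,
    PlateSpectra,
    Titrant,
    WellMeta,
    write_plate as _write_plate_files,
)

ISOSBESTIC_NM = 480.0


def _gauss(lam: np.ndarray | float, center: float, sigma: float):
    lam = np.asarray(lam, dtype=float)
    return np.exp(-((lam - center) ** 2) / (2.0 * sigma**2))


def pinned_base_amp(
    acid_center: float = 430.0,
    base_center: float = 560.0,
    acid_sigma: float = 40.0,
    base_sigma: float = 45.0,
    acid_amp: float = 1.0,
    crossing: float = ISOSBESTIC_NM,
) -> float:
    """Base-band amplitude that makes the two bands cross at ``crossing``.

    Solves acid_amp·g(crossing; acid) = base_amp·g(crossing; base); for the
    defaults this is ≈ 2.2233.
    """
    return acid_amp * float(
        _gauss(crossing, acid_center, acid_sigma)
        / _gauss(crossing, base_center, base_sigma)
    )


#: default base-band amplitude (exact isosbestic pinning at 480.0 nm)
DEFAULT_BASE_AMP = pinned_base_amp()


def base_fraction(ph: float, pka_true: float) -> float:
    """Deprotonated fraction α = 1/(1 + 10^(pKa − pH))."""
    return 1.0 / (1.0 + 10.0 ** (pka_true - ph))


@dataclass(frozen=True)
class PhenolRedBandModel:
    """Parameters of the synthetic two-state spectral model.

    ``dye_scale`` multiplies both bands (concentration × path length
    surrogate); ``noise_sd`` is the additive, homoscedastic, per-wavelength
    instrument noise in AU (0 gives the deterministic model).  ``pKa_true``
    defaults to 7.5, the midpoint of the phenol-red indication range.
    """

    acid_center: float = 430.0
    base_center: float = 560.0
    acid_sigma: float = 40.0
    base_sigma: float = 45.0
    acid_amp: float = 1.0
    base_amp: float = DEFAULT_BASE_AMP
    pka_true: float = 7.5
    dye_scale: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 0.002
    seed: int = 42

    def __post_init__(self) -> None:
        if self.acid_sigma <= 0 or self.base_sigma <= 0:
            raise ValueError("band sigmas must be positive")
        if self.acid_amp <= 0 or self.base_amp <= 0:
            raise ValueError("band amplitudes must be positive")
        if not self.acid_center < self.base_center:
            raise ValueError("acid band must be blue of the base band")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_grid(step: float = 1.0) -> np.ndarray:
    """The instrument span used throughout: 300–800 nm."""
    n = int(round((800.0 - 300.0) / step))
    return 300.0 + step * np.arange(n + 1)


def spectrum(
    model: PhenolRedBandModel,
    ph: float,
    wavelengths: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Absorbance trace of the model at one pH.

    With ``noise_sd > 0`` noise is drawn from ``rng`` (or a fresh generator
    seeded with ``model.seed`` if none is given); pass the same generator for
    sequential wells of one simulated plate.
    """
    lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    alpha = base_fraction(ph, model.pka_true)
    clean = model.dye_scale * (
        (1.0 - alpha) * model.acid_amp * _gauss(lam, model.acid_center, model.acid_sigma)
        + alpha * model.base_amp * _gauss(lam, model.base_center, model.base_sigma)
    ) + model.baseline
    if model.noise_sd > 0:
        if rng is None:
            rng = model.rng()
        clean = clean + rng.normal(0.0, model.noise_sd, size=lam.shape)
    return clean


def _role_for(ph: float, stock_ph: float | None) -> str:
    if stock_ph is not None and ph == stock_ph:
        return "stock"
    if ph < INDICATOR_FLOOR:
        return "acid_extreme"
    if ph > INDICATOR_CEILING:
        return "base_extreme"
    return "step"


def plate_from_model(
    model: PhenolRedBandModel,
    ph_steps: Sequence[float],
    replicates: int = 3,
    stock_ph: float | None = None,
    grid_step: float = 1.0,
) -> PlateSpectra:
    """Simulate a whole plate: ``replicates`` wells per pH step.

    Roles are auto-assigned (acid_extreme below 6.8, base_extreme above 8.2,
    stock for the step equal to ``stock_ph``, step otherwise) and
    ``reference_ph`` carries the generator's true pH, playing the part of the
    glass-probe reading.  Deterministic for a fixed model seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lam = default_grid(grid_step)
    rng = model.rng()
    traces: dict[str, np.ndarray] = {}
    metadata: dict[str, WellMeta] = {}
    for i, ph in enumerate(ph_steps):
        group = f"ph{ph:.2f}"
        role = _role_for(ph, stock_ph)
        for r in range(replicates):
            well = f"W{i + 1:02d}R{r + 1}"
            traces[well] = spectrum(model, ph, lam, rng)
            metadata[well] = WellMeta(
                sample_label=group,
                role=role,
                replicate_group=group,
                reference_ph=float(ph),
            )
    tol = -np.inf if model.noise_sd > 0 else None  # noise may dip below -0.05 tails
    kwargs = {} if tol is None else {"negative_tolerance": tol}
    return PlateSpectra(wavelengths=lam, traces=traces, metadata=metadata, **kwargs)


def write_plate(
    model: PhenolRedBandModel,
    ph_steps: Sequence[float],
    replicates: int,
    plate_path,
    meta_path,
    stock_ph: float | None = None,
    grid_step: float = 1.0,
) -> PlateSpectra:
    """Simulate a plate and persist it as a matrix CSV + metadata sidecar.

    Byte-identical output for identical arguments (the model seed drives all
    randomness).  Returns the in-memory plate for convenience.
    """
    plate = plate_from_model(model, ph_steps, replicates, stock_ph, grid_step)
    _write_plate_files(plate, plate_path, meta_path)
    return plate


def isosbestic_wavelength(
    model: PhenolRedBandModel,
    ph_values: Sequence[float],
    wavelengths: Sequence[float] | None = None,
) -> float:
    """Wavelength minimising the across-pH absorbance standard deviation of
    noiseless model spectra — the empirical isosbestic point."""
    lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    quiet = replace(model, noise_sd=0.0)
    stack = np.stack([spectrum(quiet, ph, lam) for ph in ph_values])
    spread = stack.std(axis=0)
    return float(lam[int(np.argmin(spread))])
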