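"""Mechanistic acid–base chemistry: polyprotic speciation, charge-balance pH
solving, additive ΔpH and strong-titrant dosing.

The solution pH is the unique root of the electroneutrality condition

    0 = Σ strong cations − Σ strong anions
        + Σ_species total · ( counterion charge + Σ_states z_i · f_i(pH) )
        + [H⁺] − Kw/[H⁺]

where f_i are the Henderson–Hasselbalch protonation-state fractions of each
polyprotic species and z_i runs from (max_charge + n_protons) for the fully
protonated form down to max_charge.  Concentration-based equilibria at 25 °C
(Kw = 1e-14); ionic-strength/activity corrections are a documented
limitation.  The net charge is strictly decreasing in pH, so bisection on
[0, 14] always finds the root when one exists.

This models the acidification-and-restoration workflow of enzymatic
dissociation media: reconstituting lyophilized papain introduces L-cysteine
(an activating cofactor, often as the hydrochloride) and EDTA (a polyprotic
chelator), both of which acidify a weakly buffered medium; a µL-scale dose
of concentrated NaOH restores physiological pH.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import InfeasibleRecipeError, ValidationError

KW = 1e-14  # water autoionization constant, 25 degC


@dataclass(frozen=True)
class BufferSpecies:
    """A (poly)protic buffer species as supplied.

    ``max_charge`` is the charge of the fully deprotonated form (e.g. −2 for
    a diprotic acid); ``counterion_charge_added`` encodes the salt form as
    net strong-ion charge per formula unit (free acid 0, mono-sodium +1,
    hydrochloride −1, ...).
    """

    name: str
    total: float  # M
    pkas: tuple[float, ...]
    max_charge: int
    counterion_charge_added: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pkas", tuple(float(p) for p in self.pkas))
        if self.total < 0:
            raise ValidationError(f"{self.name}: total concentration must be >= 0")
        if any(b <= a for a, b in zip(self.pkas, self.pkas[1:])):
            raise ValidationError(f"{self.name}: pKa ladder must be strictly increasing")
        if self.pkas and not all(-2.0 <= p <= 16.0 for p in self.pkas):
            raise ValidationError(f"{self.name}: pKa values must lie within [-2, 16]")


@dataclass(frozen=True)
class SolutionRecipe:
    """A solution: volume, buffer species and net strong (spectator) ions."""

    volume_ml: float
    species: tuple[BufferSpecies, ...] = ()
    strong_cations: float = 0.0  # M, e.g. Na+ from NaOH
    strong_anions: float = 0.0  # M, e.g. Cl- from HCl
    temperature_note: str = "equilibrium constants at 25 degC"

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.volume_ml <= 0:
            raise ValidationError("volume must be positive")
        if self.strong_cations < 0 or self.strong_anions < 0:
            raise ValidationError("strong-ion concentrations must be >= 0")

    def with_additive(self, additive: BufferSpecies) -> "SolutionRecipe":
        """Same solution with one more dissolved species (no volume change)."""
        return replace(self, species=self.species + (additive,))


def species_fractions(pkas: Sequence[float], ph: float) -> np.ndarray:
    """Fractions of the n+1 protonation states of an n-protic acid at a pH.

    Ordered from fully protonated to fully deprotonated; sums to 1.  Computed
    from cumulative log10 dissociation terms with max-subtraction for
    numerical stability.
    """
    pkas = tuple(pkas)
    if any(b <= a for a, b in zip(pkas, pkas[1:])):
        raise ValidationError("pKa ladder must be strictly increasing")
    # log10 weight of state i (i protons removed): sum_{k<=i} (pH - pKa_k)
    logw = np.concatenate([[0.0], np.cumsum([ph - p for p in pkas])])
    logw -= logw.max()
    w = 10.0**logw
    return w / w.sum()


def charge_balance(recipe: SolutionRecipe, ph: float) -> float:
    """Net charge (M) of the solution at a candidate pH; zero at equilibrium."""
    h = 10.0**-ph
    q = recipe.strong_cations - recipe.strong_anions + h - KW / h
    for sp in recipe.species:
        if sp.total == 0.0:
            continue
        q += sp.total * sp.counterion_charge_added
        n = len(sp.pkas)
        if n == 0:
            q += sp.total * sp.max_charge
            continue
        fractions = species_fractions(sp.pkas, ph)
        charges = sp.max_charge + n - np.arange(n + 1)  # protonated -> deprotonated
        q += sp.total * float(np.dot(charges, fractions))
    return q


def solve_ph(
    recipe: SolutionRecipe,
    lo: float = 0.0,
    hi: float = 14.0,
    tol: float = 1e-6,
) -> float:
    """Equilibrium pH by bisection of the charge balance on [lo, hi].

    The balance is strictly decreasing in pH, so a sign change brackets a
    unique root.  Bisection continues well past ``tol`` (to an interval of
    1e-13 pH) so that the residual net charge at the returned pH is at the
    1e-12 M level or below.
    """
    f_lo = charge_balance(recipe, lo)
    f_hi = charge_balance(recipe, hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo < 0 or f_hi > 0:
        raise InfeasibleRecipeError(
            f"charge balance has no sign change on [{lo}, {hi}] "
            f"(f({lo}) = {f_lo:.3g}, f({hi}) = {f_hi:.3g}); "
            "check strong-ion totals and salt forms"
        )
    a, b = lo, hi
    while b - a > min(tol, 1e-13):
        mid = 0.5 * (a + b)
        if charge_balance(recipe, mid) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def delta_ph(base: SolutionRecipe, additive: BufferSpecies) -> float:
    """Signed pH change from dissolving ``additive`` into ``base``."""
    return solve_ph(base.with_additive(additive)) - solve_ph(base)


def titrant_volume_to(
    recipe: SolutionRecipe,
    target_ph: float,
    titrant_molarity: float,
    titrant_sign: int,
    ph_tol: float = 1e-3,
    max_volume_ul: float = 1e8,
) -> float:
    """Smallest titrant volume (µL) that brings the recipe to ``target_ph``.

    ``titrant_sign`` is +1 for a strong base (adds cations, e.g. NaOH) and −1
    for a strong acid (adds anions, e.g. HCl).  Dilution by the added volume
    is accounted for: all recipe concentrations scale by V0/(V0+v).
    """
    if titrant_molarity <= 0:
        raise ValidationError("titrant molarity must be positive")
    if titrant_sign not in (-1, 1):
        raise ValidationError("titrant_sign must be +1 (base) or -1 (acid)")

    def ph_after(v_ul: float) -> float:
        v_ml = v_ul * 1e-3
        total = recipe.volume_ml + v_ml
        dilution = recipe.volume_ml / total
        c_titrant = titrant_molarity * v_ml / total
        diluted = SolutionRecipe(
            volume_ml=total,
            species=tuple(replace(s, total=s.total * dilution) for s in recipe.species),
            strong_cations=recipe.strong_cations * dilution
            + (c_titrant if titrant_sign > 0 else 0.0),
            strong_anions=recipe.strong_anions * dilution
            + (c_titrant if titrant_sign < 0 else 0.0),
            temperature_note=recipe.temperature_note,
        )
        return solve_ph(diluted)

    current = ph_after(0.0)
    if abs(current - target_ph) <= ph_tol:
        return 0.0
    direction = 1 if target_ph > current else -1
    if direction != titrant_sign:
        kind = "base" if titrant_sign > 0 else "acid"
        raise InfeasibleRecipeError(
            f"pH must move from {current:.3f} to {target_ph:.3f} but the "
            f"titrant is a strong {kind}"
        )
    # bracket the target volume by doubling
    hi = 0.5
    while direction * (ph_after(hi) - target_ph) < 0:
        hi *= 2.0
        if hi > max_volume_ul:
            raise InfeasibleRecipeError(
                f"target pH {target_ph} not reachable with {titrant_molarity} M "
                f"titrant within {max_volume_ul} uL"
            )
    lo_v = 0.0
    for _ in range(200):
        mid = 0.5 * (lo_v + hi)
        err = ph_after(mid) - target_ph
        if abs(err) <= ph_tol:
            return mid
        if direction * err < 0:
            lo_v = mid
        else:
            hi = mid
    return 0.5 * (lo_v + hi)


# --- shipped pKa ladders (literature values at 25 degC, editable data) -----

def pka_ladders() -> dict:
    """Shipped reference pKa ladders loaded from package data."""
    text = resources.files("phenolmetry").joinpath("data/pka_ladders.yaml").read_text()
    return yaml.safe_load(text)


def species_from_ladder(
    name: str,
    total: float,
    counterion_charge_added: float = 0.0,
) -> BufferSpecies:
    """Construct a :class:`BufferSpecies` from a shipped ladder by name."""
    ladders = pka_ladders()
    if name not in ladders:
        raise KeyError(f"no shipped pKa ladder named {name!r}; have {sorted(ladders)}")
    entry = ladders[name]
    return BufferSpecies(
        name=name,
        total=total,
        pkas=tuple(entry["pkas"]),
        max_charge=int(entry["max_charge"]),
        counterion_charge_added=counterion_charge_added,
    )


def load_recipe(path) -> SolutionRecipe:
    """Read a recipe config (YAML): volume_ml, species list, strong ions."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    species = tuple(
        BufferSpecies(
            name=s["name"],
            total=float(s["total_M"]),
            pkas=tuple(s["pkas"]),
            max_charge=int(s["max_charge"]),
            counterion_charge_added=float(s.get("counterion_charge_added", 0.0)),
        )
        for s in doc.get("species", [])
    )
    return SolutionRecipe(
        volume_ml=float(doc["volume_ml"]),
        species=species,
        strong_cations=float(doc.get("strong_cations_M", 0.0)),
        strong_anions=float(doc.get("strong_anions_M", 0.0)),
    )
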