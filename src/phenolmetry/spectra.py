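"""Plate-reader absorbance spectra: containers, delimited-text I/O, replicate
averaging and band extraction.

A *plate* is a wide matrix — one wavelength column (nm) plus one absorbance
column (AU) per well — accompanied by a metadata sidecar table mapping each
well to a sample label, role, replicate group and optional glass-probe
reference pH and titrant bookkeeping.

Roles follow the calibration workflow of the ratiometric phenol-red method:
``stock`` (medium at the manufacturer pH), ``acid_extreme`` / ``base_extreme``
(samples titrated past the indication range, pH < 6.8 / > 8.2, used for
R_min / R_max), ``step`` (titration steps) and ``blank``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    LookupErrorPh,
    RangeError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROLES = ("stock", "acid_extreme", "base_extreme", "step", "blank")

#: lower bound of the phenol-red indication range (pH units)
INDICATOR_FLOOR = 6.8
#: upper bound of the phenol-red indication range (pH units)
INDICATOR_CEILING = 8.2

#: most negative absorbance tolerated as instrument baseline noise (AU)
NEGATIVE_TOLERANCE = -0.05

META_COLUMNS = (
    "well",
    "sample_label",
    "role",
    "replicate_group",
    "reference_ph",
    "titrant_name",
    "titrant_molarity_M",
    "titrant_volume_uL",
)


@dataclass(frozen=True)
class Titrant:
    """Identity and strength of a strong titrant applied to a well."""

    name: str
    molarity: float  # M
    volume_ul: float = 0.0  # cumulative volume added, µL


@dataclass(frozen=True)
class WellMeta:
    """Per-well annotation from the metadata sidecar."""

    sample_label: str = ""
    role: str = "step"
    replicate_group: str = ""
    reference_ph: float | None = None
    titrant: Titrant | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r}; expected one of {ROLES}"
            )
        if not self.replicate_group:
            raise ValidationError("replicate_group must be non-empty")
        if self.reference_ph is not None:
            if self.role == "acid_extreme" and not self.reference_ph < INDICATOR_FLOOR:
                raise ValidationError(
                    f"acid_extreme well has reference_ph {self.reference_ph} "
                    f">= {INDICATOR_FLOOR}; the indicator must be saturated acid-side"
                )
            if self.role == "base_extreme" and not self.reference_ph > INDICATOR_CEILING:
                raise ValidationError(
                    f"base_extreme well has reference_ph {self.reference_ph} "
                    f"<= {INDICATOR_CEILING}; the indicator must be saturated base-side"
                )


@dataclass
class PlateSpectra:
    """A wavelength grid with per-well absorbance traces and well metadata.

    Invariants enforced at construction: every trace has one value per
    wavelength; wavelengths are strictly increasing and span [430, 560] nm;
    absorbances are finite and no more negative than ``negative_tolerance``.
    """

    wavelengths: np.ndarray
    traces: dict[str, np.ndarray]
    metadata: dict[str, WellMeta] = field(default_factory=dict)
    negative_tolerance: float = NEGATIVE_TOLERANCE

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValidationError("wavelength grid must be 1-D with >= 2 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.wavelengths[0] > 430.0 or self.wavelengths[-1] < 560.0:
            raise ValidationError(
                "wavelength span must include [430, 560] nm for ratiometric use "
                f"(got {self.wavelengths[0]}-{self.wavelengths[-1]})"
            )
        clean: dict[str, np.ndarray] = {}
        for well, trace in self.traces.items():
            arr = np.asarray(trace, dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise ValidationError(
                    f"well {well!r}: trace length {arr.size} != grid length "
                    f"{self.wavelengths.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"well {well!r}: non-finite absorbance")
            if np.any(arr < self.negative_tolerance):
                raise ValidationError(
                    f"well {well!r}: absorbance below the negative tolerance "
                    f"{self.negative_tolerance} AU"
                )
            clean[well] = arr
        self.traces = clean
        for well in self.traces:
            if well not in self.metadata:
                logger.warning(
                    "well %r has no metadata row; retaining with role='step'", well
                )
                self.metadata[well] = WellMeta(
                    sample_label="", role="step", replicate_group=well
                )

    @property
    def wells(self) -> list[str]:
        return list(self.traces)

    def groups(self) -> dict[str, list[str]]:
        """Replicate group -> member wells (insertion order of the plate)."""
        out: dict[str, list[str]] = {}
        for well in self.traces:
            out.setdefault(self.metadata[well].replicate_group, []).append(well)
        return out

    def baseline_corrected(self, window: tuple[float, float] = (700.0, 800.0)) -> "PlateSpectra":
        """Subtract each well's mean absorbance over ``window`` (default
        700-800 nm, outside both phenol-red bands).  Off the default pipeline;
        opt-in for instruments with a wavelength-flat offset."""
        lo, hi = window
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise RangeError(f"baseline window {window} outside the grid")
        traces = {w: t - t[mask].mean() for w, t in self.traces.items()}
        return PlateSpectra(
            wavelengths=self.wavelengths.copy(),
            traces=traces,
            metadata=dict(self.metadata),
            negative_tolerance=-np.inf,  # correction may push noise below zero
        )


def _parse_optional_float(token: str, where: str) -> float | None:
    token = token.strip()
    if token == "":
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {token!r} in {where}") from exc


def read_metadata(path, sep: str = ",") -> dict[str, WellMeta]:
    """Read the metadata sidecar (one row per well)."""
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"metadata file {path} is empty") from exc
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file {path} missing columns {missing}")
    if df["well"].duplicated().any():
        dupes = sorted(df.loc[df["well"].duplicated(), "well"].unique())
        raise FormatError(f"duplicated well ids in metadata: {dupes}")
    meta: dict[str, WellMeta] = {}
    for _, row in df.iterrows():
        well = row["well"].strip()
        tit_name = row["titrant_name"].strip()
        titrant = None
        if tit_name:
            titrant = Titrant(
                name=tit_name,
                molarity=_parse_optional_float(
                    row["titrant_molarity_M"], f"titrant_molarity_M of well {well}"
                )
                or 0.0,
                volume_ul=_parse_optional_float(
                    row["titrant_volume_uL"], f"titrant_volume_uL of well {well}"
                )
                or 0.0,
            )
        meta[well] = WellMeta(
            sample_label=row["sample_label"].strip(),
            role=row["role"].strip() or "step",
            replicate_group=row["replicate_group"].strip() or well,
            reference_ph=_parse_optional_float(
                row["reference_ph"], f"reference_ph of well {well}"
            ),
            titrant=titrant,
        )
    return meta


def read_plate(path, meta_path=None, sep: str = ",") -> PlateSpectra:
    """Read a wide plate matrix (first column ``wavelength_nm``) plus an
    optional metadata sidecar into a validated :class:`PlateSpectra`.

    Wells present in the matrix but absent from the metadata are retained
    with role ``step`` and an empty label (a warning is logged).
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"plate file {path} is empty") from exc
    if df.shape[1] < 2:
        raise SchemaError(f"plate file {path} needs a wavelength column plus wells")
    first = df.columns[0]
    if first != "wavelength_nm":
        raise FormatError(
            f"first column of {path} must be 'wavelength_nm', got {first!r}"
        )
    # pandas mangles duplicate headers, so inspect the raw header line
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [h.strip() for h in line.rstrip("\n").split(sep)]
                break
    wells_in_header = header[1:]
    seen: set[str] = set()
    for w in wells_in_header:
        if w in seen:
            raise FormatError(f"duplicated well id {w!r} in {path}")
        seen.add(w)

    def column(name: str) -> np.ndarray:
        raw = df[name].to_numpy()
        try:
            # numpy's strtod is exact to the last ulp, unlike pandas' fast parser
            return raw.astype(np.float64)
        except ValueError:
            bad = pd.to_numeric(df[name], errors="coerce").isna()
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header line
            raise FormatError(
                f"non-numeric absorbance cell at row {row}, column {name!r} of {path}"
            ) from None

    wavelengths = column(first)
    if not np.all(np.diff(wavelengths) > 0):
        raise FormatError(f"wavelength column of {path} is not strictly increasing")
    traces = {w: column(w) for w in wells_in_header}
    metadata = read_metadata(meta_path, sep=sep) if meta_path is not None else {}
    return PlateSpectra(wavelengths=wavelengths, traces=traces, metadata=metadata)


def write_plate(plate: PlateSpectra, path, meta_path=None, sep: str = ",") -> None:
    """Write a plate (and optionally its metadata) back to delimited text.

    Floats are written with shortest round-trip repr, so ``read_plate`` after
    ``write_plate`` reproduces the object exactly.
    """
    cols = {"wavelength_nm": plate.wavelengths}
    cols.update(plate.traces)
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")
    if meta_path is not None:
        rows = []
        for well, m in plate.metadata.items():
            rows.append(
                {
                    "well": well,
                    "sample_label": m.sample_label,
                    "role": m.role,
                    "replicate_group": m.replicate_group,
                    "reference_ph": "" if m.reference_ph is None else m.reference_ph,
                    "titrant_name": "" if m.titrant is None else m.titrant.name,
                    "titrant_molarity_M": "" if m.titrant is None else m.titrant.molarity,
                    "titrant_volume_uL": "" if m.titrant is None else m.titrant.volume_ul,
                }
            )
        pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(
            meta_path, sep=sep, index=False
        )


def average_replicates(plate: PlateSpectra, group: str) -> np.ndarray:
    """Pointwise arithmetic mean of all traces in a replicate group.

    All member wells must share a role; a one-well group returns that trace.
    """
    wells = [w for w in plate.traces if plate.metadata[w].replicate_group == group]
    if not wells:
        raise LookupErrorPh(f"no wells in replicate group {group!r}")
    roles = {plate.metadata[w].role for w in wells}
    if len(roles) > 1:
        raise ValidationError(
            f"replicate group {group!r} mixes roles {sorted(roles)}"
        )
    return np.mean([plate.traces[w] for w in wells], axis=0)


def band_absorbance(
    wavelengths: Sequence[float],
    trace: Sequence[float],
    nominal: float,
    mode: str = "at_nearest",
    half_window: float = 10.0,
) -> float:
    """Absorbance of a trace at (or near) a nominal band wavelength.

    ``at_nearest`` reads the grid point closest to ``nominal`` (ties resolve
    to the lower wavelength); ``window_max`` takes the maximum within
    ``nominal ± half_window`` for coarse grids where the peak may fall between
    grid points.
    """
    wl = np.asarray(wavelengths, dtype=float)
    tr = np.asarray(trace, dtype=float)
    if not (wl[0] <= nominal <= wl[-1]):
        raise RangeError(
            f"nominal wavelength {nominal} nm outside grid span "
            f"[{wl[0]}, {wl[-1]}]"
        )
    if mode == "at_nearest":
        # argmin returns the first (lower-wavelength) index on ties
        idx = int(np.argmin(np.abs(wl - nominal)))
        return float(tr[idx])
    if mode == "window_max":
        mask = np.abs(wl - nominal) <= half_window
        return float(tr[mask].max())
    raise ValueError(f"unknown band-extraction mode {mode!r}")
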