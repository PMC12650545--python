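"""Reporting-completeness auditing of tissue-dissociation protocol surveys.

Ingests a survey table — one row per publication, fifteen protocol columns —
coded with the tri-state convention: a bare ``x``/``X`` means the parameter
was *not reported*, ``N/A`` means the information is *not available* (broken
links, discontinued products), ``Use`` records use of a reagent, ``yes``
(optionally with a value in parentheses) records explicit reporting, and any
other non-empty token is the reported value itself.  Numeric ranges such as
``15–20`` or ``E16–E17`` parse to (low, high); en dash, hyphen and minus are
treated alike.

The auditor aggregates per-field completeness percentages (denominator =
number of records), the tissue-source species distribution, incubation
temperature and animal-age breakdowns, and per-study *digestion units* — the
product of enzymatic activity units and incubation minutes, with the
midpoint taken for any reported range.

The shipped fixture ``data/table2_survey.csv`` is a verbatim transcription
of a 50-publication survey of papain-based primary-neuron dissociation
protocols (2009–2024).
"""

from __future__ import annotations

import importlib.resources as resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, InsufficientDataError, LookupErrorPh, SchemaError

SURVEY_COLUMNS = (
    "ref_id",
    "year",
    "citations",
    "source",
    "region",
    "age",
    "mg_per_ml",
    "media",
    "units",
    "minutes",
    "temp_c",
    "manufacturer",
    "catalog",
    "ph",
    "lcys",
    "dnase",
)

SPECIES = ("mouse", "rat", "mouse_and_rat", "human")

_DASHES = "–—−-"  # en dash, em dash, minus, hyphen
_RANGE_RE = re.compile(
    rf"^\s*(\d+(?:\.\d+)?)\s*[{_DASHES}]\s*(\d+(?:\.\d+)?)\s*$"
)
_NUMBER_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class Cell:
    """One parsed survey cell: tri-state coding plus any numeric content.

    ``state`` is one of ``reported``, ``use`` (reagent-use record, counts as
    reported), ``not_reported`` and ``not_available``.  ``value``/``bounds``
    are filled when the token is a number or a numeric range.
    """

    raw: str
    state: str
    value: float | None = None
    bounds: tuple[float, float] | None = None

    @property
    def reported(self) -> bool:
        return self.state in ("reported", "use")

    @property
    def midpoint(self) -> float | None:
        if self.bounds is not None:
            return 0.5 * (self.bounds[0] + self.bounds[1])
        return self.value


def parse_cell(token: str) -> Cell:
    raw = token.strip()
    low = raw.lower()
    if low in ("", "x"):
        return Cell(raw=raw, state="not_reported")
    if low == "n/a":
        return Cell(raw=raw, state="not_available")
    if low == "use":
        return Cell(raw=raw, state="use")
    if low.startswith("yes"):
        m = re.search(r"\(([\d.]+)\)", raw)
        return Cell(
            raw=raw,
            state="reported",
            value=float(m.group(1)) if m else None,
        )
    # strip unit words ("mo.", "weeks") and stage letters (E17, P1) before
    # attempting numeric parsing, so "E16–E17" reads as the range 16-17
    numeric = re.sub(r"[A-Za-z.\s]+$", "", raw)
    numeric = re.sub(r"[A-Za-z\s]+", "", numeric)
    m = _RANGE_RE.match(numeric)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if lo > hi:
            raise FormatError(f"range {raw!r} has low > high")
        return Cell(raw=raw, state="reported", bounds=(lo, hi))
    m = _NUMBER_RE.match(numeric)
    if m:
        return Cell(raw=raw, state="reported", value=float(m.group(1)))
    return Cell(raw=raw, state="reported")


def _parse_species(token: str, row: int) -> str:
    canon = re.sub(r"\s+", " ", token.strip().lower())
    mapping = {
        "mouse": "mouse",
        "rat": "rat",
        "mouse & rat": "mouse_and_rat",
        "mouse and rat": "mouse_and_rat",
        "human": "human",
    }
    if canon not in mapping:
        raise FormatError(f"unknown species token {token!r} at row {row}")
    return mapping[canon]


@dataclass(frozen=True)
class ProtocolRecord:
    """One publication's dissociation-protocol reporting row."""

    ref_id: str
    year: int
    citations: int
    source_species: str
    region: Cell
    age: Cell
    conc_mg_per_ml: Cell
    media: Cell
    activity_units: Cell
    minutes: Cell
    temp_c: Cell
    manufacturer: Cell
    catalog: Cell
    ph: Cell
    lcys: Cell
    dnase: Cell

    def __post_init__(self) -> None:
        if not 2009 <= self.year <= 2024:
            raise FormatError(
                f"ref {self.ref_id}: year {self.year} outside the surveyed "
                "window 2009-2024"
            )
        if self.source_species not in SPECIES:
            raise FormatError(
                f"ref {self.ref_id}: bad species {self.source_species!r}"
            )


#: audit field name -> ProtocolRecord attribute holding its Cell
FIELDS = {
    "region": "region",
    "age": "age",
    "mg_per_ml": "conc_mg_per_ml",
    "media": "media",
    "units": "activity_units",
    "minutes": "minutes",
    "temp_c": "temp_c",
    "manufacturer": "manufacturer",
    "catalog": "catalog",
    "ph": "ph",
    "lcys": "lcys",
    "dnase": "dnase",
}


def parse_survey(path) -> list[ProtocolRecord]:
    """Parse a survey table (CSV in the 15-column schema) into records."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"survey file {path} is empty") from exc
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey file {path} missing columns {missing}")
    if df.empty:
        raise SchemaError(f"survey file {path} has a header but no rows")
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header
        try:
            year = int(row["year"])
            citations = int(row["citations"])
        except ValueError as exc:
            raise FormatError(f"non-integer year/citations at row {rownum}") from exc
        records.append(
            ProtocolRecord(
                ref_id=row["ref_id"].strip(),
                year=year,
                citations=citations,
                source_species=_parse_species(row["source"], rownum),
                region=parse_cell(row["region"]),
                age=parse_cell(row["age"]),
                conc_mg_per_ml=parse_cell(row["mg_per_ml"]),
                media=parse_cell(row["media"]),
                activity_units=parse_cell(row["units"]),
                minutes=parse_cell(row["minutes"]),
                temp_c=parse_cell(row["temp_c"]),
                manufacturer=parse_cell(row["manufacturer"]),
                catalog=parse_cell(row["catalog"]),
                ph=parse_cell(row["ph"]),
                lcys=parse_cell(row["lcys"]),
                dnase=parse_cell(row["dnase"]),
            )
        )
    return records


_SOURCE_LABELS = {
    "mouse": "Mouse",
    "rat": "Rat",
    "mouse_and_rat": "Mouse & Rat",
    "human": "Human",
}


def serialize_survey(records: Iterable[ProtocolRecord], path) -> None:
    """Write records back to the survey schema (raw tokens preserved, so
    parse -> serialize -> parse is the identity)."""
    rows = []
    for r in records:
        rows.append(
            {
                "ref_id": r.ref_id,
                "year": r.year,
                "citations": r.citations,
                "source": _SOURCE_LABELS[r.source_species],
                "region": r.region.raw,
                "age": r.age.raw,
                "mg_per_ml": r.conc_mg_per_ml.raw,
                "media": r.media.raw,
                "units": r.activity_units.raw,
                "minutes": r.minutes.raw,
                "temp_c": r.temp_c.raw,
                "manufacturer": r.manufacturer.raw,
                "catalog": r.catalog.raw,
                "ph": r.ph.raw,
                "lcys": r.lcys.raw,
                "dnase": r.dnase.raw,
            }
        )
    pd.DataFrame(rows, columns=list(SURVEY_COLUMNS)).to_csv(path, index=False)


@dataclass(frozen=True)
class Completeness:
    """Tri-state counts for one field plus percentages over all records.

    ``pct_not_reported`` is the complement of ``pct_reported`` — a parameter
    that is "not available" is still unreported from the reader's viewpoint,
    which is how survey prose usually phrases it; the separate
    ``not_available`` count keeps the distinction."""

    field: str
    reported: int
    not_reported: int
    not_available: int

    @property
    def n(self) -> int:
        return self.reported + self.not_reported + self.not_available

    @property
    def pct_reported(self) -> float:
        return 100.0 * self.reported / self.n

    @property
    def pct_not_reported(self) -> float:
        return 100.0 - self.pct_reported

    @property
    def pct_not_available(self) -> float:
        return 100.0 * self.not_available / self.n


def _cells_for(records: Sequence[ProtocolRecord], field_name: str) -> list[Cell]:
    attr = FIELDS[field_name]
    return [getattr(r, attr) for r in records]


def completeness(records: Sequence[ProtocolRecord], field_name: str) -> Completeness:
    """Tri-state counts and percentage reported for one field.

    The composite field ``concentration`` counts a record as reported when
    *either* the mg/mL concentration *or* the activity units are reported —
    the two interchangeable ways the literature quantifies enzyme amount.
    """
    if not records:
        raise InsufficientDataError("no records")
    if field_name == "concentration":
        reported = not_available = not_reported = 0
        for r in records:
            pair = (r.conc_mg_per_ml, r.activity_units)
            if any(c.reported for c in pair):
                reported += 1
            elif any(c.state == "not_available" for c in pair):
                not_available += 1
            else:
                not_reported += 1
        return Completeness("concentration", reported, not_reported, not_available)
    if field_name not in FIELDS:
        raise LookupErrorPh(
            f"unknown field {field_name!r}; expected one of "
            f"{sorted(FIELDS) + ['concentration']}"
        )
    cells = _cells_for(records, field_name)
    reported = sum(c.reported for c in cells)
    not_available = sum(c.state == "not_available" for c in cells)
    return Completeness(
        field_name, reported, len(cells) - reported - not_available, not_available
    )


def species_distribution(records: Sequence[ProtocolRecord]) -> dict[str, float]:
    """Percentage of records per source species (sums to 100)."""
    if not records:
        raise InsufficientDataError("no records")
    out = {}
    for sp in SPECIES:
        out[sp] = 100.0 * sum(r.source_species == sp for r in records) / len(records)
    return out


def digestion_units(record: ProtocolRecord) -> float | None:
    """Activity units x incubation minutes (midpoint of any range), or None
    when either factor is unreported or non-numeric."""
    u = record.activity_units.midpoint if record.activity_units.reported else None
    m = record.minutes.midpoint if record.minutes.reported else None
    if u is None or m is None:
        return None
    return u * m


def _age_category(cell: Cell) -> str:
    if cell.state == "not_available":
        return "not_available"
    if not cell.reported or cell.raw.upper() == "X":
        return "not_reported"
    raw = cell.raw
    if re.search(r"week|mo\.", raw, re.IGNORECASE):
        return "one_week_or_older"
    if re.search(r"E\s*\d", raw):
        return "embryonic"
    if re.search(r"P\s*\d", raw):
        nums = [float(x) for x in re.findall(r"\d+(?:\.\d+)?", raw)]
        return "early_postnatal" if max(nums, default=0) <= 6 else "one_week_or_older"
    return "other"


@dataclass
class AuditSummary:
    """Aggregated completeness, distributions and digestion units."""

    n_records: int
    fields: dict[str, Completeness]
    species_pct: dict[str, float]
    temperature_counts: dict[float, int]
    age_counts: dict[str, int]
    digestion_units_by_ref: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "fields": {
                name: {
                    "reported": c.reported,
                    "not_reported": c.not_reported,
                    "not_available": c.not_available,
                    "pct_reported": c.pct_reported,
                    "pct_not_reported": c.pct_not_reported,
                }
                for name, c in self.fields.items()
            },
            "species_pct": self.species_pct,
            "temperature_counts": {
                str(k): v for k, v in self.temperature_counts.items()
            },
            "age_counts": self.age_counts,
            "digestion_units_by_ref": self.digestion_units_by_ref,
        }

    def render_markdown(self) -> str:
        lines = [
            f"# Protocol reporting audit ({self.n_records} records)",
            "",
            "| field | reported | not reported | N/A | % reported |",
            "|---|---|---|---|---|",
        ]
        for name, c in self.fields.items():
            lines.append(
                f"| {name} | {c.reported} | {c.not_reported} | "
                f"{c.not_available} | {c.pct_reported:.0f}% |"
            )
        lines += ["", "## Source species", ""]
        for sp, pct in self.species_pct.items():
            lines.append(f"- {_SOURCE_LABELS[sp]}: {pct:.0f}%")
        lines += ["", "## Digestion units (activity units x minutes)", ""]
        for ref, du in self.digestion_units_by_ref.items():
            lines.append(f"- ref {ref}: {du:g}")
        return "\n".join(lines) + "\n"


def audit_report(records: Sequence[ProtocolRecord]) -> AuditSummary:
    """Full audit: every schema field plus the composite concentration field,
    species distribution, temperature/age breakdowns and digestion units."""
    if not records:
        raise InsufficientDataError("no records")
    fields = {name: completeness(records, name) for name in FIELDS}
    fields["concentration"] = completeness(records, "concentration")
    temp_counts: dict[float, int] = {}
    for r in records:
        t = r.temp_c.midpoint
        if r.temp_c.reported and t is not None:
            temp_counts[t] = temp_counts.get(t, 0) + 1
    age_counts: dict[str, int] = {}
    for r in records:
        cat = _age_category(r.age)
        age_counts[cat] = age_counts.get(cat, 0) + 1
    du = {
        r.ref_id: digestion_units(r)
        for r in records
        if digestion_units(r) is not None
    }
    return AuditSummary(
        n_records=len(records),
        fields=fields,
        species_pct=species_distribution(records),
        temperature_counts=dict(sorted(temp_counts.items())),
        age_counts=age_counts,
        digestion_units_by_ref=du,
    )


def packaged_survey_path():
    """Path to the shipped 50-publication survey fixture."""
    return resources.files("phenolmetry").joinpath("data/table2_survey.csv")
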