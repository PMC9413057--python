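"""Domain records, table readers/writers and the bundled real-world cohort.

Every analysis stage consumes one of five flat-table record types:
per-field TIL densities, segmented MIF cells, candidate somatic variants,
TCR clonotypes, and real-world patient outcomes.  Readers accept TSV or
CSV (delimiter sniffed from the header line), validate every row and
report errors with 1-based row numbers; writers emit TSV.

The 46-patient real-world adenosquamous-carcinoma cohort ships with the
package as ``data/table2.tsv`` and loads through
:func:`load_table2_fixture`.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Component",
    "Region",
    "Treatment",
    "TreatmentLine",
    "BestResponse",
    "KNOWN_MARKERS",
    "TpsValue",
    "TILFieldMeasurement",
    "CellRecord",
    "VariantCall",
    "CloneRecord",
    "PatientOutcome",
    "SchemaError",
    "ValidationError",
    "read_table",
    "write_table",
    "read_vcf_variants",
    "load_table2_fixture",
    "Thresholds",
    "load_config",
]


class SchemaError(ValueError):
    """A table's header does not match the expected schema."""


class ValidationError(ValueError):
    """A table row violates a record invariant; message carries the row number."""


class Component(str, enum.Enum):
    """Histological component of an adenosquamous tumor."""

    ACC = "ACC"
    SCCC = "SCCC"


class Region(str, enum.Enum):
    TUMOR = "tumor"
    STROMA = "stroma"


class Treatment(str, enum.Enum):
    MONO_ICI = "mono_ici"
    CHEMO_ICI = "chemo_ici"


class TreatmentLine(str, enum.Enum):
    FIRST = "first"
    SECOND = "second"
    THIRD_PLUS = "third_plus"


class BestResponse(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


#: Markers stainable in the two multiplex-immunofluorescence panels.
KNOWN_MARKERS = (
    "CD3", "CD4", "CD8", "CD57", "CD68", "CD163",
    "FOXP3", "PD1", "PDL1", "TIM3", "LAG3",
)


@dataclass(frozen=True)
class TpsValue:
    """PD-L1 tumor proportion score with its reporting qualifier.

    Clinical reports print censored scores such as ``<1%`` or ``>=50%``.
    These parse to a representative numeric value (0.5 and 50) plus a
    qualifier so that threshold subgrouping stays faithful to the report:
    ``<1%`` is negative at the 1% cut, ``>=50%`` is positive at the 50% cut.
    """

    value: float
    qualifier: str = "exact"  # one of: exact, lt, ge

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValidationError(f"TPS value {self.value} outside [0, 100]")
        if self.qualifier not in ("exact", "lt", "ge"):
            raise ValidationError(f"unknown TPS qualifier {self.qualifier!r}")

    def is_at_least(self, cutoff: float) -> bool:
        """Qualifier-aware threshold test used for PD-L1 positivity."""
        return self.value >= cutoff

    @classmethod
    def parse(cls, token: str) -> "TpsValue":
        tok = token.strip().rstrip("%").replace("≥", ">=").replace("≤", "<=")
        if tok.startswith("<"):
            bound = float(tok.lstrip("<="))
            return cls(value=bound / 2.0, qualifier="lt")
        if tok.startswith(">="):
            return cls(value=float(tok[2:]), qualifier="ge")
        if tok.startswith(">"):
            return cls(value=float(tok[1:]), qualifier="ge")
        return cls(value=float(tok), qualifier="exact")

    def __str__(self) -> str:
        if self.qualifier == "lt":
            return f"<{self.value * 2:g}%"
        if self.qualifier == "ge":
            return f">={self.value:g}%"
        return f"{self.value:g}%"


def _check_percent(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 100.0) or math.isnan(value):
        raise ValidationError(f"{name} = {value} outside [0, 100]")
    return value


@dataclass(frozen=True)
class TILFieldMeasurement:
    """One microscope field's intratumoral and stromal lymphocyte densities (%)."""

    sample_id: str
    component: Component
    field_index: int
    intratumoral_density: float
    stromal_density: float

    def __post_init__(self) -> None:
        if self.field_index < 1:
            raise ValidationError(f"field_index {self.field_index} must be >= 1")
        _check_percent("intratumoral_density", self.intratumoral_density)
        _check_percent("stromal_density", self.stromal_density)


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell with its region label and marker-positivity flags."""

    sample_id: str
    component: Component
    cell_id: str
    x: float
    y: float
    region: Region
    markers: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.markers) - set(KNOWN_MARKERS)
        if unknown:
            raise ValidationError(f"unknown marker name(s): {sorted(unknown)}")

    def positive(self, marker: str) -> bool:
        if marker not in KNOWN_MARKERS:
            raise ValidationError(f"unknown marker name: {marker}")
        return bool(self.markers.get(marker, False))


@dataclass(frozen=True)
class VariantCall:
    """A candidate somatic mutation (1-based, inclusive VCF-style coordinates).

    ``hq_support_reads`` is the count of supporting reads with base quality
    Phred >= 30 and mapping quality >= 30; ``pe_bias`` flags paired-end read
    bias.  Both arrive pre-aggregated from upstream variant calling.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    hq_support_reads: int
    consequence: str  # nonsynonymous | synonymous | other
    pe_bias: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos {self.pos} must be >= 1")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf {self.vaf} outside [0, 1]")
        if self.hq_support_reads < 0:
            raise ValidationError("hq_support_reads must be >= 0")
        if self.consequence not in ("nonsynonymous", "synonymous", "other"):
            raise ValidationError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key: the same locus/allele pair is one mutation."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CloneRecord:
    """One TCR-beta CDR3 clonotype with template abundance."""

    cdr3: str
    count: int
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.cdr3:
            raise ValidationError("cdr3 must be non-empty")
        if self.count < 1:
            raise ValidationError(f"count {self.count} must be >= 1")


@dataclass(frozen=True)
class PatientOutcome:
    """One real-world ICI-treated patient with response and survival endpoints."""

    patient_id: str
    center: str
    sex: str
    age: float
    driver_status: str | None  # gene annotation, "Wild type", or None = unknown
    pdl1_tps: TpsValue | None  # None = not assessed
    treatment: Treatment
    line: TreatmentLine
    best_response: BestResponse
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValidationError(
                f"{self.patient_id}: survival times must be >= 0"
            )


# --------------------------------------------------------------------------
# Tabular serialization
# --------------------------------------------------------------------------

_TREATMENT_TOKENS = {
    "immunotherapy": Treatment.MONO_ICI,
    "mono_ici": Treatment.MONO_ICI,
    "immunotherapy+chemotherapy": Treatment.CHEMO_ICI,
    "chemo_ici": Treatment.CHEMO_ICI,
}
_LINE_TOKENS = {
    "1": TreatmentLine.FIRST,
    "first": TreatmentLine.FIRST,
    "2": TreatmentLine.SECOND,
    "second": TreatmentLine.SECOND,
    ">=3": TreatmentLine.THIRD_PLUS,
    "≥3": TreatmentLine.THIRD_PLUS,
    "3": TreatmentLine.THIRD_PLUS,
    "third_plus": TreatmentLine.THIRD_PLUS,
}
_NA_TOKENS = {"", "na", "nan", "none", "unknown"}
_BOOL_TOKENS = {
    "1": True, "true": True, "yes": True,
    "0": False, "false": False, "no": False,
}


def _parse_bool(token: str, row: int, col: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValidationError(f"row {row}: {col}={token!r} is not a boolean") from None


def _parse_enum(token: str, mapping: Mapping[str, object], row: int, col: str):
    try:
        return mapping[token.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"row {row}: unknown {col} token {token!r}"
        ) from None


def _til_from_row(row: Mapping[str, str], rownum: int) -> TILFieldMeasurement:
    return TILFieldMeasurement(
        sample_id=row["sample_id"],
        component=_parse_enum(
            row["component"], {"acc": Component.ACC, "sccc": Component.SCCC},
            rownum, "component"),
        field_index=int(row["field_index"]),
        intratumoral_density=float(row["intratumoral_density"]),
        stromal_density=float(row["stromal_density"]),
    )


def _cell_from_row(row: Mapping[str, str], rownum: int) -> CellRecord:
    markers = {
        m: _parse_bool(row[m.lower()], rownum, m)
        for m in KNOWN_MARKERS if m.lower() in row
    }
    return CellRecord(
        sample_id=row["sample_id"],
        component=_parse_enum(
            row["component"], {"acc": Component.ACC, "sccc": Component.SCCC},
            rownum, "component"),
        cell_id=row["cell_id"],
        x=float(row["x"]),
        y=float(row["y"]),
        region=_parse_enum(
            row["region"], {"tumor": Region.TUMOR, "stroma": Region.STROMA},
            rownum, "region"),
        markers=markers,
    )


def _variant_from_row(row: Mapping[str, str], rownum: int) -> VariantCall:
    return VariantCall(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        vaf=float(row["vaf"]),
        hq_support_reads=int(row["hq_support_reads"]),
        consequence=row["consequence"].strip().lower(),
        pe_bias=_parse_bool(row.get("pe_bias", "0"), rownum, "pe_bias"),
    )


def _clone_from_row(row: Mapping[str, str], rownum: int) -> CloneRecord:
    return CloneRecord(
        cdr3=row["cdr3"],
        count=int(row["count"]),
        productive=_parse_bool(row["productive"], rownum, "productive"),
    )


def _patient_from_row(row: Mapping[str, str], rownum: int) -> PatientOutcome:
    driver = row["driver_status"].strip()
    tps_token = row["pdl1_tps"].strip()
    return PatientOutcome(
        patient_id=row["patient_id"],
        center=row["center"],
        sex=row["sex"],
        age=float(row["age"]),
        driver_status=None if driver.lower() in _NA_TOKENS else driver,
        pdl1_tps=(None if tps_token.lower() in _NA_TOKENS
                  else TpsValue.parse(tps_token)),
        treatment=_parse_enum(row["treatment"], _TREATMENT_TOKENS, rownum,
                              "treatment"),
        line=_parse_enum(row["line"], _LINE_TOKENS, rownum, "line"),
        best_response=_parse_enum(
            row["recist"],
            {r.value.lower(): r for r in BestResponse}, rownum, "recist"),
        pfs_months=float(row["pfs_months"]),
        pfs_event=_parse_bool(row["pfs_status"], rownum, "pfs_status"),
        os_months=float(row["os_months"]),
        os_event=_parse_bool(row["os_status"], rownum, "os_status"),
    )


_MARKER_COLS = tuple(m.lower() for m in KNOWN_MARKERS)

#: schema name -> (record type, required columns, row parser)
_SCHEMAS: dict[type, tuple[tuple[str, ...], object]] = {
    TILFieldMeasurement: (
        ("sample_id", "component", "field_index",
         "intratumoral_density", "stromal_density"),
        _til_from_row,
    ),
    CellRecord: (
        ("sample_id", "component", "cell_id", "x", "y", "region"),
        _cell_from_row,
    ),
    VariantCall: (
        ("chrom", "pos", "ref", "alt", "vaf", "hq_support_reads",
         "consequence"),
        _variant_from_row,
    ),
    CloneRecord: (("cdr3", "count", "productive"), _clone_from_row),
    PatientOutcome: (
        ("patient_id", "center", "sex", "age", "driver_status", "pdl1_tps",
         "treatment", "line", "recist", "pfs_months", "pfs_status",
         "os_months", "os_status"),
        _patient_from_row,
    ),
}


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_table(path: str | Path, schema: type) -> list:
    """Read a validated record table (TSV or CSV, sniffed from the header).

    Parameters
    ----------
    path
        Table file with a header row naming the schema's columns
        (case-insensitive; extra columns are ignored except cell-marker
        columns, which are collected into the marker map).
    schema
        One of the five record classes in this module.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    ValidationError
        If a row fails type conversion or a record invariant, with the
        1-based data-row number in the message.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    required, parser = _SCHEMAS[schema]
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise SchemaError(f"{path}: empty file, no header")
        delim = _sniff_delimiter(first)
        header = [h.strip().lower() for h in first.rstrip("\r\n").split(delim)]
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        reader = csv.reader(fh, delimiter=delim)
        records = []
        for rownum, raw in enumerate(reader, start=1):
            if not raw or all(not c.strip() for c in raw):
                continue
            row = dict(zip(header, raw))
            try:
                records.append(parser(row, rownum))
            except ValidationError:
                raise
            except (ValueError, KeyError) as exc:
                raise ValidationError(f"{path} row {rownum}: {exc}") from exc
    return records


def _record_to_row(record) -> dict[str, str]:
    if isinstance(record, CellRecord):
        row = {
            "sample_id": record.sample_id,
            "component": record.component.value,
            "cell_id": record.cell_id,
            "x": repr(record.x),
            "y": repr(record.y),
            "region": record.region.value,
        }
        for m in KNOWN_MARKERS:
            row[m.lower()] = "1" if record.markers.get(m, False) else "0"
        return row
    if isinstance(record, TILFieldMeasurement):
        return {
            "sample_id": record.sample_id,
            "component": record.component.value,
            "field_index": str(record.field_index),
            "intratumoral_density": repr(record.intratumoral_density),
            "stromal_density": repr(record.stromal_density),
        }
    if isinstance(record, VariantCall):
        return {
            "chrom": record.chrom, "pos": str(record.pos),
            "ref": record.ref, "alt": record.alt,
            "vaf": repr(record.vaf),
            "hq_support_reads": str(record.hq_support_reads),
            "consequence": record.consequence,
            "pe_bias": "1" if record.pe_bias else "0",
        }
    if isinstance(record, CloneRecord):
        return {
            "cdr3": record.cdr3, "count": str(record.count),
            "productive": "1" if record.productive else "0",
        }
    if isinstance(record, PatientOutcome):
        return {
            "patient_id": record.patient_id,
            "center": record.center,
            "sex": record.sex,
            "age": repr(record.age),
            "driver_status": record.driver_status or "NA",
            "pdl1_tps": str(record.pdl1_tps) if record.pdl1_tps else "NA",
            "treatment": record.treatment.value,
            "line": record.line.value,
            "recist": record.best_response.value,
            "pfs_months": repr(record.pfs_months),
            "pfs_status": "1" if record.pfs_event else "0",
            "os_months": repr(record.os_months),
            "os_status": "1" if record.os_event else "0",
        }
    raise SchemaError(f"cannot serialize record of type {type(record)!r}")


def write_table(records: Sequence, path: str | Path) -> None:
    """Write records as TSV; floats use ``repr`` so read/write round-trips
    are bit-identical."""
    if not records:
        raise ValueError("refusing to write an empty table without a schema")
    rows = [_record_to_row(r) for r in records]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


# --------------------------------------------------------------------------
# Minimal VCF dialect
# --------------------------------------------------------------------------

def read_vcf_variants(path: str | Path) -> list[VariantCall]:
    """Read variants from a minimal VCF dialect.

    Only CHROM, POS, REF, ALT plus the INFO keys ``VAF`` (fraction),
    ``HQSR`` (high-quality supporting reads), ``CSQ`` (consequence class)
    and ``PEBIAS`` (0/1) are interpreted; everything else is ignored.
    """
    variants: list[VariantCall] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValidationError(
                    f"{path} line {lineno}: expected >= 8 VCF columns")
            info = {}
            for item in parts[7].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    info[k.upper()] = v
            try:
                variants.append(VariantCall(
                    chrom=parts[0], pos=int(parts[1]),
                    ref=parts[3], alt=parts[4],
                    vaf=float(info["VAF"]),
                    hq_support_reads=int(info["HQSR"]),
                    consequence=info.get("CSQ", "other").strip().lower(),
                    pe_bias=info.get("PEBIAS", "0").strip() in ("1", "true"),
                ))
            except KeyError as exc:
                raise ValidationError(
                    f"{path} line {lineno}: missing INFO key {exc}") from exc
    return variants


# --------------------------------------------------------------------------
# Bundled real-world cohort
# --------------------------------------------------------------------------

def load_table2_fixture() -> list[PatientOutcome]:
    """Load the bundled 46-patient real-world ICI cohort.

    The table is transcribed verbatim from the published cohort listing,
    including its internal oddities (e.g. a PR with a 1.4-month PFS);
    "NA" cells become explicit unknowns, never zeros.
    """
    source = resources.files("asc_time").joinpath("data/table2.tsv")
    with resources.as_file(source) as path:
        return read_table(path, PatientOutcome)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class Thresholds:
    """Analysis cutoffs; defaults are the study's stated values."""

    til_cutoff: float = 10.0       # % lymphocyte density for "infiltrated"
    vaf_min: float = 0.02          # minimum somatic variant allele fraction
    min_hq_reads: int = 5          # minimum high-quality supporting reads
    panel_mb: float = 0.7          # targeted coding region size, Mb
    tps_positive: float = 1.0      # PD-L1 TPS positivity cut, %

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


def load_config(path: str | Path) -> dict:
    """Load a flat key=value or YAML mapping of thresholds/seeds."""
    import yaml

    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if isinstance(data, dict):
        return data
    out: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = yaml.safe_load(value)
        except yaml.YAMLError:
            out[key] = value
    return out
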