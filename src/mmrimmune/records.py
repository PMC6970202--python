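"""Core record types for per-tumor immune cell counts.

Each tumor carries manual immune-cell counts for five markers (CD3, CD8,
CD45RO, FoxP3, PD-1) in 200 um^2 regions of interest (ROIs) at two tumor
compartments: the tumor center (CT) and the invasive margin (IM).
Hysterectomy specimens have four ROIs per marker in each compartment;
diagnostic biopsies expose no invasive margin, so they carry CT ROIs only.
Missing IM data is represented as *absent*, never as zero — a zero is a
real observation.

PD-L1 is scored semi-quantitatively (percent tumor cells positive at weak/
moderate/strong intensity, plus an immune-cell staining pattern), not
counted, and lives in dedicated fields.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

ROI_PER_COMPARTMENT = 4
ROI_AREA_UM2 = 200


class Marker(str, enum.Enum):
    CD3 = "CD3"
    CD8 = "CD8"
    CD45RO = "CD45RO"
    FOXP3 = "FOXP3"
    PD1 = "PD1"


class Compartment(str, enum.Enum):
    CT = "CT"  # tumor center
    IM = "IM"  # invasive margin


class CohortLabel(str, enum.Enum):
    LS_MMRD = "LS_MMRD"            # Lynch-syndrome-associated MMR deficient
    SPORADIC_MMRD = "SPORADIC_MMRD"  # MLH1-hypermethylated MMR deficient
    MMRP = "MMRP"                  # MMR proficient


class Specimen(str, enum.Enum):
    HYSTERECTOMY = "HYSTERECTOMY"
    BIOPSY = "BIOPSY"


class Pdl1Pattern(str, enum.Enum):
    ABSENT = "ABSENT"
    FOCAL = "FOCAL"
    DIFFUSE = "DIFFUSE"


class MissingCompartmentError(LookupError):
    """A population was requested for a compartment the specimen does not have.

    Raised for invasive-margin requests on biopsy specimens, where the IM
    could not be delineated: the population is *undefined*, not zero.
    """


class CohortParseError(ValueError):
    """A cohort table violated the documented CSV dialect."""


def _validate_roi_list(counts: Sequence[int], where: str) -> list[int]:
    counts = list(counts)
    if len(counts) != ROI_PER_COMPARTMENT:
        raise ValueError(
            f"{where}: expected {ROI_PER_COMPARTMENT} ROI counts, got {len(counts)}"
        )
    out = []
    for c in counts:
        if isinstance(c, bool) or c != int(c) or c < 0:
            raise ValueError(f"{where}: ROI counts must be non-negative integers, got {c!r}")
        out.append(int(c))
    return out


@dataclass
class TumorRecord:
    """One tumor: cohort label, specimen type, ROI counts, PD-L1 scoring.

    ``roi_counts`` maps ``(Marker, Compartment)`` to the list of 4 per-ROI
    cell counts. Biopsy records must not carry IM entries.
    """

    tumor_id: str
    cohort: CohortLabel
    specimen: Specimen
    roi_counts: dict[tuple[Marker, Compartment], list[int]]
    pdl1_tumor_pct_by_intensity: dict[int, float] = field(default_factory=dict)
    pdl1_immune_pattern: Pdl1Pattern = Pdl1Pattern.ABSENT
    age_years: Optional[float] = None
    grade: Optional[str] = None
    stage: Optional[str] = None
    histology: Optional[str] = None

    def __post_init__(self) -> None:
        self.cohort = CohortLabel(self.cohort)
        self.specimen = Specimen(self.specimen)
        self.pdl1_immune_pattern = Pdl1Pattern(self.pdl1_immune_pattern)
        expected = {
            (m, c)
            for m in Marker
            for c in (Compartment if self.specimen is Specimen.HYSTERECTOMY else [Compartment.CT])
        }
        keys = {(Marker(m), Compartment(c)) for m, c in self.roi_counts}
        if keys != expected:
            missing = expected - keys
            extra = keys - expected
            raise ValueError(
                f"tumor {self.tumor_id!r} ({self.specimen.value}): ROI populations "
                f"mismatch (missing {sorted(k[0].value + '_' + k[1].value for k in missing)}, "
                f"unexpected {sorted(k[0].value + '_' + k[1].value for k in extra)})"
            )
        self.roi_counts = {
            (Marker(m), Compartment(c)): _validate_roi_list(
                v, f"tumor {self.tumor_id!r} {Marker(m).value}_{Compartment(c).value}"
            )
            for (m, c), v in self.roi_counts.items()
        }
        for intensity, pct in self.pdl1_tumor_pct_by_intensity.items():
            if intensity not in (1, 2, 3):
                raise ValueError(f"tumor {self.tumor_id!r}: PD-L1 intensity must be 1, 2 or 3")
            if not 0 <= pct <= 100:
                raise ValueError(
                    f"tumor {self.tumor_id!r}: PD-L1 percent {pct} outside [0, 100]"
                )
        if self.age_years is not None and self.age_years <= 0:
            raise ValueError(f"tumor {self.tumor_id!r}: age must be positive")

    def has_compartment(self, compartment: Compartment) -> bool:
        return Compartment(compartment) is Compartment.CT or self.specimen is Specimen.HYSTERECTOMY


def sum_compartment(record: TumorRecord, marker: Marker, compartment: Compartment) -> int:
    """Summed cell count of a marker over the 4 ROIs of one compartment."""
    marker = Marker(marker)
    compartment = Compartment(compartment)
    key = (marker, compartment)
    if key not in record.roi_counts:
        raise MissingCompartmentError(
            f"tumor {record.tumor_id!r} ({record.specimen.value}) has no "
            f"{compartment.value} ROIs; the population is undefined"
        )
    return sum(record.roi_counts[key])


def overall_sum(record: TumorRecord, marker: Marker) -> int:
    """Whole-tumor count: CT + IM for hysterectomies, CT alone for biopsies."""
    total = sum_compartment(record, marker, Compartment.CT)
    if record.has_compartment(Compartment.IM):
        total += sum_compartment(record, marker, Compartment.IM)
    return total


def expected_roi_count(n_hysterectomy: int, n_biopsy: int, n_markers: int) -> int:
    """Total ROIs scored across a study: hysterectomies contribute 8 (4 CT +
    4 IM) and biopsies 4 (CT only) per counted marker."""
    if min(n_hysterectomy, n_biopsy, n_markers) < 0:
        raise ValueError("arguments must be non-negative")
    return n_markers * (2 * ROI_PER_COMPARTMENT * n_hysterectomy + ROI_PER_COMPARTMENT * n_biopsy)


@dataclass
class Cohort:
    """An ordered collection of :class:`TumorRecord` with unique ids."""

    records: list[TumorRecord]

    def __post_init__(self) -> None:
        ids = [r.tumor_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate tumor_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TumorRecord]:
        return iter(self.records)

    @property
    def label_counts(self) -> dict[CohortLabel, int]:
        counts: dict[CohortLabel, int] = {}
        for r in self.records:
            counts[r.cohort] = counts.get(r.cohort, 0) + 1
        return counts

    def subset(self, predicate) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)])


# ---------------------------------------------------------------------------
# CSV dialect: one row per tumor; ROI counts as explicit columns
# {MARKER}_{CT|IM}_{1..4}; IM cells empty for biopsies.
# ---------------------------------------------------------------------------

_META_COLS = ["tumor_id", "cohort", "specimen", "age", "grade", "stage", "histology"]
_PDL1_COLS = ["pdl1_pct_1plus", "pdl1_pct_2plus", "pdl1_pct_3plus", "pdl1_immune_pattern"]


def _roi_columns() -> list[str]:
    return [
        f"{m.value}_{c.value}_{i}"
        for m in Marker
        for c in Compartment
        for i in range(1, ROI_PER_COMPARTMENT + 1)
    ]


COHORT_COLUMNS = _META_COLS + _roi_columns() + _PDL1_COLS


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as a flat UTF-8 CSV in the documented dialect."""
    rows = []
    for r in cohort:
        row: dict[str, object] = {
            "tumor_id": r.tumor_id,
            "cohort": r.cohort.value,
            "specimen": r.specimen.value,
            "age": r.age_years,
            "grade": r.grade,
            "stage": r.stage,
            "histology": r.histology,
            "pdl1_pct_1plus": r.pdl1_tumor_pct_by_intensity.get(1),
            "pdl1_pct_2plus": r.pdl1_tumor_pct_by_intensity.get(2),
            "pdl1_pct_3plus": r.pdl1_tumor_pct_by_intensity.get(3),
            "pdl1_immune_pattern": r.pdl1_immune_pattern.value,
        }
        for (m, c), counts in r.roi_counts.items():
            for i, v in enumerate(counts, start=1):
                row[f"{m.value}_{c.value}_{i}"] = v
        rows.append(row)
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validating arity and uniqueness with row-level errors."""
    frame = pd.read_csv(path, dtype={"tumor_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortParseError(f"missing column(s): {missing_cols}")
    records = []
    for idx, row in frame.iterrows():
        rownum = idx + 2  # header is line 1
        tumor_id = row["tumor_id"]
        if pd.isna(tumor_id) or not str(tumor_id):
            raise CohortParseError(f"row {rownum}: empty tumor_id")
        try:
            specimen = Specimen(row["specimen"])
            cohort_label = CohortLabel(row["cohort"])
        except ValueError as exc:
            raise CohortParseError(f"row {rownum} ({tumor_id}): {exc}") from exc
        roi_counts: dict[tuple[Marker, Compartment], list[int]] = {}
        compartments = (
            list(Compartment) if specimen is Specimen.HYSTERECTOMY else [Compartment.CT]
        )
        for m in Marker:
            for c in compartments:
                cols = [f"{m.value}_{c.value}_{i}" for i in range(1, ROI_PER_COMPARTMENT + 1)]
                vals = [row[col] for col in cols]
                present = [v for v in vals if not pd.isna(v)]
                if len(present) != ROI_PER_COMPARTMENT:
                    raise CohortParseError(
                        f"row {rownum} ({tumor_id}): field {m.value}_{c.value} has "
                        f"{len(present)} of {ROI_PER_COMPARTMENT} ROI values"
                    )
                try:
                    roi_counts[(m, c)] = [int(v) for v in present]
                except (TypeError, ValueError) as exc:
                    raise CohortParseError(
                        f"row {rownum} ({tumor_id}): non-integer ROI count in {m.value}_{c.value}"
                    ) from exc
        pdl1 = {}
        for intensity, col in zip((1, 2, 3), _PDL1_COLS[:3]):
            if not pd.isna(row[col]):
                pdl1[intensity] = float(row[col])
        try:
            record = TumorRecord(
                tumor_id=str(tumor_id),
                cohort=cohort_label,
                specimen=specimen,
                roi_counts=roi_counts,
                pdl1_tumor_pct_by_intensity=pdl1,
                pdl1_immune_pattern=Pdl1Pattern(row["pdl1_immune_pattern"])
                if not pd.isna(row["pdl1_immune_pattern"])
                else Pdl1Pattern.ABSENT,
                age_years=None if pd.isna(row["age"]) else float(row["age"]),
                grade=None if pd.isna(row["grade"]) else str(row["grade"]),
                stage=None if pd.isna(row["stage"]) else str(row["stage"]),
                histology=None if pd.isna(row["histology"]) else str(row["histology"]),
            )
        except ValueError as exc:
            raise CohortParseError(f"row {rownum} ({tumor_id}): {exc}") from exc
        records.append(record)
    try:
        return Cohort(records)
    except ValueError as exc:
        raise CohortParseError(str(exc)) from exc
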