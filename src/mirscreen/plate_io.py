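"""Data model and file I/O for plate-based miRNA sequencing screens.

A screen is described by three tables that this module reads, validates and
joins into a :class:`ScreenDataset`:

* a miRNA x well **count matrix** (TSV; rows = mature miRNA ids, columns =
  well ids, integer read counts),
* **well metadata** (CSV; plate, position, sequencing batch, treatment role,
  compound, dose) — one row per well,
* **compound annotations** (CSV; name, clinical indication, pathway,
  blood-brain-barrier permeability, target/compound class) used as secondary
  hit criteria and class labels downstream.

Well ids follow the ``"<plate>:<RowCol>"`` convention with zero-padded
columns (``"P02:A01"``), which sorts naturally and is unambiguous across
96- and 384-well geometries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "WellRecord",
    "CompoundAnnotation",
    "CountMatrix",
    "MismatchReport",
    "ScreenDataset",
    "read_count_matrix",
    "write_count_matrix",
    "read_well_metadata",
    "write_well_metadata",
    "read_compound_annotations",
    "write_compound_annotations",
    "assemble_screen",
]

TREATMENT_ROLES = ("compound", "vehicle", "positive_control")
QC_REASONS = ("none", "low_count", "external")
BBB_STATES = ("yes", "no", "unknown")

#: Valid row letters / column ranges per plate geometry.
PLATE_GEOMETRIES = {96: ("ABCDEFGH", 12), 384: ("ABCDEFGHIJKLMNOP", 24)}

_POSITION_RE = re.compile(r"^([A-P])(\d{2})$")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed content violates a screen-level invariant."""


def _check_position(position: str, geometry: int | None = None) -> None:
    m = _POSITION_RE.match(position)
    if not m:
        raise ValidationError(
            f"well position {position!r} is not of the form RowCol (e.g. 'A01')"
        )
    row, col = m.group(1), int(m.group(2))
    geometries = [geometry] if geometry else list(PLATE_GEOMETRIES)
    for g in geometries:
        rows, ncol = PLATE_GEOMETRIES[g]
        if row in rows and 1 <= col <= ncol:
            return
    raise ValidationError(
        f"position {position!r} invalid for {geometries}-well geometry"
    )


@dataclass(frozen=True)
class WellRecord:
    """One well of the screen: its plate coordinates, batch and treatment.

    ``treatment_role`` distinguishes library compounds from the DMSO vehicle
    wells (the per-batch normalization baseline) and the forskolin positive
    controls.  Vehicle wells must carry an empty ``compound_id``.  QC flags
    are attached after quality control; ``qc_reason='external'`` models
    exclusions decided outside this pipeline (e.g. by microscopy).
    """

    well_id: str
    plate_id: str
    position: str
    batch_id: str
    treatment_role: str
    compound_id: str = ""
    dose: float = 10.0  # screen concentration in uM
    qc_excluded: bool = False
    qc_reason: str = "none"

    def __post_init__(self) -> None:
        if self.treatment_role not in TREATMENT_ROLES:
            raise ValidationError(
                f"well {self.well_id}: unknown treatment_role "
                f"{self.treatment_role!r} (expected one of {TREATMENT_ROLES})"
            )
        if self.qc_reason not in QC_REASONS:
            raise ValidationError(
                f"well {self.well_id}: unknown qc_reason {self.qc_reason!r}"
            )
        if self.treatment_role == "vehicle" and self.compound_id:
            raise ValidationError(
                f"well {self.well_id}: vehicle wells must have empty compound_id, "
                f"got {self.compound_id!r}"
            )
        if self.qc_excluded != (self.qc_reason != "none"):
            raise ValidationError(
                f"well {self.well_id}: qc_excluded={self.qc_excluded} inconsistent "
                f"with qc_reason={self.qc_reason!r}"
            )
        _check_position(self.position)

    def excluded(self, reason: str) -> "WellRecord":
        """Return a copy flagged as QC-excluded for ``reason``."""
        return replace(self, qc_excluded=True, qc_reason=reason)


@dataclass(frozen=True)
class CompoundAnnotation:
    """Library annotation of one compound (secondary hit criteria)."""

    compound_id: str
    name: str = ""
    clinical_indication: str = ""
    in_clinical_use: bool = False
    pathway: str = ""
    bbb_permeable: str = "unknown"
    target_class: str = ""
    prior_evidence: bool = False

    def __post_init__(self) -> None:
        if self.bbb_permeable not in BBB_STATES:
            raise ValidationError(
                f"compound {self.compound_id}: bbb_permeable must be one of "
                f"{BBB_STATES}, got {self.bbb_permeable!r}"
            )
        if self.in_clinical_use and not self.clinical_indication:
            raise ValidationError(
                f"compound {self.compound_id}: in_clinical_use requires a "
                "clinical_indication"
            )


class CountMatrix:
    """Non-negative integer miRNA x well read counts.

    Thin wrapper over a :class:`pandas.DataFrame` (rows = miRNA ids, columns
    = well ids) that enforces integrality, non-negativity and id uniqueness
    at construction and preserves row/column order.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate miRNA ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate well ids: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at miRNA {counts.index[bad[0]]!r}, "
                    f"well {counts.columns[bad[1]]!r}"
                )
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at miRNA {counts.index[bad[0]]!r}, "
                f"well {counts.columns[bad[1]]!r}"
            )
        self._df = counts.astype(np.int64)
        self._df.index.name = "mirna_id"

    @property
    def counts(self) -> pd.DataFrame:
        return self._df

    @property
    def mirna_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def well_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def well_totals(self) -> pd.Series:
        """Total annotated reads per well (column sums)."""
        return self._df.sum(axis=0)

    def subset_wells(self, well_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self._df[list(well_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        n_m, n_w = self.shape
        return f"CountMatrix({n_m} miRNAs x {n_w} wells)"


@dataclass
class MismatchReport:
    """Cross-referencing report produced by :func:`assemble_screen`."""

    wells_without_counts: list[str] = field(default_factory=list)
    counts_without_wells: list[str] = field(default_factory=list)
    unannotated_compounds: list[str] = field(default_factory=list)

    @property
    def n_dropped_wells(self) -> int:
        return len(self.wells_without_counts)

    def empty(self) -> bool:
        return not (
            self.wells_without_counts
            or self.counts_without_wells
            or self.unannotated_compounds
        )


@dataclass
class ScreenDataset:
    """Counts, well metadata and compound annotations, cross-referenced.

    Every count column has a matching :class:`WellRecord` (in the same
    order); compounds referenced by wells but absent from ``annotations``
    are listed in ``mismatch`` rather than silently invented.
    """

    counts: CountMatrix
    wells: list[WellRecord]
    annotations: dict[str, CompoundAnnotation]
    mismatch: MismatchReport = field(default_factory=MismatchReport)

    def __post_init__(self) -> None:
        well_ids = [w.well_id for w in self.wells]
        if well_ids != self.counts.well_ids:
            raise ValidationError(
                "well metadata does not align with count matrix columns"
            )
        batches_with_compounds = {
            w.batch_id for w in self.wells if w.treatment_role == "compound"
        }
        batches_with_vehicle = {
            w.batch_id for w in self.wells if w.treatment_role == "vehicle"
        }
        missing = sorted(batches_with_compounds - batches_with_vehicle)
        if missing:
            raise ValidationError(
                f"batches {missing} contain compound wells but no vehicle "
                "wells; per-batch DMSO normalization is impossible"
            )

    @property
    def well_index(self) -> dict[str, WellRecord]:
        return {w.well_id: w for w in self.wells}

    def wells_df(self) -> pd.DataFrame:
        """Well metadata as a DataFrame indexed by well_id."""
        df = pd.DataFrame([vars(w) for w in self.wells])
        return df.set_index("well_id", drop=False)

    def retained_wells(self) -> list[WellRecord]:
        return [w for w in self.wells if not w.qc_excluded]

    def with_wells(self, wells: list[WellRecord]) -> "ScreenDataset":
        """Copy of the dataset with replaced well records (same order)."""
        return ScreenDataset(self.counts, wells, self.annotations, self.mismatch)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> CountMatrix:
    """Read a TSV count matrix (first column miRNA id, header = well ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from exc
    return CountMatrix(numeric)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Write the canonical TSV form (tab-separated, header row, LF endings)."""
    matrix.counts.to_csv(path, sep="\t", lineterminator="\n")


_WELL_COLUMNS = [
    "well_id",
    "plate_id",
    "position",
    "batch_id",
    "treatment_role",
    "compound_id",
    "dose",
]
_WELL_QC_COLUMNS = ["qc_excluded", "qc_reason"]


def read_well_metadata(path) -> list[WellRecord]:
    """Read well metadata CSV into validated :class:`WellRecord` objects."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _WELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            WellRecord(
                well_id=row["well_id"],
                plate_id=row["plate_id"],
                position=row["position"],
                batch_id=row["batch_id"],
                treatment_role=row["treatment_role"],
                compound_id=row["compound_id"],
                dose=float(row["dose"]) if row["dose"] else 0.0,
                qc_excluded=row.get("qc_excluded", "False") in ("True", "true", "1"),
                qc_reason=row.get("qc_reason", "none") or "none",
            )
        )
    seen: set[str] = set()
    for r in records:
        if r.well_id in seen:
            raise ValidationError(f"duplicate well_id {r.well_id!r}")
        seen.add(r.well_id)
    return records


def write_well_metadata(wells: Iterable[WellRecord], path) -> None:
    df = pd.DataFrame([vars(w) for w in wells])
    df = df[_WELL_COLUMNS + _WELL_QC_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n")


_COMPOUND_COLUMNS = [
    "compound_id",
    "name",
    "clinical_indication",
    "in_clinical_use",
    "pathway",
    "bbb_permeable",
    "target_class",
    "prior_evidence",
]


def read_compound_annotations(path) -> dict[str, CompoundAnnotation]:
    """Read a compound annotation CSV into a compound_id -> annotation map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing compound_id column")
    annotations: dict[str, CompoundAnnotation] = {}
    for _, row in df.iterrows():
        cid = row["compound_id"]
        if cid in annotations:
            raise ValidationError(f"duplicate compound_id {cid!r}")
        annotations[cid] = CompoundAnnotation(
            compound_id=cid,
            name=row.get("name", ""),
            clinical_indication=row.get("clinical_indication", ""),
            in_clinical_use=row.get("in_clinical_use", "False")
            in ("True", "true", "1"),
            pathway=row.get("pathway", ""),
            bbb_permeable=row.get("bbb_permeable", "unknown") or "unknown",
            target_class=row.get("target_class", ""),
            prior_evidence=row.get("prior_evidence", "False")
            in ("True", "true", "1"),
        )
    return annotations


def write_compound_annotations(
    annotations: Mapping[str, CompoundAnnotation], path
) -> None:
    df = pd.DataFrame([vars(a) for a in annotations.values()])
    df = df[_COMPOUND_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_screen(
    counts: CountMatrix,
    wells: Sequence[WellRecord],
    annotations: Mapping[str, CompoundAnnotation],
) -> ScreenDataset:
    """Join counts, wells and annotations into a validated screen dataset.

    Wells lacking a count column and count columns lacking metadata are
    recorded in the mismatch report, never silently dropped:
    ``len(input wells) == len(dataset wells) + len(wells_without_counts)``.
    A batch that contains compound wells but no vehicle well raises
    :class:`ValidationError` because its fold changes would have no baseline.
    """
    report = MismatchReport()
    by_id = {w.well_id: w for w in wells}
    matched_columns = [wid for wid in counts.well_ids if wid in by_id]
    report.counts_without_wells = [
        wid for wid in counts.well_ids if wid not in by_id
    ]
    report.wells_without_counts = [
        w.well_id for w in wells if w.well_id not in set(counts.well_ids)
    ]
    matched_wells = [by_id[wid] for wid in matched_columns]
    referenced = {
        w.compound_id for w in matched_wells if w.compound_id
    }
    report.unannotated_compounds = sorted(referenced - set(annotations))
    return ScreenDataset(
        counts=counts.subset_wells(matched_columns),
        wells=matched_wells,
        annotations=dict(annotations),
        mismatch=report,
    )
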