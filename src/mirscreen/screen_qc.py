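"""Well-level quality control and housekeeping-miRNA identification.

QC is a single rule: wells with fewer than 1,000 total annotated miRNA
reads are excluded from all downstream analysis (strict inequality — a
well at exactly the threshold is retained).  Exclusions decided outside
the pipeline (e.g. microscopy-based) are represented with the ``external``
reason and respected everywhere.

Housekeeping miRNAs — stable normalizers for follow-up qPCR — are found by
computing the coefficient of variation (COV = sample SD / mean) of each
miRNA's CPM within each sequencing batch and intersecting the k
lowest-COV miRNAs across batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mirscreen.plate_io import ScreenDataset, ValidationError, WellRecord

__all__ = [
    "QCReport",
    "HousekeepingReport",
    "filter_low_count_wells",
    "species_detection_summary",
    "compute_cov",
    "select_housekeeping",
    "deposition_summary",
]


@dataclass
class QCReport:
    """Outcome of the low-count well filter."""

    well_totals: pd.Series
    excluded: dict[str, str]  # well_id -> reason
    threshold: int

    @property
    def excluded_well_ids(self) -> list[str]:
        return list(self.excluded)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "total_counts": self.well_totals,
                "excluded": self.well_totals.index.isin(self.excluded),
            }
        )
        df["reason"] = [self.excluded.get(w, "none") for w in df.index]
        df.index.name = "well_id"
        return df


def filter_low_count_wells(
    dataset: ScreenDataset, threshold: int = 1000
) -> tuple[ScreenDataset, QCReport]:
    """Flag wells whose total annotated counts fall strictly below threshold.

    Wells already excluded for an external reason keep that flag.  Returns
    a new dataset (well records updated) and a :class:`QCReport`; raising
    the threshold can only grow the exclusion set (monotonicity).
    """
    totals = dataset.counts.well_totals()
    excluded: dict[str, str] = {}
    new_wells: list[WellRecord] = []
    for well in dataset.wells:
        if well.qc_excluded and well.qc_reason == "external":
            excluded[well.well_id] = "external"
            new_wells.append(well)
        elif totals[well.well_id] < threshold:
            excluded[well.well_id] = "low_count"
            new_wells.append(well.excluded("low_count"))
        else:
            new_wells.append(well)
    return dataset.with_wells(new_wells), QCReport(totals, excluded, threshold)


def species_detection_summary(
    dataset: ScreenDataset, cutoffs: Sequence[int] = (1, 5, 10, 100)
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean number of miRNA species detected per retained well at each cutoff.

    For every retained well and cutoff ``c``, counts miRNAs with at least
    ``c`` reads.  Returns the cross-well mean per cutoff and the per-well
    table.  Species counts are non-increasing in the cutoff by construction.
    """
    retained = [w.well_id for w in dataset.retained_wells()]
    if not retained:
        raise ValidationError("no retained wells; QC excluded everything")
    counts = dataset.counts.counts[retained]
    per_well = pd.DataFrame(
        {c: (counts >= c).sum(axis=0) for c in cutoffs}
    )
    per_well.columns.name = "cutoff"
    means = per_well.mean(axis=0)
    means.name = "mean_species_detected"
    return means, per_well


def compute_cov(
    expression: pd.DataFrame, wells: Sequence[WellRecord]
) -> pd.DataFrame:
    """Coefficient of variation per miRNA per batch on a normalized layer.

    ``expression`` is a miRNA x well matrix (typically CPM over retained
    wells).  COV = sample standard deviation (ddof=1) / mean within the
    batch; a zero-mean miRNA is recorded as missing (NaN), never as 0.
    COV is scale-invariant, so any common per-batch factor cancels.
    """
    by_id = {w.well_id: w for w in wells}
    unknown = [w for w in expression.columns if w not in by_id]
    if unknown:
        raise ValidationError(f"expression columns without well metadata: {unknown}")
    batches: dict[str, list[str]] = {}
    for wid in expression.columns:
        batches.setdefault(by_id[wid].batch_id, []).append(wid)
    cov_cols = {}
    for batch_id, well_ids in sorted(batches.items()):
        if len(well_ids) < 2:
            raise ValidationError(
                f"batch {batch_id} has a single well; COV undefined"
            )
        sub = expression[well_ids]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sd / mean
        cov[mean == 0] = np.nan
        cov_cols[batch_id] = cov
    table = pd.DataFrame(cov_cols)
    table.index.name = "mirna_id"
    table.columns.name = "batch_id"
    return table


@dataclass
class HousekeepingReport:
    """Per-batch COV table and the housekeeping set selected from it."""

    cov_table: pd.DataFrame
    selected: list[str]
    k: int
    per_batch_top: dict[str, list[str]] = field(default_factory=dict)


def select_housekeeping(cov_table: pd.DataFrame, k: int = 10) -> HousekeepingReport:
    """Intersect the k smallest-COV miRNAs of every batch.

    Ties are broken by mean COV across batches, then id lexicographically,
    making the selection deterministic.  miRNAs with a missing COV in a
    batch cannot be selected there.  An empty intersection is returned with
    a warning rather than an error.
    """
    if cov_table.shape[1] == 0:
        raise ValidationError("COV table covers no batches")
    mean_cov = cov_table.mean(axis=1)
    per_batch_top: dict[str, list[str]] = {}
    selected: set[str] | None = None
    for batch_id in cov_table.columns:
        col = cov_table[batch_id].dropna()
        order = sorted(
            col.index, key=lambda m: (col[m], mean_cov.get(m, np.inf), m)
        )
        top = order[:k]
        per_batch_top[batch_id] = top
        selected = set(top) if selected is None else selected & set(top)
    result = sorted(selected or set())
    if not result:
        warnings.warn(
            "housekeeping intersection across batches is empty; "
            "consider a larger k",
            stacklevel=2,
        )
    return HousekeepingReport(cov_table, result, k, per_batch_top)


def deposition_summary(
    dataset: ScreenDataset,
    threshold: int = 1000,
    focus_mirna: str | None = None,
) -> dict:
    """Screen-level summary statistics for parity checks against a deposition.

    Computes, from any locally supplied screen dataset: the number of wells
    excluded by the low-count filter, the mean total annotated reads of
    retained wells, the mean species detected at cutoff 1, and (optionally)
    the abundance rank of ``focus_mirna`` among vehicle wells (1 = most
    abundant by mean CPM).
    """
    filtered, report = filter_low_count_wells(dataset, threshold)
    retained_ids = [w.well_id for w in filtered.retained_wells()]
    totals = report.well_totals[retained_ids]
    means, _ = species_detection_summary(filtered, cutoffs=(1,))
    out = {
        "n_wells": len(dataset.wells),
        "n_excluded": report.n_excluded,
        "mean_reads_retained": float(totals.mean()),
        "mean_species_cutoff1": float(means[1]),
    }
    if focus_mirna is not None:
        vehicle = [
            w.well_id
            for w in filtered.retained_wells()
            if w.treatment_role == "vehicle"
        ]
        if vehicle:
            sub = filtered.counts.counts[vehicle]
            cpm = sub / sub.sum(axis=0) * 1e6
            mean_cpm = cpm.mean(axis=1).sort_values(ascending=False)
            ranks = pd.Series(
                np.arange(1, len(mean_cpm) + 1), index=mean_cpm.index
            )
            out["focus_rank_vehicle"] = (
                int(ranks[focus_mirna]) if focus_mirna in ranks else None
            )
    return out
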