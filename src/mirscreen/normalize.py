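"""Total-count normalization and per-batch vehicle-relative fold changes.

Counts are first scaled within each well to counts-per-million (CPM), which
removes library-size differences.  Screen comparisons then run on fold
changes relative to the DMSO vehicle wells of the *same sequencing batch*:

    FC(m, w) = (CPM(m, w) + p) / baseline_batch(w)(CPM(m, vehicle wells) + p)

with a symmetric pseudocount ``p`` (default 1 CPM) keeping fold changes
finite for undetected miRNAs.  Because every well in a batch is divided by
the same vehicle baseline, any multiplicative factor common to a batch —
the dominant batch-effect mode in pooled plate sequencing — cancels
exactly (up to the pseudocount perturbation).  Fold changes are never
computed across batches.

The default baseline is the geometric mean of the vehicle wells: it is
robust to a single outlier vehicle well and makes the mean vehicle
``log2fc`` exactly zero per batch.  Arithmetic mean and median are
selectable alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirscreen.plate_io import CountMatrix, ScreenDataset, ValidationError, WellRecord

__all__ = ["NormalizedScreen", "cpm_normalize", "vehicle_fold_change", "normalize_screen"]

BASELINES = ("geometric_mean", "arithmetic_mean", "median")


def cpm_normalize(
    counts: CountMatrix | pd.DataFrame, retained_wells: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scale each retained well's counts to a column total of one million.

    Raises when a retained well has zero total counts (such wells should
    have been excluded by QC first).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if retained_wells is not None:
        df = df[list(retained_wells)]
    totals = df.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValidationError(
            f"wells with zero total counts: {zero}; exclude them via QC "
            "before normalizing"
        )
    return df / totals * 1e6


@dataclass
class NormalizedScreen:
    """CPM and vehicle-relative fold-change layers over one well set.

    All three matrices share the same miRNA index and (retained) well
    columns; ``wells`` carries the matching metadata records in column
    order.  ``log2fc`` is the layer on which ranking, class profiling and
    correlation analysis run.
    """

    cpm: pd.DataFrame
    fold_change: pd.DataFrame
    log2fc: pd.DataFrame
    wells: list[WellRecord]
    pseudocount: float
    baseline: str

    def wells_df(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(w) for w in self.wells])
        return df.set_index("well_id", drop=False)

    def compound_wells(self) -> list[WellRecord]:
        return [w for w in self.wells if w.treatment_role == "compound"]

    def write(self, directory) -> None:
        """Write layers as TSV plus a JSON sidecar with the parameters used."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cpm.to_csv(directory / "cpm.tsv", sep="\t", lineterminator="\n")
        self.fold_change.to_csv(
            directory / "fold_change.tsv", sep="\t", lineterminator="\n"
        )
        self.log2fc.to_csv(directory / "log2fc.tsv", sep="\t", lineterminator="\n")
        params = {
            "pseudocount": self.pseudocount,
            "baseline": self.baseline,
            "n_wells": len(self.wells),
        }
        (directory / "normalization.json").write_text(
            json.dumps(params, indent=2) + "\n"
        )


def _baseline(values: pd.DataFrame, method: str) -> pd.Series:
    if method == "geometric_mean":
        return np.exp(np.log(values).mean(axis=1))
    if method == "arithmetic_mean":
        return values.mean(axis=1)
    if method == "median":
        return values.median(axis=1)
    raise ValueError(f"unknown baseline {method!r}; expected one of {BASELINES}")


def vehicle_fold_change(
    cpm: pd.DataFrame,
    wells: Sequence[WellRecord],
    pseudocount: float = 1.0,
    baseline: str = "geometric_mean",
) -> NormalizedScreen:
    """Fold change of every well against its batch's vehicle-well baseline.

    The pseudocount is added symmetrically to the numerator and to the
    vehicle CPMs entering the baseline, guaranteeing strictly positive fold
    changes and finite ``log2fc`` everywhere.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    by_id = {w.well_id: w for w in wells}
    missing = [w for w in cpm.columns if w not in by_id]
    if missing:
        raise ValidationError(f"CPM columns without well metadata: {missing}")
    records = [by_id[w] for w in cpm.columns]
    shifted = cpm + pseudocount
    fc = pd.DataFrame(index=cpm.index, columns=cpm.columns, dtype=float)
    for batch_id in sorted({w.batch_id for w in records}):
        batch_wells = [w.well_id for w in records if w.batch_id == batch_id]
        vehicle = [
            w.well_id
            for w in records
            if w.batch_id == batch_id and w.treatment_role == "vehicle"
        ]
        if not vehicle:
            raise ValidationError(
                f"batch {batch_id} has no retained vehicle well; cannot "
                "compute DMSO-relative fold changes"
            )
        base = _baseline(shifted[vehicle], baseline)
        if (base <= 0).any():
            raise ValidationError(
                f"batch {batch_id}: non-positive vehicle baseline; increase "
                "the pseudocount"
            )
        fc[batch_wells] = shifted[batch_wells].div(base, axis=0)
    return NormalizedScreen(
        cpm=cpm,
        fold_change=fc,
        log2fc=np.log2(fc),
        wells=records,
        pseudocount=pseudocount,
        baseline=baseline,
    )


def normalize_screen(
    dataset: ScreenDataset,
    pseudocount: float = 1.0,
    baseline: str = "geometric_mean",
) -> NormalizedScreen:
    """Convenience: CPM over retained wells, then vehicle fold changes."""
    retained = dataset.retained_wells()
    cpm = cpm_normalize(dataset.counts, [w.well_id for w in retained])
    return vehicle_fold_change(cpm, retained, pseudocount, baseline)
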