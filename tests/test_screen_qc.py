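"""Low-count QC, detection summaries and housekeeping selection."""

import numpy as np
import pandas as pd
import pytest

from mirscreen.plate_io import (
    CompoundAnnotation,
    CountMatrix,
    ScreenDataset,
    ValidationError,
    WellRecord,
)
from mirscreen.screen_qc import (
    compute_cov,
    deposition_summary,
    filter_low_count_wells,
    select_housekeeping,
    species_detection_summary,
)
from mirscreen.synthetic_data import ScreenSimConfig, simulate_screen


def make_dataset(columns: dict) -> ScreenDataset:
    """Single-plate dataset from a dict of well -> count column."""
    df = pd.DataFrame(
        columns, index=pd.Index([f"m{i}" for i in range(len(next(iter(columns.values()))))])
    )
    wells = []
    for i, well_id in enumerate(columns):
        role = "vehicle" if i == 0 else "compound"
        wells.append(
            WellRecord(
                well_id=well_id,
                plate_id="P01",
                position=f"A{i + 1:02d}",
                batch_id="B1",
                treatment_role=role,
                compound_id="" if role == "vehicle" else f"C{i:04d}",
            )
        )
    ann = {
        w.compound_id: CompoundAnnotation(compound_id=w.compound_id)
        for w in wells
        if w.compound_id
    }
    return ScreenDataset(CountMatrix(df), wells, ann)


class TestLowCountFilter:
    def test_strict_inequality_at_threshold(self):
        dataset = make_dataset(
            {"P01:A01": [2000, 0, 0], "P01:A02": [999, 0, 0], "P01:A03": [1000, 0, 0]}
        )
        filtered, report = filter_low_count_wells(dataset, threshold=1000)
        assert report.excluded == {"P01:A02": "low_count"}
        assert [w.qc_excluded for w in filtered.wells] == [False, True, False]

    def test_all_above_threshold_empty_list(self, small_screen):
        dataset, _ = small_screen
        _, report = filter_low_count_wells(dataset, threshold=1)
        assert report.n_excluded == 0

    def test_planted_failed_wells_exactly_recovered(self, small_screen):
        dataset, truth = small_screen
        _, report = filter_low_count_wells(dataset, threshold=1000)
        low = {w for w, r in report.excluded.items() if r == "low_count"}
        assert low == set(truth.failed_wells)

    def test_monotone_in_threshold(self, small_screen):
        dataset, _ = small_screen
        _, lo = filter_low_count_wells(dataset, threshold=500)
        _, hi = filter_low_count_wells(dataset, threshold=5000)
        assert set(lo.excluded) <= set(hi.excluded)

    def test_external_exclusions_preserved(self):
        dataset = make_dataset({"P01:A01": [2000], "P01:A02": [2000]})
        wells = [dataset.wells[0], dataset.wells[1].excluded("external")]
        filtered, report = filter_low_count_wells(dataset.with_wells(wells))
        assert report.excluded == {"P01:A02": "external"}
        assert filtered.wells[1].qc_reason == "external"


class TestSpeciesDetection:
    def test_worked_single_well(self):
        dataset = make_dataset({"P01:A01": [1, 5, 100], "P01:A02": [0, 0, 0]})
        means, per_well = species_detection_summary(dataset, cutoffs=(1, 5, 10, 100))
        assert per_well.loc["P01:A01"].tolist() == [3, 2, 1, 1]
        assert per_well.loc["P01:A02"].tolist() == [0, 0, 0, 0]
        assert means.tolist() == [1.5, 1.0, 0.5, 0.5]

    def test_counts_non_increasing_in_cutoff(self, small_screen):
        dataset, _ = small_screen
        _, per_well = species_detection_summary(dataset, cutoffs=(1, 5, 10, 100))
        diffs = per_well.to_numpy()[:, 1:] - per_well.to_numpy()[:, :-1]
        assert (diffs <= 0).all()

    def test_matches_bruteforce_recount(self, small_screen):
        dataset, _ = small_screen
        means, _ = species_detection_summary(dataset, cutoffs=(5,))
        counts = dataset.counts.counts
        manual = np.mean([(counts[w] >= 5).sum() for w in counts.columns])
        assert means[5] == pytest.approx(manual)

    def test_no_retained_wells_errors(self):
        dataset = make_dataset({"P01:A01": [1], "P01:A02": [1]})
        filtered, _ = filter_low_count_wells(dataset, threshold=10)
        with pytest.raises(ValidationError, match="retained"):
            species_detection_summary(filtered)


def two_batch_expression(values_b1, values_b2):
    wells = []
    data = {}
    for batch, values in (("B1", values_b1), ("B2", values_b2)):
        for i, column in enumerate(values):
            well_id = f"{batch}:{i}"
            wells.append(
                WellRecord(
                    well_id=well_id,
                    plate_id=batch,
                    position=f"A{i + 1:02d}",
                    batch_id=batch,
                    treatment_role="compound",
                    compound_id=f"C{batch}{i}",
                )
            )
            data[well_id] = column
    index = pd.Index([f"m{i}" for i in range(len(values_b1[0]))])
    return pd.DataFrame(data, index=index), wells


class TestCOV:
    def test_constant_series_cov_zero(self):
        expr, wells = two_batch_expression(
            [[100.0], [100.0], [100.0], [100.0]], [[5.0], [5.0]]
        )
        cov = compute_cov(expr, wells)
        assert cov.loc["m0"].tolist() == [0.0, 0.0]

    def test_two_point_cov_arithmetic(self):
        expr, wells = two_batch_expression([[50.0], [150.0]], [[1.0], [1.0]])
        cov = compute_cov(expr, wells)
        assert cov.loc["m0", "B1"] == pytest.approx(0.70710678, abs=1e-6)

    def test_zero_mean_recorded_missing(self):
        expr, wells = two_batch_expression([[0.0], [0.0]], [[1.0], [2.0]])
        cov = compute_cov(expr, wells)
        assert np.isnan(cov.loc["m0", "B1"])

    def test_scale_invariance(self, small_normalized):
        wells = small_normalized.wells
        cpm = small_normalized.cpm
        base = compute_cov(cpm, wells)
        batch1 = [w.well_id for w in wells if w.batch_id == "B1"]
        scaled = cpm.copy()
        scaled[batch1] = scaled[batch1] * 7.5
        assert np.allclose(
            compute_cov(scaled, wells).to_numpy(),
            base.to_numpy(),
            equal_nan=True,
        )

    def test_single_well_batch_errors(self):
        expr, wells = two_batch_expression([[1.0]], [[1.0], [2.0]])
        with pytest.raises(ValidationError, match="single well"):
            compute_cov(expr, wells)

    def test_cov_ordering_matches_dispersion(self, rng):
        """Planted dispersion gradient is recovered in COV order."""
        sds = [0.01, 0.05, 0.2, 0.8]
        data = {
            f"B1:{j}": [100.0 * np.exp(rng.normal(0, sd)) for sd in sds]
            for j in range(40)
        }
        expr = pd.DataFrame(data, index=[f"m{i}" for i in range(4)])
        wells = [
            WellRecord(
                well_id=f"B1:{j}",
                plate_id="P01",
                position=f"A{(j % 12) + 1:02d}",
                batch_id="B1",
                treatment_role="compound",
                compound_id=f"C{j}",
            )
            for j in range(40)
        ]
        cov = compute_cov(expr, wells)["B1"]
        assert list(cov.sort_values().index) == ["m0", "m1", "m2", "m3"]


class TestHousekeeping:
    def _cov_table(self):
        return pd.DataFrame(
            {
                "B1": [0.05, 0.10, 0.50, 0.60, 0.01],
                "B2": [0.06, 0.09, 0.55, 0.08, 0.02],
            },
            index=["m0", "m1", "m2", "m3", "m4"],
        )

    def test_lowest_cov_intersection(self):
        # B1 top-3: m4, m0, m1; B2 top-3: m4, m0, m3 -> intersection {m0, m4}
        report = select_housekeeping(self._cov_table(), k=3)
        assert report.selected == ["m0", "m4"]
        assert report.per_batch_top["B1"] == ["m4", "m0", "m1"]
        assert report.per_batch_top["B2"] == ["m4", "m0", "m3"]

    def test_k_all_returns_shared_set(self):
        report = select_housekeeping(self._cov_table(), k=5)
        assert report.selected == ["m0", "m1", "m2", "m3", "m4"]

    def test_empty_intersection_warns_not_raises(self):
        table = pd.DataFrame({"B1": [0.1, 0.9], "B2": [0.9, 0.1]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="empty"):
            report = select_housekeeping(table, k=1)
        assert report.selected == []

    def test_planted_low_dispersion_selected(self):
        """3 planted stable miRNAs among 100 found at k=5 in >=95% of runs."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n, wells_per_batch = 100, 12
            stable = ["m001", "m002", "m003"]
            covs = {}
            for batch in ("B1", "B2", "B3"):
                sds = rng.uniform(0.2, 0.8, n)
                sds[:3] = 0.02  # planted housekeeping trio
                samples = 100 * np.exp(
                    rng.normal(0, sds[:, None], (n, wells_per_batch))
                )
                covs[batch] = samples.std(axis=1, ddof=1) / samples.mean(axis=1)
            table = pd.DataFrame(covs, index=[f"m{i + 1:03d}" for i in range(n)])
            report = select_housekeeping(table, k=5)
            hits += int(set(stable) <= set(report.selected))
        assert hits / reps >= 0.95


class TestDepositionSummary:
    def test_synthetic_screen_statistics(self, small_screen):
        dataset, truth = small_screen
        out = deposition_summary(dataset, focus_mirna="miR-050")
        assert out["n_excluded"] == len(truth.failed_wells)
        assert out["mean_reads_retained"] > 10_000
        assert 0 < out["mean_species_cutoff1"] <= 60
        # the co-regulated analog is planted among the most abundant species
        assert out["focus_rank_vehicle"] <= 10
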