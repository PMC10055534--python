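"""Waterfall ranking, hit selection, class profiles and correlation maps."""

import numpy as np
import pandas as pd
import pytest

from mirscreen.hit_discovery import (
    class_profile,
    mirna_correlation_map,
    select_hits,
    top_correlates,
    waterfall_rank,
)
from mirscreen.normalize import NormalizedScreen
from mirscreen.plate_io import CompoundAnnotation, ValidationError, WellRecord


def make_normalized(log2fc: pd.DataFrame, roles: dict, batches: dict | None = None):
    """NormalizedScreen directly from a log2fc layer (cpm = fold change x 1e3)."""
    wells = []
    for i, well_id in enumerate(log2fc.columns):
        role = roles.get(well_id, "compound")
        wells.append(
            WellRecord(
                well_id=well_id,
                plate_id=(batches or {}).get(well_id, "P01"),
                position=f"A{(i % 12) + 1:02d}",
                batch_id=(batches or {}).get(well_id, "B1"),
                treatment_role=role,
                compound_id=f"cmp_{well_id}" if role == "compound" else "",
            )
        )
    fc = 2.0**log2fc
    return NormalizedScreen(
        cpm=fc * 1e3,
        fold_change=fc,
        log2fc=log2fc,
        wells=wells,
        pseudocount=1.0,
        baseline="geometric_mean",
    )


class TestWaterfall:
    def _norm(self):
        log2fc = pd.DataFrame(
            {
                "w1": [np.log2(3.0), 0.0],
                "w2": [0.0, 0.1],
                "w3": [-1.0, 0.2],
                "w0": [2.0, 0.0],
            },
            index=["miR-132", "miR-007"],
        )
        return make_normalized(log2fc, roles={"w0": "vehicle"})

    def test_descending_rank_order(self):
        result = waterfall_rank(self._norm(), "miR-132")
        plate = result.plates["B1"]
        assert plate["compound_id"].tolist() == ["cmp_w1", "cmp_w2", "cmp_w3"]
        assert plate["rank"].tolist() == [1, 2, 3]

    def test_controls_annotated_but_unranked(self):
        result = waterfall_rank(self._norm(), "miR-132")
        assert "cmp_w0" not in set(result.plates["B1"]["compound_id"])
        assert result.controls["well_id"].tolist() == ["w0"]

    def test_tie_broken_lexicographically(self):
        log2fc = pd.DataFrame({"wb": [1.0], "wa": [1.0], "w0": [0.0]}, index=["m"])
        norm = make_normalized(log2fc, roles={"w0": "vehicle"})
        first = waterfall_rank(norm, "m").plates["B1"]
        second = waterfall_rank(norm, "m").plates["B1"]
        assert first["compound_id"].tolist() == ["cmp_wa", "cmp_wb"]
        assert first.equals(second)

    def test_ranks_are_permutation(self, small_normalized):
        result = waterfall_rank(small_normalized, "miR-050")
        for plate in result.plates.values():
            assert sorted(plate["rank"]) == list(range(1, len(plate) + 1))

    def test_unknown_mirna_errors(self):
        with pytest.raises(ValidationError, match="nope"):
            waterfall_rank(self._norm(), "nope")


class TestSelectHits:
    def _setup(self, specificity_rows=None, two_plates=False):
        data = {
            "w1": [1.8, 0.0, 0.0],
            "w2": [1.8, 0.0, 0.0],
            "w3": [0.4, 0.0, 0.0],
            "w0": [0.0, 0.0, 0.0],
        }
        if specificity_rows is not None:
            for well, values in specificity_rows.items():
                data[well][1:] = values
        log2fc = pd.DataFrame(data, index=["miR-132", "miR-100", "miR-101"])
        # two_plates puts the tied inducers on separate plates so both hold
        # plate rank 1 and only secondary criteria can order them
        batches = {"w2": "B2"} if two_plates else None
        norm = make_normalized(log2fc, roles={"w0": "vehicle"}, batches=batches)
        waterfall = waterfall_rank(norm, "miR-132")
        return norm, waterfall

    def test_bbb_breaks_rank_tie(self):
        norm, waterfall = self._setup(two_plates=True)
        annotations = {
            "cmp_w1": CompoundAnnotation(compound_id="cmp_w1"),
            "cmp_w2": CompoundAnnotation(compound_id="cmp_w2", bbb_permeable="yes"),
        }
        table = select_hits(waterfall, annotations, norm)
        assert table["compound_id"].tolist()[:2] == ["cmp_w2", "cmp_w1"]

    def test_specific_inducer_beats_global_shifter(self):
        norm, waterfall = self._setup(
            specificity_rows={"w2": [1.5, 1.5]},  # w2 moves other miRNAs too
            two_plates=True,
        )
        table = select_hits(waterfall, {}, norm)
        assert table["compound_id"].tolist()[:2] == ["cmp_w1", "cmp_w2"]
        w2 = table.set_index("compound_id").loc["cmp_w2"]
        assert w2["specificity"] == 2

    def test_top_n_larger_than_library(self):
        norm, waterfall = self._setup()
        table = select_hits(waterfall, {}, norm, top_n=1000)
        assert len(table) == 3

    def test_unannotated_fail_all_secondary(self):
        norm, waterfall = self._setup()
        table = select_hits(waterfall, {}, norm).set_index("compound_id")
        assert not table["annotated"].any()
        assert (table["n_secondary"] == 0).all()


class TestClassProfile:
    def _norm(self, n_compounds=60, n_mirnas=5, seed=0, planted=()):
        rng = np.random.default_rng(seed)
        cols = {f"w{i}": rng.normal(0, 0.2, n_mirnas) for i in range(n_compounds)}
        log2fc = pd.DataFrame(cols, index=[f"m{i}" for i in range(n_mirnas)])
        log2fc["w_v"] = 0.0
        for well in planted:
            log2fc.loc["m0", well] += 1.0
        return make_normalized(log2fc, roles={"w_v": "vehicle"})

    def test_uniform_members_give_exact_median(self):
        members = ["cmp_w0", "cmp_w1", "cmp_w2", "cmp_w3", "cmp_w4"]
        norm = self._norm(planted=["w0", "w1", "w2", "w3", "w4"])
        profile = class_profile(
            norm, {}, classes={"planted": members}, B=200, seed=1
        )["planted"]
        observed = profile.table.loc["m0", "median_log2fc"]
        manual = np.median(
            [norm.log2fc.loc["m0", w] for w in ("w0", "w1", "w2", "w3", "w4")]
        )
        assert observed == pytest.approx(manual)

    def test_pvalues_never_zero_and_bounded(self):
        norm = self._norm(planted=["w0", "w1", "w2", "w3", "w4"])
        members = ["cmp_w0", "cmp_w1", "cmp_w2", "cmp_w3", "cmp_w4"]
        profile = class_profile(
            norm, {}, classes={"planted": members}, B=500, seed=1
        )["planted"]
        p = profile.table["p_value"]
        assert ((p > 0) & (p <= 1)).all()
        assert p.min() >= 1.0 / 501

    def test_small_B_rejected(self):
        norm = self._norm()
        with pytest.raises(ValueError, match="B"):
            class_profile(norm, {}, classes={"c": ["cmp_w0"] * 5}, B=50, seed=0)

    def test_undersized_class_skipped_with_warning(self):
        norm = self._norm()
        with pytest.warns(UserWarning, match="skipped"):
            profiles = class_profile(
                norm, {}, classes={"tiny": ["cmp_w0", "cmp_w1"]}, B=200, seed=0
            )
        assert profiles == {}

    def test_annotation_multilabel_classes(self):
        norm = self._norm(n_compounds=12)
        annotations = {
            f"cmp_w{i}": CompoundAnnotation(
                compound_id=f"cmp_w{i}",
                target_class="kinase inhibitor; antiviral" if i < 6 else "antiviral",
            )
            for i in range(12)
        }
        profiles = class_profile(norm, annotations, min_class_size=5, B=200, seed=0)
        assert set(profiles) == {"kinase inhibitor", "antiviral"}
        assert profiles["antiviral"].n_members == 12
        assert profiles["kinase inhibitor"].n_members == 6


class TestCorrelationMap:
    def _norm(self, seed=0):
        rng = np.random.default_rng(seed)
        shared = rng.normal(0, 1, 60)
        log2fc = pd.DataFrame(
            {
                f"w{i}": [
                    shared[i] + rng.normal(0, 0.3),
                    shared[i] + rng.normal(0, 0.3),
                    -shared[i] + rng.normal(0, 0.3),
                    rng.normal(0, 1),
                    0.0,  # zero-variance miRNA
                ]
                for i in range(60)
            },
            index=["coregA", "coregB", "anti", "indep", "flat"],
        )
        return make_normalized(log2fc, roles={})

    def test_symmetry_unit_diagonal_and_range(self):
        cmap = mirna_correlation_map(self._norm(), subset=None)
        m = cmap.matrix
        finite = m.to_numpy()[np.isfinite(m.to_numpy())]
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.all(np.diag(m) == 1.0)
        assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()

    def test_zero_variance_missing_not_zero(self):
        cmap = mirna_correlation_map(self._norm(), subset=None)
        off_diag = cmap.matrix.loc["flat"].drop("flat")
        assert off_diag.isna().all()

    def test_planted_coregulation_and_independence(self):
        cmap = mirna_correlation_map(self._norm(), subset=None)
        assert cmap.matrix.loc["coregA", "coregB"] > 0.8
        assert abs(cmap.matrix.loc["coregA", "indep"]) < 0.3

    def test_abundance_subset_selection(self, small_normalized):
        cmap = mirna_correlation_map(small_normalized, subset=10)
        top10 = (
            small_normalized.cpm.mean(axis=1).sort_values(ascending=False).index[:10]
        )
        assert list(cmap.matrix.index) == list(top10)

    def test_too_few_compound_wells(self):
        log2fc = pd.DataFrame({"w0": [0.1], "w1": [0.2]}, index=["m"])
        norm = make_normalized(log2fc, roles={})
        with pytest.raises(ValidationError, match="3 compound wells"):
            mirna_correlation_map(norm)


class TestTopCorrelates:
    def test_self_excluded_and_planted_negative_found(self):
        cmap = mirna_correlation_map(TestCorrelationMap()._norm(), subset=None)
        positive, negative = top_correlates(cmap, "coregA", k=3)
        names_pos = [m for m, _ in positive]
        names_neg = [m for m, _ in negative]
        assert "coregA" not in names_pos + names_neg
        assert names_pos[0] == "coregB"
        assert names_neg[0] == "anti"

    def test_k_truncation(self):
        cmap = mirna_correlation_map(TestCorrelationMap()._norm(), subset=None)
        positive, negative = top_correlates(cmap, "coregA", k=50)
        assert len(positive) + len(negative) <= 4  # flat is NaN, self excluded
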