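"""Unit and property tests for the five-category capillary rubric."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capscore.config import ActivationConfig, ScoringThresholds
from capscore.errors import ConfigError, InvalidInputError
from capscore.rubric import (
    AS_CATEGORIES,
    CapillaryFeatures,
    CapillaryScore,
    TriObservation,
    score_bm_reduplication,
    score_bm_thickening,
    score_capillary,
    score_endothelial_activation,
    score_ensheathment,
    score_features_frame,
    score_tri,
)


class TestBmThickening:
    @pytest.mark.parametrize(
        "thickness, expected",
        [
            (75, 0),  # inside the normal 50–100 nm band
            (150, 1),  # mild thickening 100–200 nm
            (250, 2),  # 200+ nm
            (100, 1),  # half-open boundary: 100 enters the mild band
            (200, 2),  # half-open boundary: "200+" includes 200
            (99.999, 0),
            (30, 0),  # thinner than normal is not pathological thickening
        ],
    )
    def test_bands(self, thickness, expected):
        assert score_bm_thickening(thickness) == expected

    @pytest.mark.parametrize("bad", [0, -10, float("nan"), float("inf"), None, "wide"])
    def test_invalid_thickness_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            score_bm_thickening(bad)

    def test_custom_thresholds(self):
        t = ScoringThresholds(bm_cut_1_nm=80, bm_cut_2_nm=160)
        assert score_bm_thickening(90, t) == 1
        assert score_bm_thickening(160, t) == 2

    @given(st.floats(min_value=1e-3, max_value=1e4), st.floats(min_value=0.0, max_value=500.0))
    def test_monotone_nondecreasing(self, thickness, bump):
        assert score_bm_thickening(thickness + bump) >= score_bm_thickening(thickness)


class TestBmReduplication:
    @pytest.mark.parametrize(
        "layers, expected",
        [(1, 0), (2, 1), (3, 1), (4, 2), (5, 2), (10, 2)],
    )
    def test_bands(self, layers, expected):
        assert score_bm_reduplication(layers) == expected

    @pytest.mark.parametrize("bad", [0, -1, 1.5, "two", None])
    def test_invalid_layer_count_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            score_bm_reduplication(bad)

    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=10))
    def test_monotone_nondecreasing(self, layers, bump):
        assert score_bm_reduplication(layers + bump) >= score_bm_reduplication(layers)


class TestEndothelialActivation:
    @pytest.mark.parametrize("grade, expected", [("none", 0), ("mild", 1), ("marked", 2)])
    def test_explicit_grade(self, grade, expected):
        f = CapillaryFeatures(activation_grade=grade)
        assert score_endothelial_activation(f) == expected

    def test_raw_pair_exhaustive_grid(self):
        """The (area band x organelle level) grid follows the max rule.

        Oracle: independent enumeration of the expected score for every
        combination of area band and organelle level.
        """
        cfg = ActivationConfig(reference_area_um2=5.0, mild_ratio=1.5, marked_ratio=3.0)
        area_bands = [(1.0, 0), (1.49, 0), (1.5, 1), (2.0, 1), (2.99, 1), (3.0, 2), (4.5, 2)]
        organelles = [("none", 0), ("increased", 1), ("marked", 2)]
        for (ratio, area_score), (org, org_score) in itertools.product(area_bands, organelles):
            f = CapillaryFeatures(
                endothelial_area_um2=ratio * cfg.reference_area_um2, organelle_prominence=org
            )
            assert score_endothelial_activation(f, cfg) == max(area_score, org_score)

    def test_double_reference_area_with_increased_organelles_is_mild(self):
        f = CapillaryFeatures(endothelial_area_um2=10.0, organelle_prominence="increased")
        assert score_endothelial_activation(f, ActivationConfig(reference_area_um2=5.0)) == 1

    def test_missing_both_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            score_endothelial_activation(CapillaryFeatures())


class TestEnsheathment:
    @pytest.mark.parametrize(
        "count, prominence, expected",
        [
            (3, "prominent", 0),  # 1–4 processes: no prominent ensheathment
            (6, "prominent", 1),  # 5–6 processes
            (8, "very_prominent", 2),  # 7+ processes
            (0, "focal_small", 0),
            (4, "prominent", 0),
            (5, "prominent", 1),
            (7, "prominent", 2),
            (5, "focal_small", 0),  # only focal and small demotes one level
            (8, "focal_small", 1),
        ],
    )
    def test_bands_and_size_qualifier(self, count, prominence, expected):
        assert score_ensheathment(count, prominence) == expected

    @pytest.mark.parametrize("bad", [-1, 2.5, None])
    def test_invalid_count_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            score_ensheathment(bad, "prominent")

    def test_unknown_prominence_rejected(self):
        with pytest.raises(ValueError):
            score_ensheathment(5, "gigantic")


class TestTri:
    @pytest.mark.parametrize(
        "obs, expected",
        [
            ([], 0),
            ([("small", 1)], 0),  # a single small inclusion stays below threshold
            ([("small", 2)], 1),
            ([("medium", 1)], 1),
            ([("medium", 2)], 2),
            ([("large", 1)], 2),
            ([("small", 5)], 1),
            ([("small", 2), ("medium", 1)], 1),
            ([("small", 1), ("large", 1)], 2),
            ([("medium", 1), ("medium", 1)], 2),  # split observations accumulate
        ],
    )
    def test_thresholds(self, obs, expected):
        tri = [TriObservation(size_class=s, count=c) for s, c in obs]
        assert score_tri(tri) == expected

    def test_unknown_size_class_rejected(self):
        with pytest.raises(ValueError):
            TriObservation(size_class="gigantic", count=1)

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidInputError):
            TriObservation(size_class="small", count=0)


def _features(thickness, layers, grade, procs, prominence, tri):
    return CapillaryFeatures(
        bm_thickness_nm=thickness,
        bm_layer_count=layers,
        activation_grade=grade,
        process_count=procs,
        process_prominence=prominence,
        tri=tri,
    )


class TestScoreCapillary:
    @pytest.mark.parametrize(
        "features, expected",
        [
            (  # composition of the five maximal clauses
                _features(250, 5, "marked", 8, "very_prominent", [TriObservation("large")]),
                (2, 2, 2, 2, 2),
            ),
            (  # all-normal capillary
                _features(75, 1, "none", 2, "prominent", []),
                (0, 0, 0, 0, 0),
            ),
            (  # composition of the five intermediate clauses
                _features(150, 2, "mild", 5, "prominent", [TriObservation("medium")]),
                (1, 1, 1, 1, 1),
            ),
        ],
    )
    def test_worked_compositions(self, features, expected):
        s = score_capillary(features)
        got = (s.bm_thickening, s.bm_reduplication, s.endothelial_activation, s.ensheathment, s.tri)
        assert got == expected
        assert s.four_category_sum == sum(expected[:4])

    def test_sum_excludes_tri(self):
        s = score_capillary(_features(75, 1, "none", 2, "prominent", [TriObservation("large")]))
        assert s.tri == 2
        assert s.four_category_sum == 0

    def test_degraded_partial_scoring(self):
        """A degraded capillary is scored on what remains measurable."""
        f = CapillaryFeatures(bm_thickness_nm=220, bm_layer_count=2, degraded=True)
        s = score_capillary(f)
        assert s.bm_thickening == 2 and s.bm_reduplication == 1
        assert "endothelial_activation" in s.missing and "ensheathment" in s.missing
        assert s.four_category_sum == 3
        assert not s.fully_missing

    def test_fully_unmeasurable_capillary_flagged(self):
        s = score_capillary(CapillaryFeatures(tri=()))
        assert s.fully_missing

    def test_error_names_offending_category(self):
        f = _features(-5, 1, "none", 0, "prominent", [])
        with pytest.raises(InvalidInputError, match="bm_thickening"):
            score_capillary(f)

    @given(
        st.floats(min_value=1, max_value=1000),
        st.integers(min_value=1, max_value=12),
        st.sampled_from(["none", "mild", "marked"]),
        st.integers(min_value=0, max_value=15),
        st.sampled_from(["focal_small", "prominent", "very_prominent"]),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=0, max_value=2),
    )
    def test_scores_always_valid_and_sum_consistent(
        self, thickness, layers, grade, procs, prominence, n_small, n_medium, n_large
    ):
        tri = [
            TriObservation(s, c)
            for s, c in (("small", n_small), ("medium", n_medium), ("large", n_large))
            if c > 0
        ]
        s = score_capillary(_features(thickness, layers, grade, procs, prominence, tri))
        for cat in AS_CATEGORIES + ("tri",):
            assert getattr(s, cat) in (0, 1, 2)
        assert s.four_category_sum == sum(getattr(s, c) for c in AS_CATEGORIES)
        assert 0 <= s.four_category_sum <= 8


class TestBatchScoring:
    def test_batch_equals_scalar_on_grid(self):
        """Vectorised scoring must agree exactly with the scalar scorers on
        a dense grid of feature combinations."""
        thicknesses = [60.0, 100.0, 150.0, 199.9, 200.0, 300.0]
        layer_counts = [1, 2, 3, 4, 6]
        grades = ["none", "mild", "marked"]
        procs = [0, 4, 5, 6, 7, 9]
        proms = ["focal_small", "prominent", "very_prominent"]
        tris = [(0, 0, 0), (2, 0, 0), (0, 1, 0), (0, 2, 0), (0, 0, 1)]
        rows = [
            dict(
                bm_thickness_nm=t, bm_layer_count=l, activation_grade=g,
                process_count=p, process_prominence=pr,
                tri_small=ts, tri_medium=tm, tri_large=tl,
            )
            for t, l, g, p, pr, (ts, tm, tl) in itertools.product(
                thicknesses, layer_counts, grades, procs, proms, tris
            )
        ]
        frame = pd.DataFrame(rows)
        batch = score_features_frame(frame)
        for i, row in enumerate(rows):
            tri = [
                TriObservation(s, c)
                for s, c in (
                    ("small", row["tri_small"]),
                    ("medium", row["tri_medium"]),
                    ("large", row["tri_large"]),
                )
                if c
            ]
            scalar = score_capillary(
                _features(
                    row["bm_thickness_nm"], row["bm_layer_count"], row["activation_grade"],
                    row["process_count"], row["process_prominence"], tri,
                )
            )
            for cat in AS_CATEGORIES + ("tri",):
                assert batch.iloc[i][cat] == getattr(scalar, cat), (i, cat)

    def test_missing_values_mark_categories_missing(self):
        frame = pd.DataFrame(
            [
                {"bm_thickness_nm": 250.0},
                {"process_count": 8},
                {},
            ]
        )
        batch = score_features_frame(frame)
        assert batch.loc[0, "bm_thickening"] == 2
        assert batch.loc[0, "four_category_sum"] == 2
        assert batch.loc[1, "ensheathment"] == 2
        assert bool(batch.loc[2, "fully_missing"])
        assert not bool(batch.loc[0, "fully_missing"])


def test_threshold_config_validation():
    with pytest.raises(ConfigError):
        ScoringThresholds(bm_cut_1_nm=300, bm_cut_2_nm=200)


def test_capillary_score_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        CapillaryScore(3, 0, 0, 0, 0)
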