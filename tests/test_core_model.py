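"""Core model equations: rank normalization, coefficients, piecewise dispatch."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leafpart as lp
from leafpart.errors import (
    ClampedValueWarning,
    ClippedPredictionWarning,
    DomainError,
    OutOfDomainError,
)
from leafpart.stages import CoarseStage, FineStage, COARSE_OF


class TestNormalizeLeafRank:
    @pytest.mark.parametrize(
        "rank,total,expected",
        [(5, 10, 0.5), (10, 10, 1.0), (1, 24, 1 / 24), (1, 1, 1.0)],
    )
    def test_values(self, rank, total, expected):
        assert lp.normalize_leaf_rank(rank, total) == pytest.approx(expected)

    @pytest.mark.parametrize("rank,total", [(0, 10), (11, 10), (1, 0), (-3, 5)])
    def test_domain_errors(self, rank, total):
        with pytest.raises(DomainError):
            lp.normalize_leaf_rank(rank, total)

    @given(total=st.integers(1, 60), rank=st.integers(1, 60))
    def test_result_in_unit_interval(self, total, rank):
        rank = min(rank, total)
        value = lp.normalize_leaf_rank(rank, total)
        assert 0.0 < value <= 1.0


class TestPcFromBiomass:
    @pytest.mark.parametrize(
        "biomass,expected",
        [([2, 2], [0.5, 0.5]), ([1, 1, 2], [0.25, 0.25, 0.5]), ([7.5], [1.0])],
    )
    def test_values(self, biomass, expected):
        np.testing.assert_allclose(lp.pc_from_biomass(biomass), expected)

    @pytest.mark.parametrize("bad", [[0, 0], [], [1, -1]])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            lp.pc_from_biomass(bad)

    @given(
        st.lists(st.floats(1e-6, 1e3, allow_nan=False), min_size=1, max_size=40)
    )
    def test_conservation(self, biomass):
        """Coefficients are shares of a total: they always sum to one."""
        assert lp.pc_from_biomass(biomass).sum() == pytest.approx(1.0, abs=1e-9)


class TestPredictNlr:
    def test_endpoint_equals_intercept(self, params):
        # ln(1) = 0 leaves only the intercept
        assert lp.predict_nlr(1.0, params) == 0.900

    def test_hand_evaluation_at_inverse_e(self, params):
        assert lp.predict_nlr(math.exp(-1), params) == pytest.approx(0.282)

    @pytest.mark.parametrize("bad", [0.0, -0.5])
    def test_log_singularity(self, bad):
        with pytest.raises(DomainError):
            lp.predict_nlr(bad)

    def test_clamps_low_predictions_with_warning(self, params):
        with pytest.warns(ClampedValueWarning):
            value = lp.predict_nlr(0.05, params)
        assert value == pytest.approx(1e-6)

    def test_unclamped_value_is_returned_on_request(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            raw = lp.predict_nlr(0.05, params, clamp=False)
        assert raw < 0

    def test_monotone_in_development_time(self, params):
        grid = np.linspace(0.05, 1.0, 200)
        values = [lp.predict_nlr(t, params, clamp=False) for t in grid]
        assert np.all(np.diff(values) > 0)


class TestClassifyStage:
    @pytest.mark.parametrize(
        "ndpd,coarse",
        [
            (0.30, CoarseStage.EARLIER),
            (0.50, CoarseStage.MID),
            (0.90, CoarseStage.LATE),
            (0.0, CoarseStage.EARLIER),
            (0.428, CoarseStage.MID),
            (0.640, CoarseStage.LATE),
            (1.0, CoarseStage.LATE),
        ],
    )
    def test_coarse_windows(self, ndpd, coarse):
        assert lp.classify_stage(ndpd).coarse is coarse

    def test_fine_maps_to_matching_coarse(self):
        for t in np.linspace(0.0, 1.0, 101):
            stage = lp.classify_stage(float(t))
            assert COARSE_OF[stage.fine] is stage.coarse

    def test_maturity_at_one(self):
        assert lp.classify_stage(1.0).fine is FineStage.MATURE

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            lp.classify_stage(bad)

    def test_custom_boundaries(self):
        b = lp.StageBoundaries(earlier_end=0.3, mid_end=0.6, mature_onset=0.8)
        assert lp.classify_stage(0.35, b).coarse is CoarseStage.MID
        assert lp.classify_stage(0.85, b).fine is FineStage.MATURE


class TestPredictPc:
    def test_mature_endpoint_equals_intercept(self, params):
        assert lp.predict_pc("mature", 1.0, params) == 0.024

    def test_early_seedling_hand_value(self, params):
        # 1.836 * 0.20 - 0.162
        assert lp.predict_pc("early_seedling", 0.20, params) == pytest.approx(0.2052)

    def test_out_of_domain_error_carries_intervals(self, params):
        with pytest.raises(OutOfDomainError) as exc:
            lp.predict_pc("mature", 0.30, params)
        assert exc.value.intervals
        assert "0.71" in str(exc.value)

    def test_negative_prediction_clipped_and_flagged(self, params):
        # the late-blooming parabola dips below zero close to the top rank
        with pytest.warns(ClippedPredictionWarning):
            assert lp.predict_pc("late_blooming", 0.999, params) == 0.0
        assert lp.predict_pc("late_blooming", 0.999, params, clip_negative=False) < 0

    def test_dispatch_is_total_and_unambiguous(self, params):
        """Exactly one piece claims every point of each stage's rank union."""
        for stage, pieces in params.stage_pieces.items():
            lo = pieces[0].domain.lo
            hi = pieces[-1].domain.hi
            grid = np.arange(lo, hi + 5e-4, 1e-3)
            breakpoints = [p.domain.lo for p in pieces] + [p.domain.hi for p in pieces]
            for x in list(grid) + breakpoints:
                claims = [p for p in pieces if p.domain.contains(x)]
                in_union = (
                    (x > lo if pieces[0].domain.lo_open else x >= lo)
                    and (x < hi if pieces[-1].domain.hi_open else x <= hi)
                )
                assert len(claims) == (1 if in_union else 0), (stage, x)

    def test_finite_on_every_declared_domain(self, params):
        for stage, pieces in params.stage_pieces.items():
            for piece in pieces:
                grid = np.arange(piece.domain.lo, piece.domain.hi + 5e-4, 1e-3)
                grid = grid[piece.domain.contains(grid)]
                values = piece.evaluate(grid, params.coefficients)
                assert np.all(np.isfinite(values)), stage

    def test_breakpoint_belongs_to_upper_piece(self, params):
        # 0.24 is the early-seedling breakpoint: evaluated on the second piece
        expected = -1.256 * 0.24 + 0.506
        assert lp.predict_pc("early_seedling", 0.24, params) == pytest.approx(expected)


class TestPredictProfile:
    def test_out_of_domain_ranks_are_missing(self, params):
        prof = lp.predict_profile("mature", 4, params)
        assert list(prof["in_domain"]) == [False, False, True, True]
        assert prof["pc_pred"].isna().tolist() == [True, True, False, False]

    def test_renormalized_profile_sums_to_one(self, params):
        for stage in FineStage:
            prof = lp.predict_profile(stage, 20, params, renormalize=True)
            total = prof.loc[prof["in_domain"], "pc_pred"].sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_leaves_rejected(self):
        with pytest.raises(DomainError):
            lp.predict_profile("mature", 0)

    def test_biomass_round_trip(self, params):
        """Scaling a profile by any positive total and renormalizing returns it."""
        prof = lp.predict_profile("bolting", 18, params, renormalize=True)
        kept = prof[prof["in_domain"]]
        biomass = kept["pc_pred"].to_numpy() * 37.5
        np.testing.assert_allclose(
            lp.pc_from_biomass(biomass), kept["pc_pred"], atol=1e-9
        )
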