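"""Least-squares machinery: forms, piece dispatch, form selection, recovery."""

import numpy as np
import pytest

from leafpart import fit_form, fit_piecewise, parameter_recovery, select_form
from leafpart.errors import DomainError, FitError
from leafpart.fitting import RecoveryDesign, fit_observations, observations_to_pc
from leafpart.params import Form, evaluate_form
from leafpart.stages import FineStage


def normal_equations(X, y):
    """Independent closed-form OLS solve for cross-checking fits."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitForm:
    def test_exact_line(self):
        x = np.linspace(0, 1, 12)
        res = fit_form(x, 2 * x + 1, "linear")
        np.testing.assert_allclose(res.estimates, [2, 1], atol=1e-12)
        assert res.r == pytest.approx(1.0)

    def test_exact_proportional_power(self):
        x = np.linspace(0.1, 1, 15)
        res = fit_form(x, 3 * x, "power")
        np.testing.assert_allclose(res.estimates, [3, 1], atol=1e-8)

    def test_noisy_quadratic_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.random(50)
        y = 1.5 * x**2 - 0.7 * x + 0.2 + rng.normal(0, 0.05, 50)
        res = fit_form(x, y, "quadratic")
        X = np.column_stack([x**2, x, np.ones_like(x)])
        np.testing.assert_allclose(res.estimates, normal_equations(X, y), atol=1e-8)

    def test_noisy_logarithmic_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.05, 1, 80)
        y = 0.6 * np.log(x) + 0.9 + rng.normal(0, 0.1, 80)
        res = fit_form(x, y, "logarithmic")
        X = np.column_stack([np.log(x), np.ones_like(x)])
        np.testing.assert_allclose(res.estimates, normal_equations(X, y), atol=1e-10)

    def test_r_equals_independent_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.random(40)
        y = x + rng.normal(0, 0.2, 40)
        res = fit_form(x, y, "linear")
        fitted = res.estimates[0] * x + res.estimates[1]
        assert res.r == pytest.approx(np.corrcoef(fitted, y)[0, 1], abs=1e-12)

    def test_significance_fields_populated(self):
        rng = np.random.default_rng(6)
        x = rng.random(60)
        y = 2 * x + rng.normal(0, 0.1, 60)
        res = fit_form(x, y, "linear")
        assert res.p_values.shape == (2,)
        assert res.p_values[0] < 1e-6  # strong slope
        assert res.f_stat > 0 and res.f_pvalue < 1e-6

    def test_constant_x_is_singular(self):
        with pytest.raises(FitError):
            fit_form(np.ones(10), np.arange(10.0), "linear")

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_form([1.0, 2.0], [1.0, 2.0], "linear")

    def test_nonpositive_x_rejected_for_transforms(self):
        with pytest.raises(DomainError):
            fit_form([-1.0, 0.5, 1.0], [1.0, 2.0, 3.0], "logarithmic")


class TestSelectForm:
    def test_parsimony_tie_break_on_exact_line(self):
        x = np.linspace(0.1, 1, 20)
        form, _ = select_form(x, 2 * x + 1, ["linear", "quadratic"])
        assert form is Form.LINEAR

    def test_exact_logarithmic_data(self):
        x = np.linspace(0.1, 1, 20)
        form, _ = select_form(x, 0.6 * np.log(x) + 0.9)
        assert form is Form.LOGARITHMIC

    def test_winner_matches_brute_force_sweep(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.1, 1, 60)
        y = 0.5 * x**1.7 + rng.normal(0, 0.02, 60)
        candidates = list(Form)
        form, best = select_form(x, y, candidates)
        sweep = {}
        for c in candidates:
            try:
                sweep[c] = abs(fit_form(x, y, c).r)
            except (FitError, DomainError):
                pass
        assert abs(best.r) == pytest.approx(max(sweep.values()))

    def test_all_failures_aggregate(self):
        with pytest.raises(FitError):
            select_form([-1.0, -0.5, 0.0, 0.5], [1.0, 2.0, 3.0, 4.0], ["logarithmic", "power"])


class TestFitPiecewise:
    @pytest.mark.parametrize("stage", list(FineStage))
    def test_noiseless_refit_recovers_every_stage_model(self, params, stage):
        """Sampling each piece's own curve and refitting returns its coefficients."""
        pieces = params.stage_pieces[stage]
        rng = np.random.default_rng(11)
        xs, ys = [], []
        for piece in pieces:
            x = piece.domain.lo + (piece.domain.hi - piece.domain.lo) * rng.random(40)
            x = x[piece.domain.contains(x)]
            xs.append(x)
            ys.append(piece.evaluate(x, params.coefficients))
        nlr = np.concatenate(xs)
        pc = np.concatenate(ys)
        for piece, fit in zip(pieces, fit_piecewise(nlr, pc, pieces)):
            assert fit.ok, fit.error
            np.testing.assert_allclose(
                fit.result.estimates, params.coeffs_for(piece), atol=1e-8
            )

    def test_breakpoint_observation_goes_to_upper_piece(self, params):
        pieces = params.stage_pieces[FineStage.EARLY_SEEDLING]
        nlr = np.array([0.24, 0.25, 0.30, 0.35, 0.12, 0.15, 0.20])
        pc = np.zeros_like(nlr)
        fits = fit_piecewise(nlr, pc, pieces)
        assert fits[0].n == 3  # 0.12, 0.15, 0.20
        assert fits[1].n == 4  # 0.24 joins the upper piece

    def test_empty_piece_reports_failure_without_crashing(self, params):
        pieces = params.stage_pieces[FineStage.BOLTING]
        nlr = np.linspace(0.55, 0.95, 30)  # upper piece only
        pc = 0.605 * nlr**2 - 1.130 * nlr + 0.531
        fits = fit_piecewise(nlr, pc, pieces)
        assert not fits[0].ok and "insufficient" in fits[0].error
        assert fits[1].ok


class TestParameterRecovery:
    def test_noiseless_recovery_is_exact(self, params):
        report = parameter_recovery(params, noise_sd=0.0, reps=1, seed=1)
        assert report["error"].isna().all()
        assert np.nanmax(np.abs(report["bias"])) < 1e-8

    def test_fixed_seed_is_reproducible(self):
        design = RecoveryDesign(targets=("mature",), n=60)
        a = parameter_recovery(design=design, noise_sd=0.05, reps=3, seed=123)
        b = parameter_recovery(design=design, noise_sd=0.05, reps=3, seed=123)
        assert a.equals(b)

    def test_error_shrinks_along_noise_ladder(self):
        """With a shared seed the recovery error scales down with the noise."""
        design = RecoveryDesign(targets=("nlr",), n=300)
        errors = []
        for sd in (0.30, 0.10, 0.02):
            rep = parameter_recovery(design=design, noise_sd=sd, reps=3, seed=77)
            errors.append(np.abs(rep["bias"]).max())
        assert errors[0] > errors[1] > errors[2]

    def test_degenerate_design_reported_per_piece(self, params):
        design = RecoveryDesign(targets=("mature",), n=2)  # below p + 1
        report = parameter_recovery(params, design, noise_sd=0.01, reps=2, seed=5)
        assert report["error"].notna().all()


class TestObservationPipeline:
    def test_pc_table_sums_to_one_per_plant(self, noiseless_trial):
        table = observations_to_pc(noiseless_trial)
        sums = table.groupby("plant")["pc"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_report_covers_requested_stages(self, noiseless_trial):
        report = fit_observations(noiseless_trial, stages=["mature"])
        assert set(report["model"]) == {"nlr_model", "mature"}
        ok = report[report["error"].isna()]
        assert {"coefficient", "estimate", "t", "p", "r"} <= set(ok.columns)
        assert len(ok) > 0
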