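"""Least-squares estimation of the partitioning-model parameters.

Fits the four elementary forms, dispatches observations into piece
domains, selects the best form for a point cloud, and provides a
Monte-Carlo parameter-recovery harness used to demonstrate that the
estimation machinery returns the generating coefficients.

Linear-in-parameters forms (linear, quadratic, logarithmic) are fitted
by ordinary least squares; the power law ``a·x^b`` is fitted by
nonlinear least squares on the original scale, initialized from a
log-log OLS fit.  Significance is reported per coefficient (two-sided
*t*, ``n - p`` degrees of freedom) and for the whole regression (*F*);
the tabulated *r* is the Pearson correlation between fitted and observed
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

from .errors import DomainError, FitError
from .params import Form, N_COEFFS, PartitionParams, PieceSpec, evaluate_form
from .stages import FineStage

#: Default seed for every stochastic operation in this module.
DEFAULT_SEED = 20120101

_GENERIC_NAMES = {
    Form.LINEAR: ("slope", "intercept"),
    Form.QUADRATIC: ("a", "b", "c"),
    Form.LOGARITHMIC: ("slope", "intercept"),
    Form.POWER: ("scale", "exponent"),
}


@dataclass(frozen=True)
class FitResult:
    """Estimates and significance statistics for one fitted piece."""

    form: Form
    coeff_names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    f_stat: float
    f_pvalue: float
    r: float
    n: int
    resid_sd: float

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.coeff_names, map(float, self.estimates)))


@dataclass(frozen=True)
class PieceFit:
    """Outcome of fitting one piece: a result or an explicit failure."""

    piece: PieceSpec
    n: int
    result: FitResult | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None


def _pearson(fitted: np.ndarray, observed: np.ndarray) -> float:
    if fitted.size < 2 or np.std(fitted) == 0 or np.std(observed) == 0:
        return float("nan")
    return float(np.corrcoef(fitted, observed)[0, 1])


def _validate_xy(x, y, form: Form) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise DomainError("x and y must be 1-D vectors of equal length")
    n_min = N_COEFFS[form] + 1
    if x.size < max(3, n_min):
        raise FitError(f"need at least {max(3, n_min)} points for a {form.value} fit")
    if np.ptp(x) == 0:
        raise FitError("singular design: constant x")
    if form in (Form.LOGARITHMIC, Form.POWER) and np.any(x <= 0):
        raise DomainError(f"{form.value} fit requires all x > 0")
    return x, y


def _ols_fit(X: np.ndarray, y: np.ndarray, form: Form, names) -> FitResult:
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    n, p = X.shape
    sse = float(np.sum((y - fitted) ** 2))
    return FitResult(
        form=form,
        coeff_names=tuple(names),
        estimates=np.asarray(res.params),
        se=np.asarray(res.bse),
        t_stats=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r=_pearson(fitted, y),
        n=n,
        resid_sd=float(np.sqrt(sse / (n - p))) if n > p else 0.0,
    )


def _power_fit(x: np.ndarray, y: np.ndarray, names) -> FitResult:
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        # log-log OLS initialization on the positive responses
        A = np.column_stack([np.log(x[pos]), np.ones(int(pos.sum()))])
        b, loga = np.linalg.lstsq(A, np.log(y[pos]), rcond=None)[0]
        p0 = (float(np.exp(loga)), float(b))
    else:
        raise FitError("power fit needs >= 2 positive y values for initialization")

    def model(x_, a, b_):
        return a * np.power(x_, b_)

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # no convergence
        raise FitError(f"power fit did not converge: {exc}") from exc
    n = x.size
    dof = n - 2
    se = np.sqrt(np.diag(pcov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = popt / se
    p_values = 2.0 * sps.t.sf(np.abs(t), dof)
    fitted = model(x, *popt)
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sse > 0 and sst > sse and dof > 0:
        f_stat = ((sst - sse) / 1.0) / (sse / dof)
        f_pvalue = float(sps.f.sf(f_stat, 1, dof))
    else:
        f_stat, f_pvalue = float("inf"), 0.0
    return FitResult(
        form=Form.POWER,
        coeff_names=tuple(names),
        estimates=np.asarray(popt),
        se=se,
        t_stats=np.asarray(t),
        p_values=np.asarray(p_values),
        f_stat=float(f_stat),
        f_pvalue=f_pvalue,
        r=_pearson(fitted, y),
        n=n,
        resid_sd=float(np.sqrt(sse / dof)) if dof > 0 else 0.0,
    )


def fit_form(x, y, form: Form | str, coeff_names: Sequence[str] | None = None) -> FitResult:
    """Fit one elementary form to (x, y) data.

    Coefficient order matches :func:`leafpart.params.evaluate_form`:
    highest-order term first, intercept last (power: scale, exponent).
    """
    form = Form(form)
    x, y = _validate_xy(x, y, form)
    names = tuple(coeff_names) if coeff_names is not None else _GENERIC_NAMES[form]
    if len(names) != N_COEFFS[form]:
        raise DomainError(f"{form.value} fit takes {N_COEFFS[form]} names, got {names}")
    if form is Form.LINEAR:
        X = np.column_stack([x, np.ones_like(x)])
        return _ols_fit(X, y, form, names)
    if form is Form.QUADRATIC:
        X = np.column_stack([x * x, x, np.ones_like(x)])
        return _ols_fit(X, y, form, names)
    if form is Form.LOGARITHMIC:
        X = np.column_stack([np.log(x), np.ones_like(x)])
        return _ols_fit(X, y, form, names)
    return _power_fit(x, y, names)


def fit_piecewise(
    nlr, pc, pieces: Iterable[PieceSpec]
) -> list[PieceFit]:
    """Partition (nLR, PC) observations by piece domain and fit each piece.

    Uses the same endpoint convention as prediction (breakpoints belong
    to the upper piece).  A piece whose subset is too small yields an
    explicit failure entry; the other pieces are still fitted.
    """
    nlr = np.asarray(nlr, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if nlr.shape != pc.shape:
        raise DomainError("nlr and pc must have equal length")
    results: list[PieceFit] = []
    for piece in pieces:
        mask = piece.domain.contains(nlr)
        n = int(np.sum(mask))
        if n < len(piece.coeff_names) + 1:
            results.append(
                PieceFit(piece, n, error=f"insufficient data in {piece.domain} (n={n})")
            )
            continue
        try:
            res = fit_form(nlr[mask], pc[mask], piece.form, piece.coeff_names)
        except (FitError, DomainError) as exc:
            results.append(PieceFit(piece, n, error=str(exc)))
        else:
            results.append(PieceFit(piece, n, result=res))
    return results


def select_form(
    x, y, candidates: Iterable[Form | str] | None = None
) -> tuple[Form, FitResult]:
    """Fit every candidate form and return the best one.

    Ranking: highest |r|, ties broken by lower residual standard
    deviation, then by fewer coefficients (parsimony).  Candidates whose
    preconditions fail (e.g. nonpositive x for log/power) are dropped;
    if all fail, a :class:`FitError` aggregating the reasons is raised.
    """
    cands = [Form(c) for c in (candidates or list(Form))]
    fits: dict[Form, FitResult] = {}
    failures: dict[Form, str] = {}
    for form in cands:
        try:
            fits[form] = fit_form(x, y, form)
        except (FitError, DomainError) as exc:
            failures[form] = str(exc)
    if not fits:
        raise FitError(f"all candidate forms failed: {failures}")

    def key(item):
        form, res = item
        r = 0.0 if np.isnan(res.r) else abs(res.r)
        return (-round(r, 9), round(res.resid_sd, 12), len(res.coeff_names))

    best_form, best = sorted(fits.items(), key=key)[0]
    return best_form, best


# ---------------------------------------------------------------------------
# observation-table pipeline
# ---------------------------------------------------------------------------


def observations_to_pc(obs: pd.DataFrame) -> pd.DataFrame:
    """Derive normalized ranks and measured coefficients from dry weights.

    Leaves are grouped into plant samples (by the ``plant`` column when
    present, else by treatment keys and sampling time); within each
    sample the coefficient is the leaf's share of the sample's total
    leaf biomass, so coefficients sum to one per plant.
    """
    keys = [
        c
        for c in ("season", "cultivar", "n_level", "density", "ndpd", "plant")
        if c in obs.columns
    ]
    if not keys:
        raise DomainError("observations lack grouping columns")
    out = obs.copy()
    out["nlr"] = out["rank"].astype(int) / out["total_leaves"].astype(int)
    totals = out.groupby(keys, sort=False)["biomass_g"].transform("sum")
    if (totals <= 0).any():
        raise DomainError("a plant sample has non-positive total leaf biomass")
    out["pc"] = out["biomass_g"] / totals
    return out


def fit_observations(
    obs: pd.DataFrame,
    params: PartitionParams | None = None,
    stages: Sequence[FineStage | str] | None = None,
) -> pd.DataFrame:
    """Refit the full model from a tidy observation table.

    Fits the rank-trend curve (pooled over every leaf row) and each
    stage's pieces on the stage's subset, pooling treatments, and
    returns a long-format report: one row per coefficient with the
    piece-level statistics (n, r, F) repeated alongside.
    """
    params = params or PartitionParams.default()
    data = observations_to_pc(obs)
    wanted = (
        [FineStage(s) for s in stages]
        if stages is not None
        else list(params.stage_pieces)
    )
    rows: list[dict] = []

    def emit(model: str, idx: int, piece_fit: PieceFit):
        base = {
            "model": model,
            "piece": idx,
            "domain": str(piece_fit.piece.domain),
            "form": piece_fit.piece.form.value,
            "n": piece_fit.n,
        }
        if piece_fit.ok:
            res = piece_fit.result
            for name, est, t, p in zip(
                res.coeff_names, res.estimates, res.t_stats, res.p_values
            ):
                rows.append(
                    {
                        **base,
                        "r": res.r,
                        "f_stat": res.f_stat,
                        "f_pvalue": res.f_pvalue,
                        "coefficient": name,
                        "estimate": float(est),
                        "t": float(t),
                        "p": float(p),
                        "error": None,
                    }
                )
        else:
            for name in piece_fit.piece.coeff_names:
                rows.append(
                    {
                        **base,
                        "r": np.nan,
                        "f_stat": np.nan,
                        "f_pvalue": np.nan,
                        "coefficient": name,
                        "estimate": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "error": piece_fit.error,
                    }
                )

    # rank-trend curve over nDPD, pooled across all leaf rows
    trend = data[data["ndpd"] > 0]
    try:
        res = fit_form(
            trend["ndpd"], trend["nlr"], params.nlr_piece.form, params.nlr_piece.coeff_names
        )
        emit("nlr_model", 0, PieceFit(params.nlr_piece, res.n, result=res))
    except (FitError, DomainError) as exc:
        emit("nlr_model", 0, PieceFit(params.nlr_piece, len(trend), error=str(exc)))

    for stage in wanted:
        sub = data[data["stage"] == stage.value]
        fits = fit_piecewise(sub["nlr"], sub["pc"], params.stage_pieces[stage])
        for idx, pf in enumerate(fits):
            emit(stage.value, idx, pf)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo parameter recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryDesign:
    """Which curves to exercise, and with how many points.

    ``targets`` may contain the pseudo-target ``"nlr"`` (the rank-trend
    curve sampled over ``ndpd_range``) and/or fine-stage names, whose
    pieces are each sampled uniformly over their own rank domain.
    ``n_overrides`` adjusts the per-piece sample count for individual
    targets.
    """

    targets: tuple[str, ...] = ("nlr",) + tuple(s.value for s in FineStage)
    n: int = 200
    ndpd_range: tuple[float, float] = (0.05, 1.0)
    n_overrides: Mapping[str, int] = field(default_factory=dict)


def _recover_piece(
    piece: PieceSpec,
    truth: np.ndarray,
    n: int,
    lo: float,
    hi: float,
    noise_sd: float,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-rep coefficient estimates, shape (reps, n_coeffs)."""
    estimates = np.empty((reps, truth.size))
    for rep in range(reps):
        x = lo + (hi - lo) * rng.random(n)
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        y = evaluate_form(piece.form, x, truth) + noise
        res = fit_form(x, y, piece.form, piece.coeff_names)
        estimates[rep] = res.estimates
    return estimates


def parameter_recovery(
    params: PartitionParams | None = None,
    design: RecoveryDesign | None = None,
    noise_sd: float = 0.05,
    reps: int = 20,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Simulate from the model, refit, and summarize coefficient recovery.

    For every requested target piece, ``reps`` replicates of ``n``
    points are drawn uniformly over the piece domain, responses are
    computed from the generating coefficients plus Gaussian noise of
    standard deviation ``noise_sd``, and the piece is refitted.

    Returns
    -------
    DataFrame
        One row per coefficient with columns target, piece, domain,
        coefficient, truth, mean, sd, mc_se, bias, within_2se, n, reps,
        error.  Degenerate pieces are reported as error rows.
    """
    if reps < 1:
        raise DomainError(f"reps must be >= 1, got {reps}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    params = params or PartitionParams.default()
    design = design or RecoveryDesign()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for target in design.targets:
        if target == "nlr":
            jobs = [(params.nlr_piece, design.ndpd_range[0], design.ndpd_range[1])]
        else:
            stage = FineStage(target)
            jobs = [
                (piece, piece.domain.lo, piece.domain.hi)
                for piece in params.stage_pieces[stage]
            ]
        n = int(design.n_overrides.get(target, design.n))
        for idx, (piece, lo, hi) in enumerate(jobs):
            truth = params.coeffs_for(piece)
            try:
                est = _recover_piece(piece, truth, n, lo, hi, noise_sd, reps, rng)
            except (FitError, DomainError) as exc:
                for name, t in zip(piece.coeff_names, truth):
                    rows.append(
                        {
                            "target": target,
                            "piece": idx,
                            "domain": str(piece.domain),
                            "coefficient": name,
                            "truth": float(t),
                            "mean": np.nan,
                            "sd": np.nan,
                            "mc_se": np.nan,
                            "bias": np.nan,
                            "within_2se": False,
                            "n": n,
                            "reps": reps,
                            "error": str(exc),
                        }
                    )
                continue
            mean = est.mean(axis=0)
            sd = est.std(axis=0, ddof=1) if reps > 1 else np.zeros(truth.size)
            mc_se = sd / np.sqrt(reps)
            for j, name in enumerate(piece.coeff_names):
                bias = float(mean[j] - truth[j])
                rows.append(
                    {
                        "target": target,
                        "piece": idx,
                        "domain": str(piece.domain),
                        "coefficient": name,
                        "truth": float(truth[j]),
                        "mean": float(mean[j]),
                        "sd": float(sd[j]),
                        "mc_se": float(mc_se[j]),
                        "bias": bias,
                        "within_2se": bool(abs(bias) <= 2.0 * mc_se[j] + 1e-12),
                        "n": n,
                        "reps": reps,
                        "error": None,
                    }
                )
    return pd.DataFrame(rows)
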