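"""Observed-versus-simulated agreement statistics.

For a set of paired observations O_i and simulations S_i the package
reports

* ``RMSE = sqrt( sum (O_i - S_i)^2 / n* )`` with ``n* = n - 1`` when
  ``n >= 30`` (small-sample correction; a flag restores the plain-n
  reading),
* ``d_a  = mean(O_i - S_i)`` (signed mean difference, observed minus
  simulated),
* ``d_ap = |d_a| / mean(O) * 100`` (percent of the mean observation),
* ``r``: Pearson correlation of observed and simulated values.

Grouped validation pools rows by architectural variable — the
normalized leaf rank trend (``nLR``) and the partitioning coefficient at
the seedling (``PCs``), budding-bolting (``PC_Bb``), anthesis (``PC_A``)
and mature (``PC_M``) stages — and reports one row of statistics per
group, plus a tidy 1:1-line scatter table for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import normalize_leaf_rank, pc_from_biomass, predict_nlr, predict_profile
from .errors import DomainError
from .params import PartitionParams
from .stages import FineStage, StageBoundaries, VALIDATION_GROUP, classify_stage

#: Architectural variables reported by the grouped comparison.
VALID_GROUPS = ("nLR", "PCs", "PC_Bb", "PC_A", "PC_M")


@dataclass(frozen=True)
class ValidationStats:
    """Agreement statistics for one observed-vs-simulated group."""

    n: int
    d_a: float
    d_ap_pct: float
    rmse: float
    r: float


def compare(observed, simulated, bessel_rmse: bool = True) -> ValidationStats:
    """Agreement statistics between paired observed and simulated vectors.

    ``bessel_rmse=True`` (default) divides the squared-error sum by
    ``n - 1`` when ``n >= 30``; pass ``False`` for the plain-n reading.
    """
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.ndim != 1 or s.ndim != 1:
        raise DomainError("observed and simulated must be 1-D vectors")
    if o.size != s.size:
        raise DomainError(f"length mismatch: observed {o.size}, simulated {s.size}")
    if o.size == 0:
        raise DomainError("empty vectors")
    n = o.size
    mean_obs = o.mean()
    if mean_obs == 0:
        raise DomainError("mean observation is zero; d_ap undefined")
    diff = o - s
    d_a = float(diff.mean())
    d_ap = abs(d_a) / abs(mean_obs) * 100.0
    denom = n - 1 if (bessel_rmse and n >= 30) else n
    rmse = float(np.sqrt(np.sum(diff**2) / denom))
    if n >= 2 and np.std(o) > 0 and np.std(s) > 0:
        r = float(np.corrcoef(o, s)[0, 1])
    else:
        r = float("nan")
    return ValidationStats(n=n, d_a=d_a, d_ap_pct=float(d_ap), rmse=rmse, r=r)


def grouped_validation(
    data: pd.DataFrame,
    group_col: str = "group",
    obs_col: str = "observed",
    sim_col: str = "simulated",
    valid_groups: tuple[str, ...] = VALID_GROUPS,
    bessel_rmse: bool = True,
) -> pd.DataFrame:
    """One row of agreement statistics per architectural group.

    Raises
    ------
    DomainError
        If a group label is not among ``valid_groups`` (the message
        lists the valid labels).
    """
    for col in (group_col, obs_col, sim_col):
        if col not in data.columns:
            raise DomainError(f"column {col!r} missing from validation table")
    labels = data[group_col].unique()
    unknown = set(labels) - set(valid_groups)
    if unknown:
        raise DomainError(
            f"unknown group labels {sorted(unknown)}; valid labels are {list(valid_groups)}"
        )
    rows = []
    for label in valid_groups:
        sub = data[data[group_col] == label]
        if sub.empty:
            continue
        stats = compare(sub[obs_col], sub[sim_col], bessel_rmse=bessel_rmse)
        rows.append(
            {
                "group": label,
                "n": stats.n,
                "d_a": stats.d_a,
                "d_ap_pct": stats.d_ap_pct,
                "rmse": stats.rmse,
                "r": stats.r,
            }
        )
    return pd.DataFrame(rows)


def validate_against_model(
    obs: pd.DataFrame,
    params: PartitionParams | None = None,
    boundaries: StageBoundaries | None = None,
    bessel_rmse: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full grouped validation on a tidy observation table.

    For every sampled plant the observed coefficients are computed from
    the emitted dry weights (they sum to one per plant) and compared to
    the model profile for that plant's stage and leaf count,
    renormalized over the same in-domain ranks.  The rank trend is
    validated by comparing each leaf's normalized rank to the trend
    curve evaluated at the sample's nDPD.

    If the table has no ``stage`` column the fine stage is derived from
    ``ndpd``.  Rows whose rank lies outside the stage's declared domains
    contribute to the ``nLR`` group only.

    Returns
    -------
    (stats, scatter)
        ``stats`` mirrors the grouped comparison (group, n, d_a,
        d_ap_pct, rmse, r); ``scatter`` holds the pooled 1:1-line pairs
        (group, observed, simulated).
    """
    import warnings as _warnings

    params = params or PartitionParams.default()
    obs = obs.copy()
    if "stage" not in obs.columns:
        obs["stage"] = [
            classify_stage(float(v), boundaries).fine.value for v in obs["ndpd"]
        ]
    plant_keys = [
        c
        for c in ("season", "cultivar", "n_level", "density", "ndpd", "plant")
        if c in obs.columns
    ]
    records: list[dict] = []
    for _, plant in obs.groupby(plant_keys, sort=False):
        stage = FineStage(plant["stage"].iloc[0])
        ndpd = float(plant["ndpd"].iloc[0])
        total = int(plant["total_leaves"].iloc[0])
        pc_obs = pc_from_biomass(plant["biomass_g"].to_numpy())
        profile = predict_profile(stage, total, params, renormalize=True)
        pc_sim_by_rank = dict(zip(profile["rank"], profile["pc_pred"]))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            nlr_sim = predict_nlr(ndpd, params) if ndpd > 0 else np.nan
        group = VALIDATION_GROUP[stage]
        for (_, row), pc_o in zip(plant.iterrows(), pc_obs):
            nlr_obs = normalize_leaf_rank(int(row["rank"]), total)
            records.append(
                {"group": "nLR", "observed": nlr_obs, "simulated": nlr_sim}
            )
            pc_s = pc_sim_by_rank.get(int(row["rank"]), np.nan)
            if np.isfinite(pc_s):
                records.append(
                    {"group": group, "observed": float(pc_o), "simulated": float(pc_s)}
                )
    scatter = pd.DataFrame.from_records(records).dropna()
    stats = grouped_validation(scatter, bessel_rmse=bessel_rmse)
    return stats, scatter
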