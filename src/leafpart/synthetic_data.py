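"""Synthetic destructive-sampling tables for a factorial field trial.

Generates observation tables with the statistical structure the fitting
and validation pipelines expect: a cultivar × nitrogen × density
factorial, a handful of plants sampled per treatment at a series of
normalized development times, a green-leaf-number trajectory that rises
to its maximum at nDPD = 0.64 (early anthesis) and then declines as the
canopy senesces, and per-rank dry weights whose partitioning
coefficients follow the stage curves and sum to one within each plant.

The generator emulates the *structure* of real trials, not treatment
effect sizes: all treatments share the same generating curves, and the
biological scatter is a Poisson jitter on leaf counts plus multiplicative
lognormal noise on dry weights (which preserves positivity and the
sum-to-one property after renormalization).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core_model import predict_profile
from .errors import DomainError
from .params import PartitionParams
from .stages import StageBoundaries, classify_stage

logger = logging.getLogger(__name__)

#: nDPD of the green-leaf-number maximum (early anthesis).
PEAK_NDPD = 0.64


@dataclass(frozen=True)
class TrialDesign:
    """Factorial layout and sampling schedule of a synthetic trial.

    Defaults mirror a three-by-three cultivar/nitrogen/density factorial
    with four plants per treatment per sampling date (destructive
    sampling of three to five plants is typical) and nine sampling dates
    spread so that every fine developmental stage is visited once.
    """

    cultivars: tuple[str, ...] = ("V1", "V3")
    n_levels: tuple[str, ...] = ("N0", "N1", "N2")
    densities: tuple[str, ...] = ("D1", "D2", "D3")
    plants_per_treatment: int = 4
    sampling_ndpds: tuple[float, ...] = (
        0.10,
        0.21,
        0.36,
        0.48,
        0.59,
        0.68,
        0.77,
        0.86,
        0.95,
    )
    seed: int = 20120101
    season: str = "2013-2014"
    max_leaves: int = 22
    leaf_count_jitter: bool = True

    def __post_init__(self):
        if not (self.cultivars and self.n_levels and self.densities):
            raise DomainError("the design needs at least one treatment cell")
        if self.plants_per_treatment < 1:
            raise DomainError("plants_per_treatment must be >= 1")
        if self.max_leaves < 1:
            raise DomainError("max_leaves must be >= 1")
        for t in self.sampling_ndpds:
            if not 0.0 < t <= 1.0:
                raise DomainError(f"sampling ndpd {t} outside (0, 1]")

    @property
    def n_treatments(self) -> int:
        return len(self.cultivars) * len(self.n_levels) * len(self.densities)


def green_leaf_trajectory(
    ndpd: float,
    max_leaves: int,
    peak_ndpd: float = PEAK_NDPD,
    rise_shape: float = 0.8,
    decline_shape: float = 1.2,
    residual_frac: float = 0.2,
) -> int:
    """Expected green-leaf count on the main stem at a given nDPD.

    A unimodal integer trajectory: leaf number climbs from one leaf at
    emergence (concave rise, ``rise_shape`` < 1 reproduces the fast
    pre-winter leaf production of winter rapeseed) to exactly
    ``max_leaves`` at ``peak_ndpd``, then declines toward a small
    residual (``residual_frac`` of the maximum, at least one leaf) as
    senescing leaves abscise.
    """
    if not 0.0 <= ndpd <= 1.0:
        raise DomainError(f"ndpd must lie in [0, 1], got {ndpd}")
    if max_leaves < 1:
        raise DomainError(f"max_leaves must be >= 1, got {max_leaves}")
    if not 0.0 < peak_ndpd < 1.0:
        raise DomainError(f"peak_ndpd must lie in (0, 1), got {peak_ndpd}")
    if ndpd <= peak_ndpd:
        frac = (ndpd / peak_ndpd) ** rise_shape
        count = int(np.floor(1.0 + (max_leaves - 1) * frac))
    else:
        residual = max(1, int(round(residual_frac * max_leaves)))
        frac = ((ndpd - peak_ndpd) / (1.0 - peak_ndpd)) ** decline_shape
        count = int(round(max_leaves - (max_leaves - residual) * frac))
    return int(np.clip(count, 1, max_leaves))


def default_total_biomass(ndpd: float) -> float:
    """Smooth unimodal total main-stem leaf dry biomass (g) over nDPD.

    Peaks around stem elongation / early flowering; always positive.
    The absolute scale is irrelevant to the partitioning coefficients.
    """
    return 2.0 + 28.0 * float(np.exp(-((ndpd - 0.55) ** 2) / (2 * 0.18**2)))


def generate_trial(
    design: TrialDesign | None = None,
    params: PartitionParams | None = None,
    noise_sd: float = 0.10,
    total_biomass_model: Callable[[float], float] | None = None,
    boundaries: StageBoundaries | None = None,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Generate a tidy destructive-sampling table from the model.

    For each treatment × sampling time × plant, the fine stage is
    derived from the sampling nDPD, a green leaf count is drawn around
    the trajectory (Poisson jitter, at least one leaf), the renormalized
    model profile over the in-domain ranks gives the coefficients, and
    per-rank dry weights are the coefficients times a positive total
    leaf biomass with multiplicative lognormal noise
    (``exp(N(0, noise_sd))``).  Plants whose leaf count puts no rank
    inside the stage domains are skipped with a logged warning.

    With ``renormalize=False`` the emitted dry weights are proportional
    to the raw stage curves instead of the per-plant renormalized
    profile; dividing by the (known) total-biomass curve then returns
    the raw curve values exactly, which is useful for round-trip checks
    of the fitting machinery.  Measured coefficients recomputed from the
    emitted weights sum to one per plant either way.

    Returns
    -------
    DataFrame
        Columns: season, cultivar, n_level, density, plant, ndpd, stage,
        rank, total_leaves, biomass_g.  ``attrs`` carries
        ``n_plants_total`` and ``n_plants_skipped``.
    """
    design = design or TrialDesign()
    params = params or PartitionParams.default()
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    biomass_model = total_biomass_model or default_total_biomass
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    n_total = 0
    n_skipped = 0
    treatments = itertools.product(design.cultivars, design.n_levels, design.densities)
    for cultivar, n_level, density in treatments:
        for ndpd in design.sampling_ndpds:
            stage = classify_stage(ndpd, boundaries).fine
            expected = green_leaf_trajectory(ndpd, design.max_leaves)
            for plant_idx in range(1, design.plants_per_treatment + 1):
                n_total += 1
                if design.leaf_count_jitter:
                    count = max(1, int(rng.poisson(expected)))
                else:
                    count = expected
                profile = predict_profile(stage, count, params, renormalize=renormalize)
                # clipped ranks carry zero predicted share: treat as senesced
                kept = profile[profile["in_domain"] & (profile["pc_pred"] > 0)]
                if kept.empty:
                    n_skipped += 1
                    logger.warning(
                        "skipping plant: no in-domain ranks for stage %s with "
                        "%d leaves (cultivar=%s, ndpd=%.3g)",
                        stage.value,
                        count,
                        cultivar,
                        ndpd,
                    )
                    continue
                total_b = float(biomass_model(ndpd))
                if not total_b > 0:
                    raise DomainError(
                        f"total_biomass_model must be positive, got {total_b} "
                        f"at ndpd={ndpd}"
                    )
                factors = rng.lognormal(0.0, noise_sd, len(kept))
                biomass = kept["pc_pred"].to_numpy() * total_b * factors
                plant_label = f"{cultivar}-{n_level}-{density}-t{ndpd:g}-p{plant_idx}"
                for rank, b in zip(kept["rank"], biomass):
                    rows.append(
                        {
                            "season": design.season,
                            "cultivar": cultivar,
                            "n_level": n_level,
                            "density": density,
                            "plant": plant_label,
                            "ndpd": ndpd,
                            "stage": stage.value,
                            "rank": int(rank),
                            "total_leaves": count,
                            "biomass_g": float(b),
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["n_plants_total"] = n_total
    df.attrs["n_plants_skipped"] = n_skipped
    return df
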