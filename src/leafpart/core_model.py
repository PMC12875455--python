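"""Model equations: normalized rank, partitioning coefficients, profiles.

The central quantity is the leaf biomass partitioning coefficient
PC_L(LR) = Bio_L(i) / Bio_TL — the fraction of total main-stem leaf dry
biomass held by the leaf at rank *i*.  Ranks are normalized by the total
main-stem leaf number so profiles from plants with different leaf counts
share the (0, 1] axis.  For each developmental fine stage the coefficient
follows a piecewise curve of one or two elementary forms over a declared
rank interval; outside that interval the model makes no statement (the
leaves are senesced or not yet emerged).

Two pragmatic guards keep predictions physical near domain edges:
the rank-trend curve is clamped into (1e-6, 1] and negative coefficient
predictions are clipped to zero.  Both emit a warning so silent
distortion is impossible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ClampedValueWarning, ClippedPredictionWarning, DomainError, OutOfDomainError
from .params import PartitionParams, PieceSpec
from .stages import FineStage, StageBoundaries, StageId, classify_stage  # noqa: F401  (re-export)

#: Lower clamp bound for the rank-trend prediction.
NLR_EPS = 1e-6


def normalize_leaf_rank(rank: int, total_leaves: int) -> float:
    """Normalize a main-stem leaf rank to the (0, 1] interval.

    Parameters
    ----------
    rank
        Ordinal leaf position on the main stem, counted from the base.
    total_leaves
        Total main-stem leaf number of the plant.
    """
    rank = int(rank)
    total_leaves = int(total_leaves)
    if total_leaves < 1:
        raise DomainError(f"total_leaves must be >= 1, got {total_leaves}")
    if not 1 <= rank <= total_leaves:
        raise DomainError(
            f"rank must lie in [1, total_leaves={total_leaves}], got {rank}"
        )
    return rank / total_leaves


def pc_from_biomass(biomass) -> np.ndarray:
    """Partitioning coefficients from per-rank dry weights (g).

    Element *i* of the result is ``biomass[i] / sum(biomass)``; the
    output sums to one by construction.
    """
    b = np.asarray(biomass, dtype=float)
    if b.ndim != 1 or b.size == 0:
        raise DomainError("biomass must be a non-empty 1-D vector")
    if np.any(b < 0):
        raise DomainError("biomass entries must be >= 0")
    total = b.sum()
    if not total > 0:
        raise DomainError("total biomass must be > 0 (all-zero input)")
    return b / total


def predict_nlr(
    ndpd: float, params: PartitionParams | None = None, clamp: bool = True
) -> float:
    """Rank-trend prediction: typical normalized leaf rank at a given nDPD.

    Evaluates the logarithmic trend ``Llr1·ln(nDPD) + Llr2``.  With
    ``clamp=True`` (default) the value is forced into (1e-6, 1] and a
    :class:`ClampedValueWarning` is emitted when clamping occurred; the
    fitted curve strays below zero early in the season, where few leaves
    exist and the trend is weakly constrained.
    """
    params = params or PartitionParams.default()
    if not ndpd > 0:
        raise DomainError(f"ndpd must be > 0 (log singularity), got {ndpd}")
    value = float(params.nlr_piece.evaluate(ndpd, params.coefficients))
    if clamp and not NLR_EPS < value <= 1.0:
        clamped = min(max(value, NLR_EPS), 1.0)
        warnings.warn(
            f"rank-trend prediction {value:.4g} at ndpd={ndpd:.4g} clamped to "
            f"{clamped:.4g}",
            ClampedValueWarning,
            stacklevel=2,
        )
        value = clamped
    return value


def find_piece(
    stage: FineStage | str, nlr: float, params: PartitionParams | None = None
) -> PieceSpec:
    """Return the unique piece of ``stage`` whose domain contains ``nlr``."""
    params = params or PartitionParams.default()
    stage = FineStage(stage)
    pieces = params.stage_pieces[stage]
    for piece in pieces:
        if piece.domain.contains(nlr):
            return piece
    intervals = [p.domain for p in pieces]
    raise OutOfDomainError(
        f"nlr={nlr:g} outside the declared {stage.value} domains "
        f"{', '.join(map(str, intervals))}",
        intervals=intervals,
    )


def predict_pc(
    stage: FineStage | str,
    nlr: float,
    params: PartitionParams | None = None,
    clip_negative: bool = True,
) -> float:
    """Predicted partitioning coefficient at one normalized rank.

    Dispatches ``nlr`` to the stage's matching piece and evaluates it.
    Negative predictions (possible near the upper edge of the late
    curves) are clipped to zero with a :class:`ClippedPredictionWarning`
    unless ``clip_negative=False``.

    Raises
    ------
    OutOfDomainError
        If ``nlr`` lies outside every declared piece interval; the
        error carries the valid intervals.
    """
    params = params or PartitionParams.default()
    piece = find_piece(stage, nlr, params)
    value = float(piece.evaluate(nlr, params.coefficients))
    if clip_negative and value < 0.0:
        warnings.warn(
            f"negative prediction {value:.4g} at nlr={nlr:g} "
            f"({FineStage(stage).value}) clipped to 0",
            ClippedPredictionWarning,
            stacklevel=2,
        )
        value = 0.0
    return value


def predict_profile(
    stage: FineStage | str,
    total_leaves: int,
    params: PartitionParams | None = None,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Predicted coefficient profile over all ranks of a plant.

    Evaluates the stage curve at every normalized rank ``r/total_leaves``;
    ranks outside the declared domains get ``NaN`` and ``in_domain=False``.
    With ``renormalize=True`` the in-domain values are rescaled to sum to
    one, mirroring how observed coefficients are computed from the green
    leaves actually present.

    Returns
    -------
    DataFrame
        Columns: stage, rank, total_leaves, nlr, pc_pred, in_domain,
        clipped.
    """
    params = params or PartitionParams.default()
    stage = FineStage(stage)
    total_leaves = int(total_leaves)
    if total_leaves < 1:
        raise DomainError(f"total_leaves must be >= 1, got {total_leaves}")
    ranks = np.arange(1, total_leaves + 1)
    nlr = ranks / total_leaves
    values = np.full(total_leaves, np.nan)
    in_domain = np.zeros(total_leaves, dtype=bool)
    clipped = np.zeros(total_leaves, dtype=bool)
    for piece in params.stage_pieces[stage]:
        mask = piece.domain.contains(nlr)
        if np.any(mask):
            values[mask] = piece.evaluate(nlr[mask], params.coefficients)
            in_domain |= mask
    negative = in_domain & (values < 0.0)
    values[negative] = 0.0
    clipped[negative] = True
    if renormalize:
        total = np.nansum(values)
        if total > 0:
            values = values / total
    return pd.DataFrame(
        {
            "stage": stage.value,
            "rank": ranks,
            "total_leaves": total_leaves,
            "nlr": nlr,
            "pc_pred": values,
            "in_domain": in_domain,
            "clipped": clipped,
        }
    )
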