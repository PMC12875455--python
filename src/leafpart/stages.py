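"""Developmental-stage taxonomy and classification on the nDPD axis.

Rapeseed development is tracked on normalized physiological time (nDPD),
where 0 corresponds to sowing and 1 to physiological maturity.  Three
coarse windows partition the season:

* ``earlier`` (seedling growth)            nDPD in [0, 0.428)
* ``mid``     (budding and stem elongation) nDPD in [0.428, 0.640)
* ``late``    (flowering through maturity)  nDPD in [0.640, 1]

Within the coarse windows the partitioning model distinguishes nine fine
stages (three seedling sub-stages, budding, bolting, three blooming
sub-stages and maturity), each carrying its own piecewise curve of the
partitioning coefficient against normalized leaf rank.

Only the two coarse thresholds are fixed by data; the fine sub-stage
cutoffs are configuration.  By default each coarse window is split evenly
among its sub-stages, with the onset of the mature stage (silique
dominance) exposed as a separate knob because it is agronomically the
most uncertain boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

from .errors import DomainError


class CoarseStage(str, Enum):
    EARLIER = "earlier"
    MID = "mid"
    LATE = "late"


class FineStage(str, Enum):
    EARLY_SEEDLING = "early_seedling"
    MID_SEEDLING = "mid_seedling"
    LATE_SEEDLING = "late_seedling"
    BUDDING = "budding"
    BOLTING = "bolting"
    EARLY_BLOOMING = "early_blooming"
    FULL_BLOOMING = "full_blooming"
    LATE_BLOOMING = "late_blooming"
    MATURE = "mature"


#: Every fine stage maps to exactly one coarse stage.
COARSE_OF: dict[FineStage, CoarseStage] = {
    FineStage.EARLY_SEEDLING: CoarseStage.EARLIER,
    FineStage.MID_SEEDLING: CoarseStage.EARLIER,
    FineStage.LATE_SEEDLING: CoarseStage.EARLIER,
    FineStage.BUDDING: CoarseStage.MID,
    FineStage.BOLTING: CoarseStage.MID,
    FineStage.EARLY_BLOOMING: CoarseStage.LATE,
    FineStage.FULL_BLOOMING: CoarseStage.LATE,
    FineStage.LATE_BLOOMING: CoarseStage.LATE,
    FineStage.MATURE: CoarseStage.LATE,
}

#: Grouping used when validating observed against simulated coefficients:
#: seedling sub-stages pool into PCs, budding/bolting into PC_Bb, the
#: blooming sub-stages into PC_A (anthesis) and maturity into PC_M.
VALIDATION_GROUP: dict[FineStage, str] = {
    FineStage.EARLY_SEEDLING: "PCs",
    FineStage.MID_SEEDLING: "PCs",
    FineStage.LATE_SEEDLING: "PCs",
    FineStage.BUDDING: "PC_Bb",
    FineStage.BOLTING: "PC_Bb",
    FineStage.EARLY_BLOOMING: "PC_A",
    FineStage.FULL_BLOOMING: "PC_A",
    FineStage.LATE_BLOOMING: "PC_A",
    FineStage.MATURE: "PC_M",
}


class StageId(NamedTuple):
    """A classified developmental stage (coarse window, fine stage)."""

    coarse: CoarseStage
    fine: FineStage


@dataclass(frozen=True)
class StageBoundaries:
    """nDPD cutoffs for stage classification.

    Parameters
    ----------
    earlier_end, mid_end
        Coarse thresholds separating seedling / stem-elongation /
        reproductive development.
    mature_onset
        nDPD at which siliques dominate assimilate demand and the
        canopy enters the mature stage (default 0.90).
    fine_edges
        Optional explicit override: ordered ``(lower_edge, fine_stage)``
        pairs spanning [0, 1].  When given, it replaces the even split.
    """

    earlier_end: float = 0.428
    mid_end: float = 0.640
    mature_onset: float = 0.90
    fine_edges: tuple[tuple[float, FineStage], ...] | None = None

    def __post_init__(self):
        if not 0.0 < self.earlier_end < self.mid_end < 1.0:
            raise DomainError(
                "require 0 < earlier_end < mid_end < 1, got "
                f"{self.earlier_end}, {self.mid_end}"
            )
        if not self.mid_end < self.mature_onset <= 1.0:
            raise DomainError(
                f"mature_onset must lie in (mid_end, 1], got {self.mature_onset}"
            )

    def edges(self) -> tuple[tuple[float, FineStage], ...]:
        """Ordered (lower edge, fine stage) pairs; intervals are [lo, next_lo)."""
        if self.fine_edges is not None:
            return self.fine_edges
        c1, c2, m = self.earlier_end, self.mid_end, self.mature_onset
        return (
            (0.0, FineStage.EARLY_SEEDLING),
            (c1 / 3.0, FineStage.MID_SEEDLING),
            (2.0 * c1 / 3.0, FineStage.LATE_SEEDLING),
            (c1, FineStage.BUDDING),
            ((c1 + c2) / 2.0, FineStage.BOLTING),
            (c2, FineStage.EARLY_BLOOMING),
            (c2 + (m - c2) / 3.0, FineStage.FULL_BLOOMING),
            (c2 + 2.0 * (m - c2) / 3.0, FineStage.LATE_BLOOMING),
            (m, FineStage.MATURE),
        )


DEFAULT_BOUNDARIES = StageBoundaries()


def classify_stage(ndpd: float, boundaries: StageBoundaries | None = None) -> StageId:
    """Classify a normalized development time into (coarse, fine) stages.

    Edges are half-open: an nDPD equal to a cutoff belongs to the later
    stage; nDPD = 1 is mature.

    Raises
    ------
    DomainError
        If ``ndpd`` lies outside [0, 1].
    """
    b = boundaries or DEFAULT_BOUNDARIES
    if not 0.0 <= ndpd <= 1.0:
        raise DomainError(f"ndpd must lie in [0, 1], got {ndpd}")
    fine = None
    for lo, stage in b.edges():
        if ndpd >= lo:
            fine = stage
        else:
            break
    assert fine is not None
    return StageId(COARSE_OF[fine], fine)
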