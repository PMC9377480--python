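"""Health-state and utility-scale data model.

Utilities live on two scales: the canonical [0, 1] *fraction* on a session's
anchor pair, and the presentation 0-100 scale anchored at Well = 100 and
Dead = 0. A *chained* assessment uses an intermediate state (here: transplant
with an HCV-unexposed kidney) as its best anchor; multiplying the elicited
fraction by that anchor's own utility returns the value to the common
Well/Dead scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ValidationError


class HealthState(Enum):
    """The three assessed ESKD states plus the two scale anchors."""

    HEMODIALYSIS = "hemodialysis"
    TX_UNEXPOSED = "tx_unexposed"
    TX_HCV_VIREMIC = "tx_hcv_viremic"
    WELL = "well"
    DEAD = "dead"

    @property
    def label(self) -> str:
        return _LABELS[self]

    @property
    def is_anchor(self) -> bool:
        """Well and Dead anchor the scale and are never elicitation targets."""
        return self in (HealthState.WELL, HealthState.DEAD)


_LABELS = {
    HealthState.HEMODIALYSIS: "Chronic intermittent hemodialysis",
    HealthState.TX_UNEXPOSED: "Transplant with an HCV-unexposed kidney",
    HealthState.TX_HCV_VIREMIC: "Transplant with an HCV-viremic kidney",
    HealthState.WELL: "Well (without ESKD)",
    HealthState.DEAD: "Dead",
}

#: The states whose utilities the study elicits, in assessment order.
ASSESSED_STATES = (
    HealthState.HEMODIALYSIS,
    HealthState.TX_UNEXPOSED,
    HealthState.TX_HCV_VIREMIC,
)


class AssessmentMethod(Enum):
    VAS = "vas"
    SG = "sg"
    TTO = "tto"


@dataclass(frozen=True)
class AnchorPair:
    """Best/worst anchor states with their utilities on the 0-100 scale.

    ``best_utility`` is ``None`` for a chained pair whose anchor utility has
    not been elicited yet; starting a chained session then raises a
    :class:`~hautil.errors.SequencingError`.
    """

    best: HealthState
    worst: HealthState = HealthState.DEAD
    best_utility: Optional[float] = 100.0
    worst_utility: float = 0.0

    def __post_init__(self) -> None:
        if self.best == self.worst:
            raise ValidationError("anchor states must differ")
        if not 0.0 <= self.worst_utility <= 100.0:
            raise ValidationError(f"worst_utility out of [0, 100]: {self.worst_utility}")
        if self.best_utility is not None:
            if not 0.0 <= self.best_utility <= 100.0:
                raise ValidationError(f"best_utility out of [0, 100]: {self.best_utility}")
            if self.best_utility <= self.worst_utility:
                raise ValidationError(
                    "best_utility must exceed worst_utility "
                    f"({self.best_utility} <= {self.worst_utility})"
                )

    @property
    def is_chained(self) -> bool:
        """True when the best anchor is itself an assessed (non-Well) state."""
        return self.best != HealthState.WELL

    @classmethod
    def well_dead(cls) -> "AnchorPair":
        """The study's default pair: Well = 100, Dead = 0."""
        return cls(best=HealthState.WELL)

    @classmethod
    def chained(cls, best: HealthState, best_utility: Optional[float]) -> "AnchorPair":
        """A chained pair, e.g. (transplant = U_tx, Dead = 0)."""
        return cls(best=best, best_utility=best_utility)


@dataclass(frozen=True)
class UtilityValue:
    """One elicited utility: raw indifference fraction plus its 0-100 value."""

    state: HealthState
    method: AssessmentMethod
    raw_fraction: float
    normalized: float
    chained: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.raw_fraction <= 1.0:
            raise ValidationError(f"raw_fraction out of [0, 1]: {self.raw_fraction}")
        if not 0.0 <= self.normalized <= 100.0:
            raise ValidationError(f"normalized out of [0, 100]: {self.normalized}")


def normalize_chained_utility(raw_fraction: float, anchor_utility: float) -> float:
    """Return a chained utility on the common Well/Dead 0-100 scale.

    The chained assessment elicits ``raw_fraction`` on a (best-anchor, Dead)
    pair; multiplying by the anchor's own utility re-expresses it against
    Well/Dead: raw HCV utility x transplant utility = HCV utility.
    """
    if not 0.0 <= raw_fraction <= 1.0:
        raise ValidationError(f"raw_fraction out of [0, 1]: {raw_fraction}")
    if not 0.0 <= anchor_utility <= 100.0:
        raise ValidationError(f"anchor_utility out of [0, 100]: {anchor_utility}")
    return raw_fraction * anchor_utility


def implied_death_risk(sg_utility: float) -> float:
    """Maximum acceptable probability (%) of immediate death in the gamble.

    A standard-gamble utility of u (0-100) means the respondent is indifferent
    at a gamble offering the best anchor with probability u%; they will accept
    up to 100 - u percent risk of death to escape the assessed state.
    """
    if not 0.0 <= sg_utility <= 100.0:
        raise ValidationError(f"sg_utility out of [0, 100]: {sg_utility}")
    return 100.0 - sg_utility


def scale_convert(value: float, from_scale: str, to_scale: str) -> float:
    """Convert between the 'fraction' [0, 1] and 'percent' [0, 100] scales.

    Results are rounded at 1e-12 so round trips are exact for any value
    representable at the platform's half-point resolution.
    """
    scales = {"fraction", "percent"}
    if from_scale not in scales or to_scale not in scales:
        raise ValidationError(f"unknown scale in ({from_scale!r}, {to_scale!r})")
    if from_scale == to_scale:
        return value
    if from_scale == "fraction":
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"fraction out of [0, 1]: {value}")
        return round(value * 100.0, 12)
    if not 0.0 <= value <= 100.0:
        raise ValidationError(f"percent out of [0, 100]: {value}")
    return round(value / 100.0, 12)
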