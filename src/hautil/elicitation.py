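"""Adaptive question-generation state machines for SG, TTO and VAS.

A session brackets the respondent's indifference point on the canonical
[0, 1] fraction scale of its anchor pair. Probes follow a "ping-pong" ladder
(high, low, high, ... closing in from both ends), then bisection until the
bracket is narrower than the configured resolution. The answer semantics
follow expected utility: the gamble's expected value at probability ``p`` of
the best anchor is ``p`` on the fraction scale, so choosing the gamble
(or trading years down) implies the respondent values the assessed state
below the probe, and the probe becomes the new upper bound; choosing the
sure state (or staying) makes it the new lower bound.

TTO probes are posed in whole months of the life-table horizon; the same
ladder/bisection logic runs on the month grid. VAS is a single placement on
the 0-100 feeling thermometer, not adaptive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple, Union

from .errors import ProtocolError, SequencingError, ValidationError
from .lifetable import LifeTable, tto_horizon
from .utility import (
    AnchorPair,
    AssessmentMethod,
    HealthState,
    UtilityValue,
    normalize_chained_utility,
)

DEFAULT_LADDER = (0.95, 0.05, 0.85, 0.15, 0.75, 0.25)


@dataclass(frozen=True)
class TitrationConfig:
    """Probe schedule: ladder rungs, terminal bracket width, question cap."""

    ladder: Tuple[float, ...] = DEFAULT_LADDER
    resolution: float = 0.005
    max_questions: int = 14

    def __post_init__(self) -> None:
        if not self.ladder:
            raise ValidationError("ladder must not be empty")
        if any(not 0.0 < p < 1.0 for p in self.ladder):
            raise ValidationError("ladder rungs must be strictly inside (0, 1)")
        if len(set(self.ladder)) != len(self.ladder):
            raise ValidationError("ladder rungs must be distinct")
        if not self.resolution > 0:
            raise ValidationError("resolution must be positive")
        needed = math.ceil(math.log2(1.0 / self.resolution)) + len(self.ladder)
        if self.max_questions < needed:
            raise ValidationError(
                f"max_questions {self.max_questions} below ladder+bisection bound {needed}"
            )


class Phase(Enum):
    LADDER = "ladder"
    BISECTION = "bisection"
    DONE = "done"


class Choice(Enum):
    SURE = "sure"      # SG: take the certain intermediate state
    GAMBLE = "gamble"  # SG: take the best-anchor-or-dead gamble
    STAY = "stay"      # TTO: keep the full horizon in the assessed state
    TRADE = "trade"    # TTO: accept fewer years in the best anchor


#: Responses implying the respondent's value is BELOW the probe (upper bound).
_BELOW = frozenset({Choice.GAMBLE, Choice.TRADE})
#: Responses implying the value is at or ABOVE the probe (lower bound).
_ABOVE = frozenset({Choice.SURE, Choice.STAY})


@dataclass(frozen=True)
class GambleQuestion:
    """Sure state vs gamble: best anchor with probability p_best, else dead."""

    sure_state: HealthState
    gamble_best: HealthState
    gamble_worst: HealthState
    p_best: float

    def __post_init__(self) -> None:
        if self.gamble_worst != HealthState.DEAD:
            raise ValidationError("gamble's worst outcome must be DEAD")
        if not 0.0 < self.p_best < 1.0:
            raise ValidationError(f"p_best must be interior: {self.p_best}")


@dataclass(frozen=True)
class TradeQuestion:
    """Full horizon in the assessed state vs fewer years in the best anchor."""

    target_state: HealthState
    best_state: HealthState
    full_horizon_years: float
    offered_years: float

    def __post_init__(self) -> None:
        if self.full_horizon_years <= 0:
            raise ValidationError("horizon must be positive")
        if not 0.0 <= self.offered_years <= self.full_horizon_years:
            raise ValidationError("offered_years must lie in [0, horizon]")

    @property
    def offered_fraction(self) -> float:
        return self.offered_years / self.full_horizon_years


@dataclass(frozen=True)
class PlacementQuestion:
    """VAS: place the state on the 0-100 thermometer between the anchors."""

    target_state: HealthState
    best_state: HealthState


Question = Union[GambleQuestion, TradeQuestion, PlacementQuestion]


@dataclass
class SessionState:
    """Evolving bracket/ladder state of one (patient, state, method) session."""

    method: AssessmentMethod
    target_state: HealthState
    anchors: AnchorPair
    config: TitrationConfig
    bracket_low: float = 0.0
    bracket_high: float = 1.0
    phase: Phase = Phase.LADDER
    transcript: List[dict] = field(default_factory=list)
    horizon_years: Optional[int] = None  # TTO only
    vas_placement: Optional[float] = None
    _ladder_index: int = 0
    _pending: Optional[Question] = None

    @property
    def width(self) -> float:
        return self.bracket_high - self.bracket_low

    @property
    def done(self) -> bool:
        return self.phase == Phase.DONE

    @property
    def n_questions(self) -> int:
        return len(self.transcript)

    # -- month grid (TTO) ---------------------------------------------------

    def _snap(self, fraction: float) -> float:
        """Quantize a probe to the TTO month grid; identity for SG."""
        if self.method != AssessmentMethod.TTO:
            return fraction
        months = 12 * int(self.horizon_years)
        return round(fraction * months) / months

    def _grid_step(self) -> float:
        if self.method != AssessmentMethod.TTO:
            return 0.0
        return 1.0 / (12 * int(self.horizon_years))


def start_session(
    method: AssessmentMethod,
    target_state: HealthState,
    anchors: AnchorPair,
    config: Optional[TitrationConfig] = None,
    *,
    patient_age: Optional[int] = None,
    patient_sex: Optional[str] = None,
    life_table: Optional[LifeTable] = None,
) -> SessionState:
    """Open an elicitation session and stage its first question.

    Chained sessions require the anchor's utility to have been elicited
    already (``anchors.best_utility`` is not None). TTO sessions resolve
    their horizon from (age, sex) through the life table.
    """
    if config is None:
        config = TitrationConfig()
    if target_state.is_anchor:
        raise ValidationError(f"{target_state} is an anchor, not an elicitation target")
    if anchors.best_utility is None:
        raise SequencingError(
            "chained session requested before its anchor utility was elicited"
        )
    horizon = None
    if method == AssessmentMethod.TTO:
        if patient_age is None or patient_sex is None or life_table is None:
            raise ValidationError("TTO requires patient_age, patient_sex and life_table")
        horizon = tto_horizon(patient_age, patient_sex, life_table)
    session = SessionState(
        method=method,
        target_state=target_state,
        anchors=anchors,
        config=config,
        horizon_years=horizon,
    )
    _stage_next_question(session)
    return session


def current_question(session: SessionState) -> Optional[Question]:
    """The staged question, or None when the session is DONE."""
    return None if session.done else session._pending


def _make_question(session: SessionState, fraction: float) -> Question:
    if session.method == AssessmentMethod.SG:
        return GambleQuestion(
            sure_state=session.target_state,
            gamble_best=session.anchors.best,
            gamble_worst=session.anchors.worst,
            p_best=fraction,
        )
    horizon = int(session.horizon_years)
    return TradeQuestion(
        target_state=session.target_state,
        best_state=session.anchors.best,
        full_horizon_years=float(horizon),
        offered_years=round(fraction * horizon * 12) / 12.0,
    )


def _stage_next_question(session: SessionState) -> None:
    """Pick the next probe, advancing LADDER -> BISECTION -> DONE."""
    if session.method == AssessmentMethod.VAS:
        session._pending = PlacementQuestion(
            target_state=session.target_state, best_state=session.anchors.best
        )
        return
    if session.width <= session.config.resolution:
        session.phase = Phase.DONE
        session._pending = None
        return
    if session.n_questions >= session.config.max_questions:
        # Question cap acts as a hard stop; the bracket midpoint still stands.
        session.phase = Phase.DONE
        session._pending = None
        return

    low, high = session.bracket_low, session.bracket_high
    if session.phase == Phase.LADDER:
        ladder = session.config.ladder
        while session._ladder_index < len(ladder):
            probe = session._snap(ladder[session._ladder_index])
            session._ladder_index += 1
            if low < probe < high:
                session._pending = _make_question(session, probe)
                return
        session.phase = Phase.BISECTION

    probe = session._snap((low + high) / 2.0)
    if not low < probe < high:
        # TTO month grid exhausted inside the bracket: cannot refine further.
        session.phase = Phase.DONE
        session._pending = None
        return
    session._pending = _make_question(session, probe)


def record_response(
    session: SessionState, choice: Union[Choice, float]
) -> SessionState:
    """Fold one answer into the bracket and stage the next question.

    GAMBLE/TRADE at probe f implies the respondent values the state below f
    (f becomes the upper bound); SURE/STAY implies a value at or above f.
    VAS takes a numeric 0-100 placement instead of a choice.
    """
    if session.done:
        raise SequencingError("response recorded on a DONE session")
    question = session._pending
    if question is None:
        raise SequencingError("no question staged")

    if session.method == AssessmentMethod.VAS:
        if isinstance(choice, Choice):
            raise ProtocolError("VAS expects a numeric 0-100 placement")
        placement = float(choice)
        if not 0.0 <= placement <= 100.0:
            raise ValidationError(f"placement out of [0, 100]: {placement}")
        session.vas_placement = placement
        session.phase = Phase.DONE
        session._pending = None
        session.transcript.append(
            {
                "method": session.method.value,
                "state": session.target_state.value,
                "phase": "placement",
                "question": {"kind": "placement"},
                "response": placement,
                "bracket_low": placement / 100.0,
                "bracket_high": placement / 100.0,
            }
        )
        return session

    if not isinstance(choice, Choice):
        raise ProtocolError(f"expected a Choice, got {choice!r}")
    expected = (
        (Choice.SURE, Choice.GAMBLE)
        if session.method == AssessmentMethod.SG
        else (Choice.STAY, Choice.TRADE)
    )
    if choice not in expected:
        raise ProtocolError(f"{choice} is not admissible for {session.method}")

    if isinstance(question, GambleQuestion):
        probe = question.p_best
    else:
        probe = question.offered_fraction

    if choice in _BELOW:
        session.bracket_high = probe
    else:
        session.bracket_low = probe
    session.transcript.append(
        {
            "method": session.method.value,
            "state": session.target_state.value,
            "phase": session.phase.value,
            "question": _question_record(question),
            "response": choice.value,
            "bracket_low": session.bracket_low,
            "bracket_high": session.bracket_high,
        }
    )
    session._pending = None
    _stage_next_question(session)
    return session


def _question_record(question: Question) -> dict:
    if isinstance(question, GambleQuestion):
        return {"kind": "gamble", "p_best": question.p_best}
    if isinstance(question, TradeQuestion):
        return {
            "kind": "trade",
            "offered_years": question.offered_years,
            "full_horizon_years": question.full_horizon_years,
        }
    return {"kind": "placement"}


def write_transcript(session: SessionState, path) -> None:
    """Append-style JSON-lines dump of the session transcript."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, rec in enumerate(session.transcript):
            fh.write(json.dumps({"ts": i, **rec}) + "\n")


def indifference_point(session: SessionState) -> float:
    """Elicited fraction: bracket midpoint (SG/TTO) or placement/100 (VAS)."""
    if not session.done:
        raise SequencingError("indifference point requested before session is DONE")
    if session.method == AssessmentMethod.VAS:
        return session.vas_placement / 100.0
    return (session.bracket_low + session.bracket_high) / 2.0


# -- indifference -> utility conversions -------------------------------------


def _linear_utility(fraction: float, anchors: AnchorPair) -> float:
    return fraction * anchors.best_utility + (1.0 - fraction) * anchors.worst_utility


def sg_utility_from_indifference(p_star: float, anchors: AnchorPair) -> float:
    """Expected-utility value of the indifference gamble on the 0-100 scale."""
    if not 0.0 <= p_star <= 1.0:
        raise ValidationError(f"p_star out of [0, 1]: {p_star}")
    return _linear_utility(p_star, anchors)


def tto_utility_from_indifference(
    offered_years: float, horizon_years: float, anchors: AnchorPair
) -> float:
    """Utility implied by indifference at offered/horizon years traded."""
    if horizon_years < 1:
        raise ValidationError(f"horizon must be >= 1 year: {horizon_years}")
    if not 0.0 <= offered_years <= horizon_years:
        raise ValidationError(
            f"offered_years {offered_years} outside [0, {horizon_years}]"
        )
    return _linear_utility(offered_years / horizon_years, anchors)


def vas_utility_from_placement(placement: float, anchors: AnchorPair) -> float:
    """Thermometer placement (0-100) mapped onto the anchor pair."""
    if not 0.0 <= placement <= 100.0:
        raise ValidationError(f"placement out of [0, 100]: {placement}")
    return _linear_utility(placement / 100.0, anchors)


def run_auto_session(
    method: AssessmentMethod,
    target_state: HealthState,
    anchors: AnchorPair,
    config: Optional[TitrationConfig] = None,
    respondent=None,
    *,
    patient_age: Optional[int] = None,
    patient_sex: Optional[str] = None,
    life_table: Optional[LifeTable] = None,
) -> UtilityValue:
    """Drive a session to completion against a simulated respondent.

    Returns the elicited :class:`UtilityValue`; chained sessions are
    normalized onto the common scale via the chained product.
    """
    if respondent is None:
        raise ValidationError("run_auto_session requires a respondent")
    session = start_session(
        method,
        target_state,
        anchors,
        config,
        patient_age=patient_age,
        patient_sex=patient_sex,
        life_table=life_table,
    )
    guard = 2 * session.config.max_questions + 2
    while not session.done:
        guard -= 1
        if guard < 0:
            raise ProtocolError("session failed to terminate within the question cap")
        question = current_question(session)
        answer = respondent.respond(question)
        record_response(session, answer)
    raw = indifference_point(session)
    if anchors.is_chained:
        normalized = normalize_chained_utility(raw, anchors.best_utility)
    else:
        normalized = _linear_utility(raw, anchors)
    return UtilityValue(
        state=target_state,
        method=method,
        raw_fraction=raw,
        normalized=normalized,
        chained=anchors.is_chained,
    )
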