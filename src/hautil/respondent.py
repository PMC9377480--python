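"""Behavioral model of a simulated elicitation respondent.

A respondent holds latent state utilities on the Well/Dead [0, 1] scale,
an optional additive per-method bias (risk-averse respondents inflate SG
answers relative to TTO/VAS), and optional per-question threshold noise.
Answers follow expected utility against the (possibly perturbed) target:
the gamble (or trade) is chosen exactly when the probe fraction exceeds the
respondent's target indifference, with ties resolving to the sure/stay
option. In a chained session the target is re-expressed on the chained
anchor pair by dividing by the latent utility of the best-anchor state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

from .elicitation import (
    Choice,
    GambleQuestion,
    PlacementQuestion,
    Question,
    TradeQuestion,
)
from .errors import ProtocolError, ValidationError
from .utility import AnchorPair, AssessmentMethod, HealthState


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass
class RespondentProfile:
    """Latent utilities plus the behavioral parameters driving answers."""

    latent_utilities: Dict[HealthState, float]
    method_bias: Dict[AssessmentMethod, float] = field(default_factory=dict)
    response_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.latent_utilities = dict(self.latent_utilities)
        self.latent_utilities.setdefault(HealthState.WELL, 1.0)
        self.latent_utilities.setdefault(HealthState.DEAD, 0.0)
        if self.latent_utilities[HealthState.WELL] != 1.0:
            raise ValidationError("WELL latent utility is fixed at 1")
        if self.latent_utilities[HealthState.DEAD] != 0.0:
            raise ValidationError("DEAD latent utility is fixed at 0")
        for state, u in self.latent_utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"latent utility for {state} out of [0, 1]: {u}")
        if self.response_noise_sd < 0:
            raise ValidationError("response_noise_sd must be >= 0")
        self._rng = np.random.default_rng(self.rng_seed)

    # -- behavior -----------------------------------------------------------

    def biased_latent(self, state: HealthState, method: AssessmentMethod) -> float:
        """Latent utility shifted by the method bias, clamped to [0, 1]."""
        return _clamp01(
            self.latent_utilities[state] + self.method_bias.get(method, 0.0)
        )

    def _target(
        self, method: AssessmentMethod, target_state: HealthState, best_state: HealthState
    ) -> float:
        value = self.biased_latent(target_state, method)
        if best_state != HealthState.WELL:  # chained: re-express on anchor pair
            anchor = self.biased_latent(best_state, method)
            if anchor == 0.0:
                raise ValidationError(
                    f"degenerate chained anchor: latent utility of {best_state} is 0"
                )
            value = _clamp01(value / anchor)
        return value

    def respond(self, question: Question):
        """Answer one question; deterministic when response_noise_sd == 0."""
        if isinstance(question, GambleQuestion):
            method, target, best = (
                AssessmentMethod.SG,
                question.sure_state,
                question.gamble_best,
            )
            probe = question.p_best
        elif isinstance(question, TradeQuestion):
            method, target, best = (
                AssessmentMethod.TTO,
                question.target_state,
                question.best_state,
            )
            probe = question.offered_fraction
        elif isinstance(question, PlacementQuestion):
            method, target, best = (
                AssessmentMethod.VAS,
                question.target_state,
                question.best_state,
            )
            probe = None
        else:
            raise ProtocolError(f"inadmissible question: {question!r}")

        threshold = self._target(method, target, best)
        if self.response_noise_sd > 0:
            threshold = _clamp01(
                threshold + self._rng.normal(0.0, self.response_noise_sd)
            )
        if method == AssessmentMethod.VAS:
            return threshold * 100.0
        if probe > threshold:
            return Choice.GAMBLE if method == AssessmentMethod.SG else Choice.TRADE
        return Choice.SURE if method == AssessmentMethod.SG else Choice.STAY


def target_indifference(
    profile: RespondentProfile,
    method: AssessmentMethod,
    target_state: HealthState,
    anchors: AnchorPair,
) -> float:
    """The fraction on the session's anchor pair at which the profile is
    indifferent (before any per-question noise)."""
    return profile._target(method, target_state, anchors.best)


def respond(profile: RespondentProfile, question: Question):
    """Functional form of :meth:`RespondentProfile.respond`."""
    return profile.respond(question)


def make_respondent(
    calibration,
    seed: int,
    *,
    method: AssessmentMethod = AssessmentMethod.SG,
    rank: Optional[float] = None,
    method_bias: Optional[Mapping[AssessmentMethod, float]] = None,
    response_noise_sd: float = 0.0,
) -> RespondentProfile:
    """Draw a respondent from a cohort calibration's utility marginals.

    A single uniform rank (drawn from ``seed`` unless supplied) is mapped
    through each assessed state's calibrated marginal for ``method``, so the
    respondent's latent utilities are comonotone across states.
    """
    rng = np.random.default_rng(seed)
    if rank is None:
        rank = float(rng.uniform())
    if not 0.0 < rank < 1.0:
        raise ValidationError(f"rank must be strictly interior: {rank}")
    latents = {
        state: _clamp01(calibration.marginal_ppf(state, method, rank) / 100.0)
        for state in calibration.assessed_states()
    }
    return RespondentProfile(
        latent_utilities=latents,
        method_bias=dict(method_bias or {}),
        response_noise_sd=response_noise_sd,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
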