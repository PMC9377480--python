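"""Synthetic study cohorts calibrated to the published summary tables.

The generator reproduces the study's marginal structure: exact categorical
counts (race, gender, education, prior transplant), continuous demographics
from [low, high]-truncated normals moment-matched to the reported mean/SD,
knowledge scores on the 10-item (10-point) grid, and per-(state, method)
latent utility marginals. A single uniform rank per patient is mapped through
every utility marginal, so a patient's latent utilities are comonotone across
states and methods (the published tables give no joint distribution; the
shared rank preserves the marginals while inducing realistic positive
within-patient dependence).

Two calibration subtleties, both handled numerically:

* The [0, 100]-truncated normal family cannot reach every (mean, SD) pair;
  at mean 82.5 the attainable SD tops out near 16.8 (the sigma -> infinity
  limit is an exponentially tilted uniform). ``fit_truncated_normal`` matches
  both moments when feasible; otherwise (``strict=False``) it matches the
  mean exactly and takes the largest attainable SD. ``calibrate_truncated_normal``
  is the strict variant and raises :class:`CalibrationError` when the target
  is infeasible.
* Knowledge scores are capped at 100, so an unadjusted N(10, 13.8) change
  draw would realize a mean change well under 10 points after clamping.
  The change-draw parameters are calibrated against the exact discrete
  pre-score distribution so the realized clamped-and-rounded change matches
  the target moments (mean prioritized exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .elicitation import TitrationConfig, run_auto_session
from .errors import CalibrationError, ValidationError
from .lifetable import LifeTable, load_bundled_life_table
from .respondent import RespondentProfile, make_respondent
from .utility import (
    ASSESSED_STATES,
    AnchorPair,
    AssessmentMethod,
    HealthState,
)

# -- truncated-normal moment matching ---------------------------------------


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)


def _trunc_moments(mu: float, sigma: float, low: float, high: float) -> Tuple[float, float]:
    """Mean and SD of the [low, high]-truncated N(mu, sigma).

    Computed by Gauss-Legendre quadrature on the sub-interval that carries
    the mass, with the log-density re-centered at its maximum: stable even
    when [low, high] sits dozens of sigmas into a tail (the regime the
    mean-exact SD-frontier calibration pushes into), where
    ``scipy.stats.truncnorm`` moments lose all precision.
    """
    xstar = min(max(mu, low), high)
    e0 = (xstar - mu) ** 2 / (2.0 * sigma**2)
    half = sigma * np.sqrt(2.0 * (e0 + 45.0))
    lo, hi = max(low, mu - half), min(high, mu + half)
    mid, rad = (hi + lo) / 2.0, (hi - lo) / 2.0
    x = mid + rad * _GL_NODES
    w = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2) + e0) * _GL_WEIGHTS
    z = w.sum()
    m = float(w @ x / z)
    v = float(w @ (x - m) ** 2 / z)
    return m, float(np.sqrt(v))


def _mu_for_mean(target_mean: float, sigma: float, low: float, high: float) -> float:
    """Solve for mu so the truncated mean hits target_mean (monotone in mu).

    The bracket expands geometrically: at large sigma the required mu sits
    far outside [low, high] (tilt regime, mu ~ theta * sigma^2)."""

    def gap(mu: float) -> float:
        return _trunc_moments(mu, sigma, low, high)[0] - target_mean

    step = sigma + (high - low)
    lo, hi = low, high
    g_lo, g_hi = gap(lo), gap(hi)
    for _ in range(200):
        if g_lo <= 0:
            break
        lo -= step
        step *= 2.0
        g_lo = gap(lo)
    step = sigma + (high - low)
    for _ in range(200):
        if g_hi >= 0:
            break
        hi += step
        step *= 2.0
        g_hi = gap(hi)
    return brentq(gap, lo, hi, xtol=1e-10, rtol=1e-14)


def fit_truncated_normal(
    target_mean: float,
    target_sd: float,
    low: float = 0.0,
    high: float = 100.0,
    *,
    strict: bool = True,
    tol: float = 1e-6,
) -> Tuple[float, float]:
    """Parameters (mu, sigma) of the underlying normal whose [low, high]
    truncation has the requested mean and SD.

    With ``strict=True`` an unattainable target raises
    :class:`CalibrationError`; with ``strict=False`` the mean is matched
    exactly and sigma is pushed to the family's attainable-SD frontier.
    """
    if not low < target_mean < high:
        raise CalibrationError(
            f"target mean {target_mean} outside open interval ({low}, {high})"
        )
    if target_sd <= 0:
        raise CalibrationError(f"target SD must be positive: {target_sd}")
    # Bhatia-Davis: no [low, high]-supported distribution has a larger variance.
    bd_var = (high - target_mean) * (target_mean - low)
    if target_sd * target_sd >= bd_var:
        bound = high if (high - target_mean) < (target_mean - low) else low
        raise CalibrationError(
            f"SD {target_sd} infeasible for mean {target_mean} near bound {bound} "
            f"(Bhatia-Davis limit {np.sqrt(bd_var):.3f})"
        )

    span = high - low
    sigma_lo, sigma_hi = 1e-3 * span, 3.0 * span

    def sd_at(sigma: float) -> float:
        mu = _mu_for_mean(target_mean, sigma, low, high)
        return _trunc_moments(mu, sigma, low, high)[1]

    if sd_at(sigma_hi) < target_sd:
        if strict:
            raise CalibrationError(
                f"SD {target_sd} unattainable by a [{low}, {high}]-truncated normal "
                f"with mean {target_mean} (family maximum ~{sd_at(sigma_hi):.3f})"
            )
        sigma = sigma_hi
    elif sd_at(sigma_lo) > target_sd:
        sigma = sigma_lo
    else:
        sigma = brentq(lambda s: sd_at(s) - target_sd, sigma_lo, sigma_hi, xtol=1e-10)
    mu = _mu_for_mean(target_mean, sigma, low, high)
    got_mean, got_sd = _trunc_moments(mu, sigma, low, high)
    if abs(got_mean - target_mean) > tol:
        raise CalibrationError(f"mean residual {got_mean - target_mean:g} exceeds {tol}")
    if strict and abs(got_sd - target_sd) > tol:
        raise CalibrationError(f"SD residual {got_sd - target_sd:g} exceeds {tol}")
    return float(mu), float(sigma)


def calibrate_truncated_normal(
    target_mean: float, target_sd: float, low: float = 0.0, high: float = 100.0
) -> Tuple[float, float]:
    """Strict two-moment matching (mean and SD both within 1e-6)."""
    return fit_truncated_normal(target_mean, target_sd, low, high, strict=True)


@lru_cache(maxsize=256)
def _fit_cached(target_mean: float, target_sd: float, low: float, high: float):
    return fit_truncated_normal(target_mean, target_sd, low, high, strict=False)


def _trunc_ppf(q, mu: float, sigma: float, low: float, high: float):
    a, b = (low - mu) / sigma, (high - mu) / sigma
    return truncnorm.ppf(q, a, b, loc=mu, scale=sigma)


# -- knowledge-change calibration -------------------------------------------


def _round10(x):
    return np.clip(np.floor(np.asarray(x) / 10.0 + 0.5) * 10.0, 0.0, 100.0)


def _pre_grid_probs(mu: float, sigma: float) -> np.ndarray:
    """P(pre score = 10k), k = 0..10, for the rounded truncated normal."""
    a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
    edges = np.concatenate([[0.0], np.arange(5.0, 100.0, 10.0), [100.0]])
    cdf = truncnorm.cdf(edges, a, b, loc=mu, scale=sigma)
    return np.diff(cdf)


def _change_moments(mu_c: float, sigma_c: float, pre_probs: np.ndarray) -> Tuple[float, float]:
    """Exact mean/SD of round10(clamp(pre + N(mu_c, sigma_c))) - pre."""
    pre_levels = np.arange(0.0, 101.0, 10.0)
    post_levels = np.arange(0.0, 101.0, 10.0)
    inner = np.arange(5.0, 100.0, 10.0)  # bin edges between post levels
    m1 = m2 = 0.0
    for p_k, pre in zip(pre_probs, pre_levels):
        if p_k == 0.0:
            continue
        cuts = norm.cdf(inner, loc=pre + mu_c, scale=sigma_c)
        probs = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
        delta = post_levels - pre
        m1 += p_k * float(probs @ delta)
        m2 += p_k * float(probs @ delta**2)
    var = m2 - m1 * m1
    return m1, float(np.sqrt(max(var, 0.0)))


@lru_cache(maxsize=64)
def _calibrate_change(
    pre_mu: float, pre_sigma: float, target_mean: float, target_sd: float
) -> Tuple[float, float]:
    """Change-draw (mu, sigma) whose realized clamped/rounded change matches
    the target mean exactly and the target SD as closely as attainable."""
    pre_probs = _pre_grid_probs(pre_mu, pre_sigma)

    def mu_for(sigma_c: float) -> float:
        return brentq(
            lambda m: _change_moments(m, sigma_c, pre_probs)[0] - target_mean,
            -80.0,
            180.0,
            xtol=1e-10,
        )

    def sd_gap(sigma_c: float) -> float:
        return _change_moments(mu_for(sigma_c), sigma_c, pre_probs)[1] - target_sd

    lo, hi = 0.5, 80.0
    if sd_gap(lo) > 0:
        sigma_c = lo
    elif sd_gap(hi) < 0:
        sigma_c = hi
    else:
        sigma_c = brentq(sd_gap, lo, hi, xtol=1e-8)
    return float(mu_for(sigma_c)), float(sigma_c)


# -- calibration config ------------------------------------------------------

AFRICAN_AMERICAN = "african_american"
EUROPEAN_AMERICAN = "european_american"

EDUCATION_LEVELS = (
    "less_than_high_school",
    "high_school_or_ged",
    "some_college",
    "associate",
    "bachelor",
    "master",
)


@dataclass(frozen=True)
class CalibrationConfig:
    """Targets the synthetic cohort is calibrated to (published overall column)."""

    n_patients: int = 63
    race_counts: Mapping[str, int] = field(
        default_factory=lambda: {AFRICAN_AMERICAN: 44, EUROPEAN_AMERICAN: 19}
    )
    gender_counts: Mapping[str, int] = field(
        default_factory=lambda: {"male": 33, "female": 30}
    )
    education_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(
            zip(EDUCATION_LEVELS, (10, 25, 11, 5, 9, 3))
        )
    )
    age_low: float = 21.0
    age_high: float = 80.0
    age_mean: float = 57.8
    age_sd: float = 12.3
    vintage: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            AFRICAN_AMERICAN: (7.3, 8.8),
            EUROPEAN_AMERICAN: (2.79, 3.0),
        }
    )
    vintage_max: float = 60.0
    knowledge_pre: Tuple[float, float] = (79.0, 17.3)
    knowledge_change: Tuple[float, float] = (10.0, 13.8)
    arm_effect: float = 0.0  # added to the change-draw mean in the MATCHED arm
    utility_targets: Mapping[Tuple[HealthState, AssessmentMethod], Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_UTILITY_TARGETS)
    )
    prior_transplant_count: int = 9
    respondent_noise_sd: float = 0.0
    block_size: int = 4

    def __post_init__(self) -> None:
        for name, counts in (
            ("race_counts", self.race_counts),
            ("gender_counts", self.gender_counts),
            ("education_counts", self.education_counts),
        ):
            if sum(counts.values()) != self.n_patients:
                raise ValidationError(f"{name} must sum to n_patients={self.n_patients}")
        if not 0 <= self.prior_transplant_count <= self.n_patients:
            raise ValidationError("prior_transplant_count out of range")
        for key, (m, s) in self.utility_targets.items():
            if not 0.0 <= m <= 100.0 or s < 0:
                raise ValidationError(f"bad utility target for {key}: ({m}, {s})")

    # -- calibrated marginals ------------------------------------------------

    def assessed_states(self) -> Tuple[HealthState, ...]:
        return ASSESSED_STATES

    def utility_marginal(
        self, state: HealthState, method: AssessmentMethod
    ) -> Tuple[float, float]:
        """(mu, sigma) of the calibrated underlying normal for a target."""
        mean, sd = self.utility_targets[(state, method)]
        if sd == 0.0:
            return mean, 0.0
        return _fit_cached(mean, sd, 0.0, 100.0)

    def marginal_ppf(self, state: HealthState, method: AssessmentMethod, rank: float) -> float:
        mean, sd = self.utility_targets[(state, method)]
        if sd == 0.0:
            return mean
        mu, sigma = self.utility_marginal(state, method)
        return float(_trunc_ppf(rank, mu, sigma, 0.0, 100.0))

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["utility_targets"] = {
            f"{s.value}:{m.value}": list(v) for (s, m), v in self.utility_targets.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        targets = {
            (HealthState(k.split(":")[0]), AssessmentMethod(k.split(":")[1])): tuple(v)
            for k, v in payload.pop("utility_targets").items()
        }
        payload["knowledge_pre"] = tuple(payload["knowledge_pre"])
        payload["knowledge_change"] = tuple(payload["knowledge_change"])
        payload["vintage"] = {k: tuple(v) for k, v in payload["vintage"].items()}
        return cls(utility_targets=targets, **payload)


#: Table-4 overall column, (state, method) -> (mean, SD) on the 0-100 scale.
_DEFAULT_UTILITY_TARGETS = {
    (HealthState.HEMODIALYSIS, AssessmentMethod.VAS): (57.9, 25.9),
    (HealthState.TX_UNEXPOSED, AssessmentMethod.VAS): (88.2, 17.8),
    (HealthState.TX_HCV_VIREMIC, AssessmentMethod.VAS): (66.3, 27.3),
    (HealthState.HEMODIALYSIS, AssessmentMethod.SG): (82.5, 23.1),
    (HealthState.TX_UNEXPOSED, AssessmentMethod.SG): (89.0, 18.0),
    (HealthState.TX_HCV_VIREMIC, AssessmentMethod.SG): (75.5, 28.2),
    (HealthState.HEMODIALYSIS, AssessmentMethod.TTO): (80.3, 20.5),
    (HealthState.TX_UNEXPOSED, AssessmentMethod.TTO): (84.8, 22.0),
    (HealthState.TX_HCV_VIREMIC, AssessmentMethod.TTO): (73.8, 28.1),
}


def default_calibration() -> CalibrationConfig:
    """The published overall-column targets (Tables 1, 2 and 4)."""
    return CalibrationConfig()


# -- cohort ------------------------------------------------------------------


@dataclass
class SyntheticPatient:
    id: str
    age: int
    sex: str
    race: str
    education: str
    vintage_years: float
    prior_transplant: bool
    arm: str  # "matched" | "mismatched"
    knowledge_pre: int
    knowledge_post: int
    latent_rank: float
    profiles: Dict[AssessmentMethod, RespondentProfile]

    @property
    def profile(self) -> RespondentProfile:
        """The SG-method profile (back-compat alias)."""
        return self.profiles[AssessmentMethod.SG]


@dataclass
class SyntheticCohort:
    patients: List[SyntheticPatient]
    seed: int
    calibration: CalibrationConfig

    def __len__(self) -> int:
        return len(self.patients)

    def demographics_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.id,
                    "age": p.age,
                    "sex": p.sex,
                    "race": p.race,
                    "education": p.education,
                    "vintage_years": p.vintage_years,
                    "prior_transplant": p.prior_transplant,
                    "arm": p.arm,
                    "knowledge_pre": p.knowledge_pre,
                    "knowledge_post": p.knowledge_post,
                }
            )
        return pd.DataFrame(rows)


def _exact_counts(rng: np.random.Generator, counts: Mapping[str, int]) -> np.ndarray:
    values = np.repeat(
        np.array(list(counts.keys()), dtype=object),
        np.array(list(counts.values()), dtype=int),
    )
    return rng.permutation(values)


def generate_cohort(
    calibration: Optional[CalibrationConfig] = None, seed: int = 0
) -> SyntheticCohort:
    """Draw one synthetic cohort; byte-identical given (calibration, seed)."""
    from .studyio import randomize_arm  # local import avoids a cycle

    cal = calibration or default_calibration()
    rng = np.random.default_rng(seed)
    n = cal.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]

    races = _exact_counts(rng, cal.race_counts)
    sexes = _exact_counts(rng, cal.gender_counts)
    education = _exact_counts(rng, cal.education_counts)
    prior = np.zeros(n, dtype=bool)
    prior[rng.choice(n, size=cal.prior_transplant_count, replace=False)] = True

    age_mu, age_sigma = _fit_cached(cal.age_mean, cal.age_sd, cal.age_low, cal.age_high)
    ages = _trunc_ppf(rng.uniform(size=n), age_mu, age_sigma, cal.age_low, cal.age_high)
    ages = np.clip(np.round(ages), cal.age_low, cal.age_high).astype(int)

    vintages = np.empty(n)
    for race, (vm, vs) in cal.vintage.items():
        mask = races == race
        mu_v, sigma_v = _fit_cached(vm, vs, 0.0, cal.vintage_max)
        vintages[mask] = _trunc_ppf(
            rng.uniform(size=int(mask.sum())), mu_v, sigma_v, 0.0, cal.vintage_max
        )
    vintages = np.round(vintages, 1)

    pre_mu, pre_sigma = _fit_cached(*cal.knowledge_pre, 0.0, 100.0)
    pre = _round10(_trunc_ppf(rng.uniform(size=n), pre_mu, pre_sigma, 0.0, 100.0))
    change_mu, change_sigma = _calibrate_change(
        pre_mu, pre_sigma, cal.knowledge_change[0], cal.knowledge_change[1]
    )

    arm_of = {a.patient_id: a.arm for a in randomize_arm(ids, seed=seed, block_size=cal.block_size)}
    arm_shift = np.array(
        [cal.arm_effect if arm_of[i] == "matched" else 0.0 for i in ids]
    )
    post = _round10(pre + rng.normal(change_mu + arm_shift, change_sigma, size=n))

    ranks = rng.uniform(size=n)
    profile_seeds = rng.integers(0, 2**31 - 1, size=n)

    # one vectorized ppf evaluation per (state, method); each patient's single
    # rank indexes every marginal (comonotone latents)
    latent = {}
    for method in AssessmentMethod:
        for state in cal.assessed_states():
            mean, sd = cal.utility_targets[(state, method)]
            if sd == 0.0:
                vals = np.full(n, mean)
            else:
                mu_u, sigma_u = cal.utility_marginal(state, method)
                vals = _trunc_ppf(ranks, mu_u, sigma_u, 0.0, 100.0)
            latent[(state, method)] = np.clip(vals / 100.0, 0.0, 1.0)

    patients = []
    for i, pid in enumerate(ids):
        profiles = {
            method: RespondentProfile(
                latent_utilities={
                    state: float(latent[(state, method)][i])
                    for state in cal.assessed_states()
                },
                response_noise_sd=cal.respondent_noise_sd,
                rng_seed=int(profile_seeds[i]),
            )
            for method in AssessmentMethod
        }
        patients.append(
            SyntheticPatient(
                id=pid,
                age=int(ages[i]),
                sex=str(sexes[i]),
                race=str(races[i]),
                education=str(education[i]),
                vintage_years=float(vintages[i]),
                prior_transplant=bool(prior[i]),
                arm=arm_of[pid],
                knowledge_pre=int(pre[i]),
                knowledge_post=int(post[i]),
                latent_rank=float(ranks[i]),
                profiles=profiles,
            )
        )
    return SyntheticCohort(patients=patients, seed=seed, calibration=cal)


# -- full study simulation ---------------------------------------------------


def simulate_study(
    calibration: Optional[CalibrationConfig] = None,
    elicitation_config: Optional[TitrationConfig] = None,
    seed: int = 0,
    *,
    methods: Sequence[AssessmentMethod] = tuple(AssessmentMethod),
    life_table: Optional[LifeTable] = None,
) -> pd.DataFrame:
    """Run the full two-part assessment for every patient of one cohort.

    Part 1 elicits hemodialysis and transplant on Well/Dead anchors; part 2
    runs the chained HCV-viremic assessment on (transplant, Dead) anchors
    using the patient's freshly elicited transplant utility, then normalizes
    by the chained product. Returns one row per (patient, state, method) with
    the patient's demographics and knowledge scores attached.
    """
    cal = calibration or default_calibration()
    config = elicitation_config or TitrationConfig()
    table = life_table or load_bundled_life_table()
    cohort = generate_cohort(cal, seed)

    rows = []
    for patient in cohort.patients:
        for method in methods:
            respondent = patient.profiles[method]
            well_dead = AnchorPair.well_dead()
            kwargs = dict(
                patient_age=patient.age, patient_sex=patient.sex, life_table=table
            )
            results = {}
            for state in (HealthState.HEMODIALYSIS, HealthState.TX_UNEXPOSED):
                results[state] = run_auto_session(
                    method, state, well_dead, config, respondent, **kwargs
                )
            chained_anchors = AnchorPair.chained(
                HealthState.TX_UNEXPOSED,
                results[HealthState.TX_UNEXPOSED].normalized,
            )
            results[HealthState.TX_HCV_VIREMIC] = run_auto_session(
                method,
                HealthState.TX_HCV_VIREMIC,
                chained_anchors,
                config,
                respondent,
                **kwargs,
            )
            for state, value in results.items():
                rows.append(
                    {
                        "patient_id": patient.id,
                        "state": state.value,
                        "method": method.value,
                        "raw_fraction": value.raw_fraction,
                        "normalized": value.normalized,
                        "chained": value.chained,
                    }
                )

    long = pd.DataFrame(rows)
    return long.merge(cohort.demographics_frame(), on="patient_id", how="left")


def results_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long simulation table to one row per patient.

    Columns ``utility_{method}_{state}`` hold normalized 0-100 utilities;
    ``raw_{method}_tx_hcv_viremic`` holds the chained raw fraction.
    """
    demo_cols = [
        "patient_id",
        "age",
        "sex",
        "race",
        "education",
        "vintage_years",
        "prior_transplant",
        "arm",
        "knowledge_pre",
        "knowledge_post",
    ]
    demo = long[demo_cols].drop_duplicates("patient_id").set_index("patient_id")
    util = long.pivot_table(
        index="patient_id", columns=["method", "state"], values="normalized"
    )
    util.columns = [f"utility_{m}_{s}" for m, s in util.columns]
    chained = long[long["chained"]]
    raw = chained.pivot_table(
        index="patient_id", columns=["method", "state"], values="raw_fraction"
    )
    raw.columns = [f"raw_{m}_{s}" for m, s in raw.columns]
    wide = demo.join(util).join(raw).reset_index()
    return wide.sort_values("patient_id").reset_index(drop=True)
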