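"""Statistical computations of the study.

Rank-based two-group and paired comparisons use midranks for ties and exact
p-values by full enumeration when the sample is small enough (rank-sum:
total n <= 12; signed-rank: nonzero n <= 15), switching to the tie-corrected
normal approximation with continuity correction beyond the caps. Each result
records which route produced it. The design-stage power computation finds
the smallest integer per-arm n whose two-sample t test attains the target
power under the noncentral-t distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import nct, norm
from scipy.stats import t as t_dist
from scipy.stats import rankdata

from .errors import ValidationError
from .utility import ASSESSED_STATES, AssessmentMethod, HealthState

EXACT_RANK_SUM_CAP = 12    # total n for full combination enumeration
EXACT_SIGNED_RANK_CAP = 15  # nonzero differences for full sign enumeration

EXACT = "exact_permutation"
APPROX = "normal_approximation"


@dataclass(frozen=True)
class KnowledgeScores:
    patient_id: str
    pre: float
    post: float
    items_pre: Optional[Tuple[int, ...]] = None
    items_post: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        for name, score, items in (
            ("pre", self.pre, self.items_pre),
            ("post", self.post, self.items_post),
        ):
            if not 0.0 <= score <= 100.0:
                raise ValidationError(f"{name} score out of [0, 100]: {score}")
            if items is not None and score != 10 * sum(items):
                raise ValidationError(
                    f"{name} score {score} inconsistent with item vector {items}"
                )


@dataclass(frozen=True)
class GroupComparison:
    """Result of a rank-based test with its exact-vs-approximate provenance."""

    statistic: float
    p_value: float
    method: str  # EXACT or APPROX
    n_a: int
    n_b: int
    ties_note: str = ""


# -- change scores -----------------------------------------------------------


def change_scores(scores: Sequence[KnowledgeScores]) -> Dict[str, object]:
    """Per-patient post - pre changes with mean/median/SD summary."""
    missing = [s.patient_id for s in scores if s.pre is None or s.post is None]
    if missing:
        raise ValidationError(f"missing pre/post for patient(s): {', '.join(missing)}")
    if not scores:
        raise ValidationError("no knowledge scores supplied")
    changes = np.array([s.post - s.pre for s in scores], dtype=float)
    return {
        "per_patient": {s.patient_id: float(c) for s, c in zip(scores, changes)},
        "mean": float(np.mean(changes)),
        "median": float(np.median(changes)),
        "sd": float(np.std(changes, ddof=1)) if len(changes) > 1 else 0.0,
        "n": len(changes),
    }


def knowledge_scores_from_frame(df: pd.DataFrame) -> List[KnowledgeScores]:
    sub = df.drop_duplicates("patient_id")
    return [
        KnowledgeScores(str(r.patient_id), float(r.knowledge_pre), float(r.knowledge_post))
        for r in sub.itertuples()
    ]


# -- internal consistency ----------------------------------------------------


def cronbach_alpha(item_matrix) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / total-score variance),
    with sample (n-1) variances."""
    items = np.asarray(item_matrix, dtype=float)
    if items.ndim != 2 or items.shape[0] < 2 or items.shape[1] < 2:
        raise ValidationError("item matrix must be at least 2 patients x 2 items")
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# -- rank-sum (Mann-Whitney) -------------------------------------------------


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float], sides: str = "two"
) -> GroupComparison:
    """Wilcoxon rank-sum with midranks; exact by enumeration for n <= 12."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if sides not in ("one", "two"):
        raise ValidationError(f"sides must be 'one' or 'two': {sides!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    note = "midranks for ties" if has_ties else ""

    if n <= EXACT_RANK_SUM_CAP:
        stats = [
            sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), n_a)
        ]
        stats = np.asarray(stats)
        eps = 1e-9
        if sides == "two":
            p = float(np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - eps))
        else:
            p = float(np.mean(stats >= w_obs - eps))
        return GroupComparison(w_obs, p, EXACT, n_a, n_b, note)

    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return GroupComparison(w_obs, 1.0, APPROX, n_a, n_b, "all values tied")
    diff = w_obs - mu
    if sides == "two":
        z = (abs(diff) - 0.5) / math.sqrt(var)
        p = 2.0 * norm.sf(max(z, 0.0))
    else:
        z = (diff - 0.5) / math.sqrt(var)
        p = float(norm.sf(z))
    return GroupComparison(w_obs, float(min(p, 1.0)), APPROX, n_a, n_b, note)


# -- signed-rank (paired Wilcoxon) -------------------------------------------


def signed_rank_test(differences: Sequence[float], sides: str = "two") -> GroupComparison:
    """Wilcoxon signed-rank on paired differences, zeros dropped, midranks
    for tied magnitudes; exact by sign enumeration for nonzero n <= 15."""
    d = np.asarray(differences, dtype=float)
    if sides not in ("one", "two"):
        raise ValidationError(f"sides must be 'one' or 'two': {sides!r}")
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all differences are zero; signed-rank test degenerate")
    m = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    has_ties = len(np.unique(np.abs(d))) < m
    note = "zeros dropped" + ("; midranks for tied magnitudes" if has_ties else "")

    if m <= EXACT_SIGNED_RANK_CAP:
        eps = 1e-9
        count = 0
        total = 1 << m
        obs_dev = abs(w_plus - mu)
        for mask in range(total):
            w = 0.0
            for i in range(m):
                if mask >> i & 1:
                    w += ranks[i]
            if sides == "two":
                if abs(w - mu) >= obs_dev - eps:
                    count += 1
            else:
                if w >= w_plus - eps:
                    count += 1
        return GroupComparison(w_plus, count / total, EXACT, m, m, note)

    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 2.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term / 24.0
    diff = w_plus - mu
    if sides == "two":
        z = (abs(diff) - 0.5) / math.sqrt(var)
        p = 2.0 * norm.sf(max(z, 0.0))
    else:
        z = (diff - 0.5) / math.sqrt(var)
        p = float(norm.sf(z))
    return GroupComparison(w_plus, float(min(p, 1.0)), APPROX, m, m, note)


# -- within-patient ranking --------------------------------------------------


def ranking_proportions(
    results: pd.DataFrame, method: AssessmentMethod
) -> Dict[str, float]:
    """Count and percent of patients whose HCV-viremic transplant utility is
    strictly below their hemodialysis utility under the given method."""
    col_hcv = f"utility_{method.value}_{HealthState.TX_HCV_VIREMIC.value}"
    col_hemo = f"utility_{method.value}_{HealthState.HEMODIALYSIS.value}"
    for col in (col_hcv, col_hemo):
        if col not in results.columns:
            raise ValidationError(f"results table missing column {col}")
    sub = results[[col_hcv, col_hemo]]
    complete = sub.dropna()
    count = int((complete[col_hcv] < complete[col_hemo]).sum())
    n = len(complete)
    if n == 0:
        raise ValidationError("no patients with both utilities present")
    return {
        "count": count,
        "n": n,
        "percent": int(math.floor(100.0 * count / n + 0.5)),
        "excluded": len(sub) - n,
    }


# -- correlations and subgroup contrasts -------------------------------------


def _sg_decrement(results: pd.DataFrame) -> pd.Series:
    """Per-patient U_SG(HCV-viremic tx) - U_SG(hemodialysis)."""
    col_hcv = f"utility_sg_{HealthState.TX_HCV_VIREMIC.value}"
    col_hemo = f"utility_sg_{HealthState.HEMODIALYSIS.value}"
    for col in (col_hcv, col_hemo):
        if col not in results.columns:
            raise ValidationError(f"results table missing column {col}")
    return results[col_hcv] - results[col_hemo]


def vintage_correlation(results: pd.DataFrame) -> float:
    """Pearson r between the SG HCV-vs-hemodialysis decrement and vintage."""
    from scipy.stats import pearsonr

    dec = _sg_decrement(results)
    vintage = results["vintage_years"]
    ok = dec.notna() & vintage.notna()
    dec, vintage = dec[ok], vintage[ok]
    if len(dec) < 3:
        raise ValidationError("need at least 3 patients for a correlation")
    if dec.nunique() < 2 or vintage.nunique() < 2:
        raise ValidationError("correlation undefined for constant input")
    return float(pearsonr(dec, vintage).statistic)


def subgroup_decrement(results: pd.DataFrame) -> Dict[str, object]:
    """Mean SG decrement by prior-transplant history plus the rank-sum test."""
    dec = _sg_decrement(results)
    flag = results["prior_transplant"].astype(bool)
    with_prior = dec[flag]
    without_prior = dec[~flag]
    if with_prior.empty or without_prior.empty:
        raise ValidationError("both prior-transplant levels must be nonempty")
    return {
        "mean_with_prior": float(with_prior.mean()),
        "mean_without_prior": float(without_prior.mean()),
        "comparison": rank_sum_test(with_prior, without_prior),
    }


# -- design-stage power ------------------------------------------------------


def power_two_sample_t(
    n_per_arm: int, delta: float, sd: float, alpha: float = 0.05, sides: int = 2
) -> float:
    """Power of the two-sample t test at n per arm (noncentral t)."""
    df = 2 * n_per_arm - 2
    ncp = (delta / sd) * math.sqrt(n_per_arm / 2.0)
    if sides == 2:
        crit = t_dist.ppf(1 - alpha / 2, df)
        return float(nct.sf(crit, df, ncp) + nct.cdf(-crit, df, ncp))
    crit = t_dist.ppf(1 - alpha, df)
    return float(nct.sf(crit, df, ncp))


def sample_size_two_sample_t(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    sides: int = 2,
) -> int:
    """Smallest integer n per arm attaining the target power (minimum 2)."""
    if delta <= 0 or sd <= 0:
        raise ValidationError("delta and sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValidationError("alpha and power must be in (0, 1)")
    if power <= alpha:
        raise ValidationError("target power must exceed alpha")
    n = 2
    while power_two_sample_t(n, delta, sd, alpha, sides) < power:
        n += 1
        if n > 10_000_000:
            raise ValidationError("required n exceeds 1e7; check inputs")
    return n


# -- stratified summary tables -----------------------------------------------

_METHOD_TITLES = {
    AssessmentMethod.VAS: "Visual analog scale",
    AssessmentMethod.SG: "Standard gamble",
    AssessmentMethod.TTO: "Time trade-off",
}


def stratified_summary(results: pd.DataFrame, stratifier: str) -> pd.DataFrame:
    """Mean (SD) per (method, state) overall and per stratum, with a rank-sum
    p per row — the layout of the published utility tables."""
    if stratifier not in results.columns:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    levels = sorted(results[stratifier].dropna().unique())
    if len(levels) < 2:
        raise ValidationError(f"stratifier {stratifier!r} has fewer than 2 levels")
    rows = []
    for method in AssessmentMethod:
        for state in ASSESSED_STATES:
            col = f"utility_{method.value}_{state.value}"
            if col not in results.columns:
                continue
            values = results[col]
            row = {
                "method": _METHOD_TITLES[method],
                "state": state.label,
                "overall_mean": round(float(values.mean()), 1),
                "overall_sd": round(float(values.std(ddof=1)), 1),
            }
            groups = []
            for level in levels:
                sub = values[results[stratifier] == level].dropna()
                groups.append(sub)
                row[f"{level}_mean"] = round(float(sub.mean()), 1)
                row[f"{level}_sd"] = round(float(sub.std(ddof=1)), 1)
            if len(levels) == 2:
                row["p_value"] = rank_sum_test(groups[0], groups[1]).p_value
            rows.append(row)
    return pd.DataFrame(rows)


def knowledge_summary(results: pd.DataFrame, stratifier: str) -> pd.DataFrame:
    """Pre/post/change mean (SD) per stratum with rank-sum p — Table-2 layout."""
    if stratifier not in results.columns:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    sub = results.drop_duplicates("patient_id").copy()
    sub["change"] = sub["knowledge_post"] - sub["knowledge_pre"]
    levels = sorted(sub[stratifier].dropna().unique())
    if len(levels) < 2:
        raise ValidationError(f"stratifier {stratifier!r} has fewer than 2 levels")
    rows = []
    for label, col in (
        ("Before test", "knowledge_pre"),
        ("After test", "knowledge_post"),
        ("Change score", "change"),
    ):
        row = {
            "test": label,
            "overall_mean": round(float(sub[col].mean()), 1),
            "overall_sd": round(float(sub[col].std(ddof=1)), 1),
        }
        groups = []
        for level in levels:
            vals = sub.loc[sub[stratifier] == level, col]
            groups.append(vals)
            row[f"{level}_mean"] = round(float(vals.mean()), 1)
            row[f"{level}_sd"] = round(float(vals.std(ddof=1)), 1)
        if len(levels) == 2:
            row["p_value"] = rank_sum_test(groups[0], groups[1]).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def radar_export(long_results: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-patient utilities per method/state for external radar plots."""
    cols = ["patient_id", "method", "state", "normalized"]
    missing = [c for c in cols if c not in long_results.columns]
    if missing:
        raise ValidationError(f"long results missing column(s): {', '.join(missing)}")
    return long_results[cols].sort_values(["method", "state", "patient_id"]).reset_index(
        drop=True
    )
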