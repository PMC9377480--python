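"""Randomization, exemplar-clip selection, and cohort file formats.

Arm assignment uses seeded permuted blocks (default size 4) so complete
blocks are balanced 1:1 between the race-matched and race-mismatched arms;
``block_size=0`` selects simple (coin-flip) randomization. The exemplar
inventory is the study's 12 clips: 3 assessed health states x 2 races x
2 genders; the matched arm serves the clip matching the patient's race and
gender, the mismatched arm flips race and keeps gender.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .utility import ASSESSED_STATES, HealthState

MATCHED = "matched"
MISMATCHED = "mismatched"

RACES = ("african_american", "european_american")
GENDERS = ("female", "male")


@dataclass(frozen=True)
class ArmAssignment:
    patient_id: str
    arm: str
    block: int
    seed: int


@dataclass(frozen=True)
class ExemplarClip:
    state: HealthState
    race: str
    gender: str

    @property
    def clip_id(self) -> str:
        return f"{self.state.value}-{self.race}-{self.gender}"


#: The full inventory: one clip per (assessed state, race, gender).
CLIP_INVENTORY = tuple(
    ExemplarClip(state=s, race=r, gender=g)
    for s in ASSESSED_STATES
    for r in RACES
    for g in GENDERS
)


def randomize_arm(
    patient_ids: Sequence[str], seed: int, block_size: int = 4
) -> List[ArmAssignment]:
    """Seeded permuted-block 1:1 randomization into matched/mismatched arms."""
    if not patient_ids:
        raise ValidationError("patient id list must not be empty")
    if block_size < 0 or block_size % 2 != 0:
        raise ValidationError(f"block_size must be a nonnegative even integer: {block_size}")
    rng = np.random.default_rng(seed)
    assignments: List[ArmAssignment] = []
    if block_size == 0:  # simple randomization
        for pid in patient_ids:
            arm = MATCHED if rng.uniform() < 0.5 else MISMATCHED
            assignments.append(ArmAssignment(pid, arm, block=0, seed=seed))
        return assignments
    half = block_size // 2
    for start in range(0, len(patient_ids), block_size):
        block_ids = patient_ids[start : start + block_size]
        arms = rng.permutation([MATCHED] * half + [MISMATCHED] * half)
        for pid, arm in zip(block_ids, arms):
            assignments.append(
                ArmAssignment(pid, str(arm), block=start // block_size, seed=seed)
            )
    return assignments


def select_exemplar(race: str, gender: str, state: HealthState, arm: str) -> ExemplarClip:
    """The clip shown to a patient: matched arm matches race and gender;
    mismatched arm flips race and keeps gender."""
    if race not in RACES:
        raise ValidationError(f"unknown race {race!r}; expected one of {RACES}")
    if gender not in GENDERS:
        raise ValidationError(f"unknown gender {gender!r}; expected one of {GENDERS}")
    if state not in ASSESSED_STATES:
        raise ValidationError(f"{state} has no exemplar clip")
    if arm == MATCHED:
        clip_race = race
    elif arm == MISMATCHED:
        clip_race = RACES[1] if race == RACES[0] else RACES[0]
    else:
        raise ValidationError(f"unknown arm {arm!r}")
    return ExemplarClip(state=state, race=clip_race, gender=gender)


# -- cohort CSV --------------------------------------------------------------

DEMOGRAPHIC_COLUMNS = (
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
)

UTILITY_PRECISION = 1  # utilities stored to 0.1
RAW_PRECISION = 4      # chained raw fractions stored to 1e-4


def _utility_columns(df: pd.DataFrame) -> List[str]:
    return [c for c in df.columns if c.startswith("utility_")]


def _raw_columns(df: pd.DataFrame) -> List[str]:
    return [c for c in df.columns if c.startswith("raw_")]


def write_cohort_csv(results: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the wide per-patient results table (see ``results_wide``)."""
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing column(s): {', '.join(missing)}")
    out = results.copy()
    for col in _utility_columns(out):
        out[col] = out[col].round(UTILITY_PRECISION)
    for col in _raw_columns(out):
        out[col] = out[col].round(RAW_PRECISION)
    out.to_csv(path, index=False)


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort results CSV written by write_cohort_csv."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty cohort file: {path}") from exc
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort file missing column(s): {', '.join(missing)}")
    known = set(DEMOGRAPHIC_COLUMNS)
    unknown = [
        c
        for c in df.columns
        if c not in known and not (c.startswith("utility_") or c.startswith("raw_"))
    ]
    if unknown:
        raise FormatError(f"unknown column(s): {', '.join(unknown)}")
    for col in _utility_columns(df):
        bad = df[(df[col] < 0) | (df[col] > 100)]
        if not bad.empty:
            raise FormatError(
                f"{col} outside [0, 100] for patient {bad['patient_id'].iloc[0]}"
            )
    for col in _raw_columns(df):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if not bad.empty:
            raise FormatError(
                f"{col} outside [0, 1] for patient {bad['patient_id'].iloc[0]}"
            )
    if df["arm"].isin([MATCHED, MISMATCHED]).sum() != len(df):
        raise FormatError("arm column must be matched/mismatched")
    return df
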