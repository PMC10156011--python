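"""Factorial trial construction and simulation drivers.

Experiment 1 (emotion categorization): every base recording is paired
with its happy, sad, and afraid transformations — 96 manipulated pairs
per main language (3 emotions x 4 sentences x 4 conditions x 2 speakers)
plus 24 for the unfamiliar-language control (normal condition only) —
and, optionally, one neutral (identical) pair per base item. Each trial
presents the neutral recording first and the comparison second;
listeners pick one of four labels.

Experiment 2 (pitch-change detection): the 64 untransformed main-language
recordings are presented in three blocks; on each trial one of the two
presentations carries a sudden positive pitch shift with onset uniform in
400-600 ms. The shift magnitude is fixed per speaker sex at the threshold
from a per-participant adaptive staircase run beforehand on native
normal-type sentences.

The drivers in this module run simulated listeners over those designs and
return tidy response tables ready for the stats layer. Cohort-level
helpers (``simulate_exp1_cohort``, ``simulate_exp2_cohort``) compute the
same quantities through closed-form response distributions — one
multinomial per design cell instead of per-trial draws — for studies that
repeat the whole experiment hundreds of times (power and type-I
calibration curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import psychophysics as psy
from .observers import (
    CATEGORIES,
    EmotionObserver,
    PsychometricObserver,
    category_templates,
    respond_2ifc,
    respond_emotion,
    simulate_confusion,
)
from .stats import ConfusionTable, hit_rates
from .voicegen import SentenceMeta, build_sentence_inventory

__all__ = [
    "TrialRecord",
    "Participant",
    "build_exp1_trials",
    "build_exp2_trials",
    "simulate_exp1",
    "simulate_exp2",
    "simulate_exp1_cohort",
    "simulate_exp2_cohort",
    "trials_to_frame",
]

EMOTIONS = ("happy", "sad", "afraid")
ISI_RANGE_S = (0.7, 1.3)
STEP_ONSET_RANGE_MS = (400.0, 600.0)


@dataclass(frozen=True)
class TrialRecord:
    """One two-interval trial.

    The first interval is always the unmanipulated (neutral) recording;
    the second is the comparison — an emotional transformation, the same
    recording again (neutral trials), or, in the detection task, the
    pitch-stepped version placed in ``target_interval`` 1 or 2.
    """

    language: str
    condition: str
    sentence_id: int
    speaker: str
    emotion: str | None = None  # Exp 1 comparison category
    level_cents: float | None = None  # Exp 2 step magnitude
    onset_ms: float | None = None  # Exp 2 step onset
    target_interval: int = 2
    block: int = 1
    isi_s: float = 1.0

    def __post_init__(self) -> None:
        if not ISI_RANGE_S[0] <= self.isi_s <= ISI_RANGE_S[1]:
            raise ValueError("inter-stimulus interval outside 0.7-1.3 s")
        if self.onset_ms is not None and not (
            STEP_ONSET_RANGE_MS[0] <= self.onset_ms <= STEP_ONSET_RANGE_MS[1]
        ):
            raise ValueError("pitch-step onset outside 400-600 ms")
        if self.target_interval not in (1, 2):
            raise ValueError("target_interval must be 1 or 2")


@dataclass(frozen=True)
class Participant:
    participant_id: int
    group: str  # native language: "FR" or "JP"
    observer: object  # EmotionObserver or PsychometricObserver

    def is_native(self, stimulus_language: str) -> bool:
        return stimulus_language == self.group


def _base_items(inventory: Sequence[SentenceMeta]) -> list[SentenceMeta]:
    return list(inventory)


def build_exp1_trials(
    inventory: Sequence[SentenceMeta] | None = None,
    emotions: Sequence[str] = EMOTIONS,
    include_neutral: bool = True,
    seed: int = 0,
) -> list[TrialRecord]:
    """Emotion-categorization trial list.

    With the default inventory this yields 96 manipulated trials each for
    JP and FR, 24 for SE, plus one neutral pair per base item when
    ``include_neutral`` is set. Trial order is shuffled by ``seed``; the
    trial multiset does not depend on the seed.
    """
    if inventory is None:
        inventory = build_sentence_inventory()
    rng = np.random.default_rng(seed)
    trials = []
    for meta in _base_items(inventory):
        comparisons = list(emotions) + (["neutral"] if include_neutral else [])
        for emotion in comparisons:
            trials.append(
                TrialRecord(
                    language=meta.language,
                    condition=meta.condition,
                    sentence_id=meta.sentence_id,
                    speaker=meta.speaker,
                    emotion=emotion,
                    isi_s=float(rng.uniform(*ISI_RANGE_S)),
                )
            )
    rng.shuffle(trials)
    return trials


def build_exp2_trials(
    inventory: Sequence[SentenceMeta] | None = None,
    shift_cents_by_speaker_sex: dict[str, float] | None = None,
    n_blocks: int = 3,
    seed: int = 0,
) -> list[TrialRecord]:
    """Pitch-change detection trial list: ``n_blocks`` x 64 trials.

    Each block presents every untransformed JP/FR recording once (4
    sentences x 4 conditions x 2 speakers x 2 languages), shuffled within
    block; the step onset is uniform in 400-600 ms per trial and the
    target interval is balanced-random. The step magnitude is the
    calibrated shift for the stimulus speaker's sex.
    """
    if shift_cents_by_speaker_sex is None:
        raise ValueError("calibrated shift per speaker sex is required")
    if inventory is None:
        inventory = build_sentence_inventory(languages=("JP", "FR"))
    items = [m for m in inventory if m.language in ("JP", "FR")]
    for m in items:
        if m.speaker not in shift_cents_by_speaker_sex:
            raise ValueError(f"missing calibrated shift for speaker sex {m.speaker!r}")
    rng = np.random.default_rng(seed)
    trials = []
    for block in range(1, n_blocks + 1):
        order = list(items)
        rng.shuffle(order)
        # balanced-random target interval within block
        intervals = [1, 2] * (len(order) // 2) + [rng.integers(1, 3)] * (len(order) % 2)
        rng.shuffle(intervals)
        for meta, interval in zip(order, intervals):
            trials.append(
                TrialRecord(
                    language=meta.language,
                    condition=meta.condition,
                    sentence_id=meta.sentence_id,
                    speaker=meta.speaker,
                    level_cents=float(shift_cents_by_speaker_sex[meta.speaker]),
                    onset_ms=float(rng.uniform(*STEP_ONSET_RANGE_MS)),
                    target_interval=int(interval),
                    block=block,
                    isi_s=float(rng.uniform(*ISI_RANGE_S)),
                )
            )
    return trials


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trials])


# ---------------------------------------------------------------------------
# trial-level simulation

def simulate_exp1(
    trials: Sequence[TrialRecord],
    participants: Sequence[Participant],
    seed: int = 0,
) -> pd.DataFrame:
    """Run emotion observers over a categorization trial list.

    Returns one row per trial per participant with the sampled response
    category. Stimulus cues are the category templates (transform
    parameters are identical across languages by design, so the cue
    vector depends only on the comparison category).
    """
    templates = category_templates()
    rows = []
    root = np.random.SeedSequence(seed)
    for part, ss in zip(participants, root.spawn(len(participants))):
        rng = np.random.default_rng(ss)
        for trial in trials:
            native = part.is_native(trial.language)
            resp = respond_emotion(
                part.observer, templates[trial.emotion], native, rng, trial.condition
            )
            rows.append(
                {
                    "participant_id": part.participant_id,
                    "group": part.group,
                    "stimulus_language": trial.language,
                    "condition": trial.condition,
                    "sentence_id": trial.sentence_id,
                    "speaker": trial.speaker,
                    "true_category": trial.emotion,
                    "response_category": resp,
                    "correct": resp == trial.emotion,
                }
            )
    return pd.DataFrame(rows)


def simulate_exp2(
    participants: Sequence[Participant],
    inventory: Sequence[SentenceMeta] | None = None,
    n_blocks: int = 3,
    seed: int = 0,
    staircase_config: psy.StaircaseConfig = psy.StaircaseConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full detection experiment: calibration staircases, then test blocks.

    Each participant first runs one adaptive staircase per speaker sex on
    native-language stimuli; the two converged thresholds set the fixed
    step magnitudes for their test trials (identical across languages and
    conditions, mirroring the calibrated design). Returns ``(responses,
    calibration)`` tables.
    """
    if inventory is None:
        inventory = build_sentence_inventory(languages=("JP", "FR"))
    rows, calib_rows = [], []
    root = np.random.SeedSequence(seed)
    for part, ss in zip(participants, root.spawn(len(participants))):
        rng = np.random.default_rng(ss)
        obs: PsychometricObserver = part.observer
        thresholds = {}
        for sex in ("male", "female"):
            threshold, state = psy.run_staircase(
                lambda level, r: respond_2ifc(obs, level, True, r),
                staircase_config,
                rng,
            )
            thresholds[sex] = threshold
            calib_rows.append(
                {
                    "participant_id": part.participant_id,
                    "group": part.group,
                    "speaker": sex,
                    "threshold_cents": threshold,
                    "n_trials": state.n_trials,
                    "n_reversals": state.n_reversals,
                }
            )
        trials = build_exp2_trials(
            inventory, thresholds, n_blocks, seed=int(rng.integers(2**31))
        )
        for trial in trials:
            native = part.is_native(trial.language)
            correct = respond_2ifc(obs, trial.level_cents, native, rng)
            rows.append(
                {
                    "participant_id": part.participant_id,
                    "group": part.group,
                    "stimulus_language": trial.language,
                    "condition": trial.condition,
                    "sentence_id": trial.sentence_id,
                    "speaker": trial.speaker,
                    "level_cents": trial.level_cents,
                    "onset_ms": trial.onset_ms,
                    "block": trial.block,
                    "correct": bool(correct),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(calib_rows)


# ---------------------------------------------------------------------------
# cohort-level simulation (closed-form response distributions)

def _heterogeneous(base: float, sd_log: float, rng: np.random.Generator) -> float:
    """Lognormal individual difference around a population value."""
    return float(base * np.exp(sd_log * rng.standard_normal()))


def simulate_exp1_cohort(
    n_fr: int = 20,
    n_jp: int = 21,
    precision_native: float = 0.25,
    precision_foreign: float = 0.17,
    n_per_category: int = 8,
    between_subject_sd_log: float = 0.25,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """One categorization cohort: per-participant mean unbiased hit rate
    (over the three emotion categories) for native and foreign stimuli.

    Participants' precisions vary lognormally around the population
    values (individual differences); each participant contributes
    ``n_per_category`` trials per category per language (default 8 = 4
    sentences x 2 speakers, the normal-condition cell). Setting
    ``precision_foreign = precision_native`` yields a null cohort with no
    familiarity gap.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    pid = 0
    for group, n_group in (("FR", n_fr), ("JP", n_jp)):
        for _ in range(n_group):
            pid += 1
            scale = np.exp(between_subject_sd_log * rng.standard_normal())
            obs = EmotionObserver(
                precision_native=precision_native * scale,
                precision_foreign=min(precision_foreign * scale,
                                      precision_native * scale),
            )
            for language in ("FR", "JP"):
                native = language == group
                counts = simulate_confusion(obs, n_per_category, native, rng)
                metrics = hit_rates(ConfusionTable(counts, CATEGORIES))
                emo = [metrics.h_unbiased[CATEGORIES.index(e)] for e in EMOTIONS]
                rows.append(
                    {
                        "subject": pid,
                        "group": group,
                        "language": language,
                        "native": native,
                        "y": float(np.mean(emo)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_exp2_cohort(
    n_fr: int = 24,
    n_jp: int = 20,
    threshold_cents: float = 80.0,
    slope: float = 4.5,
    lapse_rate: float = 0.02,
    familiarity_gain: float = 1.2,
    n_trials_per_language: int = 96,
    between_subject_sd_log: float = 0.25,
    staircase_config: psy.StaircaseConfig = psy.StaircaseConfig(),
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """One detection cohort: per-participant accuracy by stimulus language.

    Each participant's sensitivity varies lognormally around the
    population threshold. Their two calibration staircases (native
    stimuli, one per speaker sex) are simulated trial-by-trial; test
    accuracy per language pools the binomial outcomes of
    ``n_trials_per_language`` trials at the fixed calibrated levels
    (half per speaker sex). ``familiarity_gain = 1`` gives a null cohort.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    pid = 0
    for group, n_group in (("FR", n_fr), ("JP", n_jp)):
        for _ in range(n_group):
            pid += 1
            obs = PsychometricObserver(
                threshold_cents=_heterogeneous(threshold_cents, between_subject_sd_log, rng),
                slope=slope,
                lapse_rate=lapse_rate,
                familiarity_gain=familiarity_gain,
            )
            levels = []
            for _sex in ("male", "female"):
                thr, _ = psy.run_staircase(
                    lambda level, r: respond_2ifc(obs, level, True, r),
                    staircase_config,
                    rng,
                )
                levels.append(thr)
            n_half = n_trials_per_language // 2
            for language in ("FR", "JP"):
                native = language == group
                n_correct = sum(
                    rng.binomial(n_half, obs.p_correct(lv, native)) for lv in levels
                )
                rows.append(
                    {
                        "subject": pid,
                        "group": group,
                        "language": language,
                        "native": native,
                        "y": n_correct / (2 * n_half),
                        "threshold_male": levels[0],
                        "threshold_female": levels[1],
                    }
                )
    return pd.DataFrame(rows)
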