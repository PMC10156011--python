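"""Synthetic utterance generation: source-filter stand-ins for recorded speech.

The experiments this package reproduces were run on 1.5 s recorded
sentences in Japanese (JP), French (FR), and Swedish (SE), RMS-normalized
in intensity. Recorded speech is out of scope here; instead this module
synthesizes voiced utterances with a controllable F0 contour, formant
resonances, and syllable-like amplitude modulation. These carry enough
harmonic structure for F0 tracking and spectral-filter verification, which
is all the downstream pipeline needs.

The sentence inventory is purely metadata: 4 sentences per language, in
normal / jabberwocky (pseudo-word) / shuffled (scrambled word order) /
reversed variants, spoken by a male and a female speaker. Degraded
variants of a synthetic utterance differ only in metadata — and, for the
reversed condition, by actual time reversal — because synthetic audio
carries no semantics or syntax to degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .waveform import (
    DegenerateSignalError,
    Waveform,
    read_wav,
    reverse_waveform,
    rms_normalize,
    write_wav,
)

__all__ = [
    "Waveform",
    "UtterancePlan",
    "SentenceMeta",
    "InvalidPlanError",
    "DegenerateSignalError",
    "synthesize_utterance",
    "reverse_waveform",
    "rms_normalize",
    "build_sentence_inventory",
    "inventory_to_csv",
    "default_plan",
    "flat_vowel",
    "read_wav",
    "write_wav",
    "LANGUAGES",
    "CONDITIONS",
    "SPEAKERS",
    "SENTENCE_TEXTS",
]

DEFAULT_SAMPLE_RATE = 22050
DEFAULT_DURATION_S = 1.5
DEFAULT_TARGET_RMS = 0.05

LANGUAGES = ("JP", "FR", "SE")
CONDITIONS = ("normal", "jabberwocky", "shuffled", "reversed")
SPEAKERS = ("male", "female")

# 4 semantically neutral sentences per language; JP/FR carry normal,
# jabberwocky (content words -> same-syllable pseudo-words) and shuffled
# (scrambled word order) text variants; SE exists in the normal condition
# only (unfamiliar-language baseline) with placeholder texts.
SENTENCE_TEXTS: dict[tuple[str, str], tuple[str, ...]] = {
    ("JP", "normal"): (
        "Uwagi wo wasureta",
        "Kaigi ni itta",
        "Hikouki wa ippai",
        "Hyoumen wa nameraka",
    ),
    ("JP", "jabberwocky"): (
        "Etaki wo morushita",
        "Goito ni etta",
        "Komeubi wa ottai",
        "Bouren wa soniyaka",
    ),
    ("JP", "shuffled"): (
        "Wo morushita etaki",
        "Etta ni goite",
        "Komeubi ottai wa",
        "Bouren soniyaka wa",
    ),
    ("FR", "normal"): (
        "J'ai oublié mon pardessus",
        "Je suis allé à la réunion",
        "L'avion est complet",
        "La surface est lisse",
    ),
    ("FR", "jabberwocky"): (
        "J'ai odrié mon tarpodu",
        "Je suis ijé à la boussion",
        "L'ation est bondret",
        "La borpaque est nitte",
    ),
    ("FR", "shuffled"): (
        "Odrié j'ai tarpodu mon",
        "Boussion ijé la je à suis",
        "L'est ation bondret",
        "La est nitte borpaque",
    ),
    ("SE", "normal"): (
        "SE sentence 1",
        "SE sentence 2",
        "SE sentence 3",
        "SE sentence 4",
    ),
}

# typical adult vowel formants (center Hz, bandwidth Hz) per speaker sex
FORMANTS = {
    "male": ((600.0, 90.0), (1200.0, 110.0), (2500.0, 160.0)),
    "female": ((730.0, 100.0), (1450.0, 120.0), (2900.0, 180.0)),
}
F0_BASE = {"male": 120.0, "female": 210.0}


class InvalidPlanError(ValueError):
    """Raised for an unrealizable utterance plan."""


@dataclass(frozen=True)
class UtterancePlan:
    """Recipe for one synthetic utterance.

    ``f0_contour`` is a piecewise-linear cents-offset curve relative to
    ``f0_base``, given as (time_s, offset_cents) breakpoints; an empty
    contour means a flat F0. ``voiced_segments`` are (start_s, end_s)
    intervals inside which the glottal source is active; the rest is
    silence (no aspiration noise is modeled). Syllables are realized as
    amplitude modulation across the voiced span.
    """

    duration_s: float = DEFAULT_DURATION_S
    f0_base: float = 200.0
    f0_contour: tuple[tuple[float, float], ...] = ()
    formants: tuple[tuple[float, float], ...] = FORMANTS["female"]
    voiced_segments: tuple[tuple[float, float], ...] = ((0.05, 1.45),)
    syllable_count: int = 7

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise InvalidPlanError("duration_s must be positive")
        if self.f0_base <= 0:
            raise InvalidPlanError("f0_base must be positive")
        if self.syllable_count < 1:
            raise InvalidPlanError("syllable_count must be >= 1")
        prev_end = 0.0
        for start, end in sorted(self.voiced_segments):
            if not (0.0 <= start < end <= self.duration_s + 1e-9):
                raise InvalidPlanError(
                    f"voiced segment ({start}, {end}) outside [0, {self.duration_s}]"
                )
            if start < prev_end - 1e-9:
                raise InvalidPlanError("voiced segments must not overlap")
            prev_end = end


def default_plan(
    speaker: str = "female",
    duration_s: float = DEFAULT_DURATION_S,
    syllable_count: int = 7,
    f0_base: float | None = None,
) -> UtterancePlan:
    """Plan a typical declarative utterance for one speaker sex.

    The default F0 contour rises slightly onto the utterance and declines
    toward its end, mimicking a declarative declination line.
    """
    if speaker not in SPEAKERS:
        raise ValueError(f"unknown speaker sex: {speaker!r}")
    base = F0_BASE[speaker] if f0_base is None else f0_base
    contour = (
        (0.0, -80.0),
        (0.12 * duration_s, 60.0),
        (0.75 * duration_s, 0.0),
        (duration_s, -180.0),
    )
    return UtterancePlan(
        duration_s=duration_s,
        f0_base=base,
        f0_contour=contour,
        formants=FORMANTS[speaker],
        voiced_segments=((0.04 * duration_s, 0.96 * duration_s),),
        syllable_count=syllable_count,
    )


def flat_vowel(
    f0_hz: float = 200.0,
    duration_s: float = DEFAULT_DURATION_S,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    speaker: str = "female",
) -> Waveform:
    """Steady vowel with a flat F0 — the workhorse verification stimulus."""
    plan = UtterancePlan(
        duration_s=duration_s,
        f0_base=f0_hz,
        f0_contour=(),
        formants=FORMANTS[speaker],
        voiced_segments=((0.0, duration_s),),
        syllable_count=1,
    )
    return synthesize_utterance(plan, sample_rate, seed)


def _f0_track(plan: UtterancePlan, t: np.ndarray, rng: np.random.Generator,
              jitter_frac: float) -> np.ndarray:
    """Per-sample F0 in Hz from the plan's cents-offset breakpoints."""
    if plan.f0_contour:
        pts = np.asarray(plan.f0_contour, dtype=np.float64)
        cents = np.interp(t, pts[:, 0], pts[:, 1])
    else:
        cents = np.zeros_like(t)
    f0 = plan.f0_base * np.exp2(cents / 1200.0)
    if jitter_frac > 0:
        # slow multiplicative jitter: smooth noise resampled from ~30 Hz
        n_ctrl = max(int(plan.duration_s * 30), 4)
        ctrl = rng.standard_normal(n_ctrl)
        jit = np.interp(t, np.linspace(t[0], t[-1], n_ctrl), ctrl)
        f0 = f0 * (1.0 + jitter_frac * jit)
    return f0


def synthesize_utterance(
    plan: UtterancePlan,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    jitter_frac: float = 0.001,
    shimmer_frac: float = 0.03,
) -> Waveform:
    """Source-filter synthesis of one utterance.

    The glottal source is a band-limited harmonic pulse train (harmonics up
    to Nyquist, 1/h amplitude roll-off) following the plan's F0 contour,
    with mild seeded jitter and shimmer. The source is shaped by a parallel
    bank of second-order formant resonators, gated by the voiced segments
    with 10 ms raised-cosine edges, amplitude-modulated per syllable, and
    RMS-normalized to the package default.
    """
    plan.validate()
    if sample_rate < 8000:
        raise InvalidPlanError("sample_rate must be at least 8000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(plan.duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    f0 = _f0_track(plan, t, rng, jitter_frac)
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate

    # band-limited pulse train: all harmonics below 95% of Nyquist
    f0_max = float(np.max(f0))
    n_harm = max(int(0.95 * sample_rate / 2 / f0_max), 1)
    h = np.arange(1, n_harm + 1)
    # zero out harmonics that would alias for any sample
    source = np.zeros(n)
    for k in h:
        amp = 1.0 / k
        source += amp * np.sin(k * phase)
    source /= np.max(np.abs(source)) + 1e-12

    # parallel formant resonator bank
    shaped = np.zeros(n)
    nyq = sample_rate / 2
    for fc, bw in plan.formants:
        if fc >= nyq:
            continue
        r = np.exp(-np.pi * bw / sample_rate)
        theta = 2 * np.pi * fc / sample_rate
        b = [1.0 - r]
        a = [1.0, -2 * r * np.cos(theta), r * r]
        shaped += sps.lfilter(b, a, source)
    if not plan.formants:
        shaped = source

    # voicing gate with raised-cosine 10 ms edges
    gate = np.zeros(n)
    edge = max(int(0.010 * sample_rate), 1)
    for start, end in plan.voiced_segments:
        i0, i1 = int(round(start * sample_rate)), min(int(round(end * sample_rate)), n)
        if i1 <= i0:
            continue
        seg = np.ones(i1 - i0)
        e = min(edge, (i1 - i0) // 2)
        if e > 0:
            ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, e)))
            seg[:e] = ramp
            seg[-e:] = ramp[::-1]
        gate[i0:i1] = np.maximum(gate[i0:i1], seg)

    # syllable-like amplitude modulation over the voiced span
    if plan.syllable_count > 1 and plan.voiced_segments:
        span0 = min(s for s, _ in plan.voiced_segments)
        span1 = max(e for _, e in plan.voiced_segments)
        syl_rate = plan.syllable_count / max(span1 - span0, 1e-6)
        am = 1.0 - 0.35 * 0.5 * (1 + np.cos(2 * np.pi * syl_rate * (t - span0)))
        gate = gate * am

    # shimmer: slow multiplicative amplitude perturbation
    if shimmer_frac > 0:
        n_ctrl = max(int(plan.duration_s * 20), 4)
        ctrl = rng.standard_normal(n_ctrl)
        shim = np.interp(t, np.linspace(0, plan.duration_s, n_ctrl), ctrl)
        gate = gate * (1.0 + shimmer_frac * shim)

    out = shaped * gate
    w = Waveform(out if np.any(out) else out + 0.0, sample_rate)
    if w.rms() > 0:
        w = rms_normalize(w, DEFAULT_TARGET_RMS)
    return w


@dataclass(frozen=True)
class SentenceMeta:
    """Metadata for one base recording in the stimulus inventory."""

    language: str
    condition: str
    sentence_id: int
    speaker: str
    text: str
    file: str = ""

    def __post_init__(self) -> None:
        if self.language not in LANGUAGES:
            raise ValueError(f"unknown language: {self.language!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.language == "SE" and self.condition != "normal":
            raise ValueError("SE exists only in the normal condition")
        if self.speaker not in SPEAKERS:
            raise ValueError(f"unknown speaker sex: {self.speaker!r}")
        if not 1 <= self.sentence_id <= 4:
            raise ValueError("sentence_id must be in 1..4")


def build_sentence_inventory(
    languages: Sequence[str] = ("JP", "FR", "SE"),
    conditions: Sequence[str] = CONDITIONS,
    speakers: Sequence[str] = SPEAKERS,
    n_sentences: int = 4,
) -> list[SentenceMeta]:
    """Full factorial base-stimulus inventory.

    JP and FR cross ``n_sentences`` sentences × the requested conditions ×
    speaker sexes (default 4 × 4 × 2 = 32 items per language); SE
    contributes normal-condition items only (4 × 2 = 8 by default).
    """
    for lang in languages:
        if lang not in LANGUAGES:
            raise ValueError(f"unknown language: {lang!r}")
    for cond in conditions:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition: {cond!r}")
    for spk in speakers:
        if spk not in SPEAKERS:
            raise ValueError(f"unknown speaker sex: {spk!r}")
    items = []
    for lang in languages:
        langconds = ("normal",) if lang == "SE" else tuple(conditions)
        for cond in langconds:
            # reversed recordings reuse the normal sentences, played backwards
            texts = SENTENCE_TEXTS[(lang, "normal" if cond == "reversed" else cond)]
            for sid in range(1, n_sentences + 1):
                for spk in speakers:
                    items.append(
                        SentenceMeta(
                            language=lang,
                            condition=cond,
                            sentence_id=sid,
                            speaker=spk,
                            text=texts[(sid - 1) % len(texts)],
                        )
                    )
    return items


def inventory_to_csv(items: Sequence[SentenceMeta], path) -> None:
    """Serialize an inventory as CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "language": m.language,
                "condition": m.condition,
                "sentence_id": m.sentence_id,
                "speaker": m.speaker,
                "text": m.text,
                "file": m.file,
            }
            for m in items
        ]
    ).to_csv(path, index=False)


def synthesize_inventory_item(
    meta: SentenceMeta,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> Waveform:
    """Render the base (neutral) waveform for one inventory item.

    The seed is combined with the item's identity so each (language,
    sentence, speaker) triple gets a stable, distinct rendering; the
    jabberwocky and shuffled conditions share their normal counterpart's
    audio (only metadata differs), and the reversed condition is the
    normal rendering played backwards.
    """
    ident = (meta.language, meta.sentence_id, meta.speaker)
    sub = np.random.SeedSequence([seed, abs(hash(ident)) % (2**31)])
    item_seed = int(sub.generate_state(1)[0] % (2**31))
    plan = default_plan(speaker=meta.speaker, syllable_count=6 + meta.sentence_id % 3)
    # vary the declination endpoint a little per sentence
    plan = replace(
        plan,
        f0_contour=tuple(
            (tt, cc + 10.0 * ((meta.sentence_id % 4) - 1.5)) for tt, cc in plan.f0_contour
        ),
    )
    w = synthesize_utterance(plan, sample_rate, item_seed)
    if meta.condition == "reversed":
        w = reverse_waveform(w)
    return w
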