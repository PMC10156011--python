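"""Fundamental-frequency estimation and cents-scale utilities.

Pitch is represented on the cents scale throughout: 100 cents is one
semitone, and a frequency ratio maps to cents as ``1200 * log2(ratio)``.
Contours are plotted and compared relative to a 200 Hz reference by
default, matching the convention used for female-speaker utterances.

The F0 estimator is a frame-based autocorrelation tracker: each frame's
normalized autocorrelation is searched for its strongest peak in the lag
band corresponding to [fmin, fmax], with parabolic interpolation of the
peak lag for sub-sample precision. Frames with a weak periodicity peak or
negligible energy are marked unvoiced. On clean synthetic vowels this is
accurate to well under 3 cents, which is the verification currency every
voice transformation in this package is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import Waveform

__all__ = [
    "F0Contour",
    "PitchCurve",
    "hz_to_cents",
    "cents_to_ratio",
    "ratio_to_cents",
    "estimate_f0",
    "measure_offset",
    "contour_to_csv",
    "plot_contours",
]

DEFAULT_REFERENCE_HZ = 200.0


def hz_to_cents(f, reference: float = DEFAULT_REFERENCE_HZ):
    """Convert frequency to cents relative to a reference frequency."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f <= 0) or reference <= 0:
        raise ValueError("frequencies must be positive")
    out = 1200.0 * np.log2(f / reference)
    return float(out) if out.ndim == 0 else out


def cents_to_ratio(c):
    """Frequency ratio corresponding to a shift in cents: ``2**(c/1200)``."""
    c = np.asarray(c, dtype=np.float64)
    out = np.exp2(c / 1200.0)
    return float(out) if out.ndim == 0 else out


def ratio_to_cents(r):
    """Inverse of :func:`cents_to_ratio`."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    out = 1200.0 * np.log2(r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class F0Contour:
    """Frame-wise fundamental-frequency track.

    ``f0_hz`` is NaN on unvoiced frames; ``times`` are frame centers.
    """

    times: np.ndarray = field(repr=False)
    f0_hz: np.ndarray = field(repr=False)
    frame_step_s: float = 0.01

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        f0 = np.asarray(self.f0_hz, dtype=np.float64)
        if times.shape != f0.shape:
            raise ValueError("times and f0_hz must have matching shapes")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f0[np.isfinite(f0)] <= 0):
            raise ValueError("voiced F0 values must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f0_hz", f0)

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0_hz)

    def median_f0(self) -> float:
        """Median F0 over voiced frames (NaN if fully unvoiced)."""
        v = self.f0_hz[self.voiced]
        return float(np.median(v)) if v.size else float("nan")

    def to_cents(self, reference: float = DEFAULT_REFERENCE_HZ) -> "PitchCurve":
        """Express the contour as cents offsets relative to ``reference``."""
        offs = np.full_like(self.f0_hz, np.nan)
        v = self.voiced
        offs[v] = 1200.0 * np.log2(self.f0_hz[v] / reference)
        return PitchCurve(self.times.copy(), offs, reference)


@dataclass(frozen=True)
class PitchCurve:
    """Cents-offset contour relative to a reference frequency (default 200 Hz)."""

    times: np.ndarray = field(repr=False)
    offset_cents: np.ndarray = field(repr=False)
    reference_hz: float = DEFAULT_REFERENCE_HZ

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        offs = np.asarray(self.offset_cents, dtype=np.float64)
        if times.shape != offs.shape:
            raise ValueError("times and offset_cents must have matching shapes")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "offset_cents", offs)

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.offset_cents)

    def median_offset(self, t_min: float = -np.inf, t_max: float = np.inf) -> float:
        """Median cents offset over voiced frames within ``[t_min, t_max]``."""
        sel = self.voiced & (self.times >= t_min) & (self.times <= t_max)
        v = self.offset_cents[sel]
        return float(np.median(v)) if v.size else float("nan")

    def max_abs_offset(self) -> float:
        v = self.offset_cents[self.voiced]
        return float(np.max(np.abs(v))) if v.size else float("nan")

    def dominant_modulation_hz(self) -> float:
        """Frequency of the strongest oscillation in the contour.

        Computes the periodogram of the mean-removed voiced contour (gaps
        linearly interpolated) on a zero-padded FFT grid and returns the
        parabolic-interpolated peak frequency. Used to verify vibrato rates.
        """
        v = self.voiced
        if v.sum() < 8:
            raise ValueError("too few voiced frames for spectral analysis")
        t, x = self.times[v], self.offset_cents[v]
        dt = float(np.median(np.diff(t)))
        grid = np.arange(t[0], t[-1] + dt / 2, dt)
        xg = np.interp(grid, t, x)
        xg = xg - xg.mean()
        n_fft = int(2 ** np.ceil(np.log2(xg.size * 16)))
        spec = np.abs(np.fft.rfft(xg * np.hanning(xg.size), n_fft))
        freqs = np.fft.rfftfreq(n_fft, dt)
        k = int(np.argmax(spec[1:])) + 1
        if 1 <= k < spec.size - 1:  # parabolic refinement
            a, b, c = spec[k - 1], spec[k], spec[k + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
            return float(freqs[k] + shift * (freqs[1] - freqs[0]))
        return float(freqs[k])


def _interp_peak(ac: np.ndarray, k: int) -> float:
    """Parabolic sub-sample refinement of the autocorrelation peak lag."""
    if not 1 <= k < ac.size - 1:
        return float(k)
    a, b, c = ac[k - 1], ac[k], ac[k + 1]
    denom = a - 2 * b + c
    delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    return k + float(np.clip(delta, -1, 1))


def _frame_f0(frame: np.ndarray, sample_rate: int, lag_min: int, lag_max: int,
              voicing_threshold: float) -> float:
    """Window-corrected autocorrelation F0 for one frame; NaN when unvoiced.

    The frame is Hann-windowed and its autocorrelation divided by the
    window's own autocorrelation, which cancels both the linear lag taper
    and the phase-dependent edge terms that bias the plain estimate by
    several cents on short frames.
    """
    frame = frame - frame.mean()
    if float(np.dot(frame, frame)) < 1e-10:
        return np.nan
    n = frame.size
    if lag_min < 1 or lag_max <= lag_min or lag_max > n - 2:
        return np.nan
    win = np.hanning(n)
    n_fft = int(2 ** np.ceil(np.log2(n + lag_max + 2)))
    ac_x = np.fft.irfft(np.abs(np.fft.rfft(frame * win, n_fft)) ** 2, n_fft)
    ac_w = np.fft.irfft(np.abs(np.fft.rfft(win, n_fft)) ** 2, n_fft)
    r = ac_x[: lag_max + 2] / ac_w[: lag_max + 2].clip(min=1e-12)
    r = r / r[0]
    band = r[lag_min : lag_max + 1]
    vmax = float(np.max(band))
    if vmax < voicing_threshold:
        return np.nan
    # prefer the shortest near-maximal local maximum: the correlation is
    # ~equal at the period and its multiples, and the smallest such lag is
    # the true period (guards against octave-down errors)
    interior = band[1:-1]
    is_peak = (interior >= band[:-2]) & (interior >= band[2:])
    candidates = np.flatnonzero(is_peak & (interior >= 0.9 * vmax)) + 1 + lag_min
    k = int(candidates[0]) if candidates.size else int(np.argmax(band)) + lag_min
    if r[k] < voicing_threshold:
        return np.nan
    return sample_rate / _interp_peak(r, k)


def estimate_f0(
    w: Waveform,
    fmin: float = 75.0,
    fmax: float = 500.0,
    frame_step_s: float = 0.01,
    window_s: float | None = None,
    voicing_threshold: float = 0.6,
    silence_rms: float = 1e-4,
) -> F0Contour:
    """Track the fundamental frequency of a waveform.

    Parameters
    ----------
    fmin, fmax
        F0 search band in Hz; must satisfy ``fmin < fmax < sample_rate/2``.
    frame_step_s
        Hop between frame centers (default 10 ms).
    window_s
        Analysis window length; defaults to ``3 / fmin`` so at least three
        periods of the lowest trackable F0 fit in each frame. Shorter
        windows (via a higher ``fmin``) track fast modulations such as
        vibrato with less temporal smearing.
    voicing_threshold
        Minimum normalized autocorrelation peak for a frame to count as
        voiced (default 0.6).
    silence_rms
        Frames below this RMS are unvoiced regardless of periodicity.
    """
    if not (0 < fmin < fmax < w.sample_rate / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    sr = w.sample_rate
    if window_s is None:
        window_s = 3.0 / fmin
    win = max(int(round(window_s * sr)), 16)
    hop = max(int(round(frame_step_s * sr)), 1)
    x = w.samples
    if x.size < win:
        raise ValueError("signal shorter than one analysis window")
    lag_min = max(int(np.floor(sr / fmax)), 1)
    lag_max = min(int(np.ceil(sr / fmin)), win - 1)

    starts = np.arange(0, x.size - win + 1, hop)
    times = (starts + win / 2) / sr
    f0 = np.empty(starts.size)
    for i, s in enumerate(starts):
        frame = x[s : s + win]
        if np.sqrt(np.mean(frame**2)) < silence_rms:
            f0[i] = np.nan
            continue
        est = _frame_f0(frame, sr, lag_min, lag_max, voicing_threshold)
        f0[i] = est if (np.isnan(est) or fmin <= est <= fmax) else np.nan
    return F0Contour(times, f0, frame_step_s)


def measure_offset(original: F0Contour, transformed: F0Contour) -> PitchCurve:
    """Per-frame cents difference between two F0 contours.

    The transformed contour is linearly interpolated onto the original's
    frame grid over voiced regions; frames unvoiced in either contour are
    NaN in the result. Raises if the contours share no voiced frames.
    """
    t = original.times
    offs = np.full(t.size, np.nan)
    v2 = transformed.voiced
    if not v2.any() or not original.voiced.any():
        raise ValueError("no voiced frames to compare")
    f2 = np.interp(t, transformed.times[v2], transformed.f0_hz[v2],
                   left=np.nan, right=np.nan)
    # mark frames outside the transformed voiced support as unvoiced
    in_support = (t >= transformed.times[v2][0]) & (t <= transformed.times[v2][-1])
    joint = original.voiced & in_support & np.isfinite(f2)
    if not joint.any():
        raise ValueError("no jointly voiced frames to compare")
    offs[joint] = 1200.0 * np.log2(f2[joint] / original.f0_hz[joint])
    return PitchCurve(t.copy(), offs, DEFAULT_REFERENCE_HZ)


def contour_to_csv(contour: F0Contour, path, reference: float = DEFAULT_REFERENCE_HZ) -> None:
    """Export a contour as CSV with columns time_s, f0_hz, offset_cents."""
    import pandas as pd

    cents = contour.to_cents(reference).offset_cents
    pd.DataFrame(
        {"time_s": contour.times, "f0_hz": contour.f0_hz, "offset_cents": cents}
    ).to_csv(path, index=False)


def plot_contours(contours: dict, path=None, reference: float = DEFAULT_REFERENCE_HZ):
    """Plot one or more labelled F0 contours on a cents axis re ``reference``.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    for label, contour in contours.items():
        curve = contour.to_cents(reference)
        ax.plot(curve.times, curve.offset_cents, label=label, lw=1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"pitch (cents re {reference:g} Hz)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
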