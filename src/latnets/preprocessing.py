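"""Trial screening, artifact rejection, decimation, line-noise removal and
local stationarization.

Screening classifies each trial as C+ (eye position within the screen area
strictly more than 80% of the time during the first 0.5 s of the Context
period) or C−.  Artifact rejection flags trials whose band-averaged log
spectral power is a robust-z outlier across trials.  Stationarization is the
three-step recipe required by windowed VAR fitting: per-trial linear
detrend, per-trial z-scoring, then pointwise ensemble normalization across
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import TrialRecording

__all__ = [
    "ScreeningReport",
    "screen_condition",
    "reject_artifact_trials",
    "decimate",
    "remove_line_noise",
    "stationarize",
    "ARTIFACT_BANDS",
]

#: Band set (Hz) for spectral artifact screening.
ARTIFACT_BANDS = ((1, 4), (4, 8), (8, 30), (30, 80), (80, 120))


@dataclass
class ScreeningReport:
    """Gaze-screening outcome: per-trial condition and on-screen fraction."""

    condition: list[str]
    on_screen_fraction: np.ndarray
    threshold: float
    window: tuple[float, float]

    def counts(self) -> dict[str, int]:
        return {
            "Cplus": sum(c == "Cplus" for c in self.condition),
            "Cminus": sum(c == "Cminus" for c in self.condition),
        }


def screen_condition(
    rec: TrialRecording,
    threshold: float = 0.8,
    window: tuple[float, float] | None = None,
    screen_halfwidth_deg: float = 20.0,
) -> ScreeningReport:
    """Classify each trial C+/C− from gaze.

    C+ iff the on-screen fraction within the screening window is strictly
    greater than ``threshold``.  NaN gaze samples (eyes closed) and samples
    outside ±screen_halfwidth_deg count as off-screen.
    """
    if rec.gaze is None:
        raise ValueError(f"recording {rec.subject} has no gaze traces")
    if window is None:
        t0 = rec.timeline.context_start
        window = (t0, t0 + 0.5)
    i0 = int(round(window[0] * rec.gaze_fs))
    i1 = int(round(window[1] * rec.gaze_fs))
    if not (0 <= i0 < i1 <= rec.gaze.shape[1]):
        raise ValueError("screening window outside gaze trace")
    seg = rec.gaze[:, i0:i1, :]
    with np.errstate(invalid="ignore"):
        on = np.all(np.abs(seg) <= screen_halfwidth_deg, axis=2) & np.all(
            np.isfinite(seg), axis=2
        )
    frac = on.mean(axis=1)
    cond = ["Cplus" if f > threshold else "Cminus" for f in frac]
    return ScreeningReport(
        condition=cond, on_screen_fraction=frac, threshold=threshold, window=window
    )


def apply_screening(rec: TrialRecording, report: ScreeningReport) -> TrialRecording:
    """Return a copy of the recording with conditions written into labels."""
    out = rec.with_data(rec.data)
    out.labels = [
        lab.with_condition(c) for lab, c in zip(rec.labels, report.condition)
    ]
    return out


def _band_log_power(data: np.ndarray, fs: float) -> np.ndarray:
    """Per (trial, channel, band) mean log10 Welch power."""
    nper = min(data.shape[2], int(fs))
    freqs, psd = signal.welch(data, fs=fs, nperseg=nper, axis=2)
    out = np.empty(data.shape[:2] + (len(ARTIFACT_BANDS),))
    for b, (lo, hi) in enumerate(ARTIFACT_BANDS):
        m = (freqs >= lo) & (freqs < min(hi, fs / 2))
        if not m.any():  # degenerate band at low fs: nearest bin
            m = np.zeros_like(m)
            m[np.argmin(np.abs(freqs - min(lo, fs / 2)))] = True
        out[:, :, b] = np.log10(psd[:, :, m].mean(axis=2) + 1e-300)
    return out


def _robust_z(x: np.ndarray, axis: int = 0) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    mad = np.median(np.abs(x - med), axis=axis, keepdims=True)
    scale = 1.4826 * mad
    scale = np.where(scale < 1e-12, 1e-12, scale)
    return (x - med) / scale


def reject_artifact_trials(
    rec: TrialRecording, z_threshold: float = 4.0
) -> tuple[np.ndarray, dict]:
    """Flag trials whose band-averaged log power is an outlier.

    A trial is removed if any channel's log band power lies more than
    ``z_threshold`` robust z-units above the cross-trial median in any of
    the fixed screening bands.  Returns (kept indices, report).
    """
    if rec.n_trials < 10:
        raise ValueError("artifact rejection requires at least 10 trials")
    blp = _band_log_power(rec.data, rec.fs)
    z = _robust_z(blp, axis=0)
    bad = np.any(z > z_threshold, axis=(1, 2))
    kept = np.flatnonzero(~bad)
    if kept.size == 0:
        raise ValueError("all trials rejected; z_threshold too low")
    reasons = {}
    for i in np.flatnonzero(bad):
        ch, b = np.unravel_index(np.argmax(z[i]), z[i].shape)
        reasons[int(i)] = (
            f"channel {ch} band {ARTIFACT_BANDS[b]} Hz z={z[i, ch, b]:.1f}"
        )
    report = {"rejected": reasons, "n_kept": int(kept.size), "z_threshold": z_threshold}
    return kept, report


def decimate(rec: TrialRecording, factor: int = 4) -> TrialRecording:
    """Anti-aliased downsampling by an integer factor (zero-phase IIR)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return rec.with_data(rec.data.copy())
    if rec.n_samples // factor < 2:
        raise ValueError("too few samples for this decimation factor")
    out = signal.decimate(rec.data, factor, axis=2, zero_phase=True)
    return rec.with_data(out, fs=rec.fs / factor)


def remove_line_noise(
    rec: TrialRecording, line_hz: float = 50.0, q: float = 35.0
) -> TrialRecording:
    """Zero-phase IIR notch at the power-line frequency."""
    if line_hz >= rec.fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    b, a = signal.iirnotch(line_hz, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=2)
    return rec.with_data(out)


def stationarize(rec: TrialRecording, eps: float = 1e-12) -> TrialRecording:
    """Three-step local stationarization.

    (1) per trial/channel: subtract the best-fitting line; (2) per
    trial/channel: z-score over the trial; (3) per (channel, time point):
    subtract the ensemble mean and divide by the ensemble SD across trials.
    """
    if rec.n_trials < 2:
        raise ValueError("ensemble normalization needs at least 2 trials")
    x = signal.detrend(rec.data, axis=2, type="linear")
    sd = x.std(axis=2, keepdims=True)
    flat = np.argwhere(sd[:, :, 0] < eps)
    if flat.size:
        t, c = flat[0]
        raise ValueError(f"zero variance after detrend: trial {t}, channel {c}")
    x = (x - x.mean(axis=2, keepdims=True)) / sd
    mu = x.mean(axis=0, keepdims=True)
    sde = x.std(axis=0, keepdims=True)
    flat = np.argwhere(sde[0] < eps)
    if flat.size:
        c, t = flat[0]
        raise ValueError(f"zero ensemble SD at channel {c}, time point {t}")
    x = (x - mu) / sde
    return rec.with_data(x)
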