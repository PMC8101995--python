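"""Force statistics and spectral analysis of steady-state force traces.

Six parameters summarise a force trace over the 2000-4000 ms steady state:
mean, maximum, min-max range, RMS of the deviation about the mean, the
percentage of variance accounted for (VAF) against the non-synchronized
reference trace, and the mean spectral frequency of the PSD.  The PSD is
computed after mean subtraction with a rectangular window, zero-padded
from the 2000-sample record to 2048 FFT points (0.49 Hz resolution); the
DC bin is excluded, so the spectrum and its mean frequency describe the
oscillatory component of the force, not its static level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .firing import STEADY_STATE

NFFT = 2048
FS_HZ = 1000.0


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude-squared spectrum, DC excluded."""

    freqs_hz: np.ndarray
    psd: np.ndarray


def _window_samples(trace: np.ndarray,
                    window: tuple[int, int] = STEADY_STATE) -> np.ndarray:
    lo, hi = window
    if lo < 0 or hi > len(trace) or hi <= lo:
        raise ValueError(f"window {window} outside trace of {len(trace)} samples")
    return np.asarray(trace[lo:hi], dtype=float)


def force_stats(trace: np.ndarray,
                window: tuple[int, int] = STEADY_STATE) -> dict[str, float]:
    """meanF, maxF, rangeF and rmsF of a trace over the window.

    rmsF is the root-mean-square about the mean, i.e. the (population)
    standard deviation of the force oscillation.
    """
    x = _window_samples(trace, window)
    mean = float(x.mean())
    return {
        "meanF": mean,
        "maxF": float(x.max()),
        "rangeF": float(x.max() - x.min()),
        "rmsF": float(np.sqrt(np.mean((x - mean) ** 2))),
    }


def vaf(fs_trace: np.ndarray, fns_trace: np.ndarray,
        window: tuple[int, int] = STEADY_STATE) -> float | None:
    """Percentage of variance accounted for between two traces.

    ``100 * (1 - var(FS - FNS) / var(FNS))`` with variances about their own
    means over the window.  100% for identical traces; negative when the
    difference fluctuates more than the reference.  ``None`` when the
    reference has zero variance.
    """
    a = _window_samples(fs_trace, window)
    b = _window_samples(fns_trace, window)
    vref = float(np.var(b))
    if vref == 0.0:
        return None
    return 100.0 * (1.0 - float(np.var(a - b)) / vref)


def psd(trace: np.ndarray,
        window: tuple[int, int] = STEADY_STATE) -> Spectrum:
    """FFT power spectrum of the mean-subtracted, zero-padded window."""
    x = _window_samples(trace, window)
    x = x - x.mean()
    spec = np.fft.rfft(x, NFFT)
    freqs = np.fft.rfftfreq(NFFT, d=1.0 / FS_HZ)
    power = np.abs(spec) ** 2
    return Spectrum(freqs_hz=freqs[1:], psd=power[1:])  # drop DC


def mean_freq(spec: Spectrum) -> float | None:
    """PSD-weighted mean frequency in Hz; ``None`` for an all-zero spectrum."""
    total = float(spec.psd.sum())
    if total == 0.0:
        return None
    return float((spec.freqs_hz * spec.psd).sum() / total)


def trend_correlation(cisi_curve: np.ndarray,
                      param_curves: dict[str, np.ndarray]
                      ) -> dict[str, float | None]:
    """Pearson correlation of each force-parameter trend with the CISI trend.

    The curves hold one value per synchronization window level (the
    non-synchronized baseline followed by increasing window widths).
    ``None`` marks a constant curve, for which the correlation is undefined.
    """
    c = np.asarray(cisi_curve, dtype=float)
    out: dict[str, float | None] = {}
    for name, curve in param_curves.items():
        p = np.asarray(curve, dtype=float)
        if p.shape != c.shape:
            raise ValueError(f"{name}: curve length mismatch")
        if np.std(p) == 0.0 or np.std(c) == 0.0:
            out[name] = None
        else:
            out[name] = float(np.corrcoef(c, p)[0, 1])
    return out
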