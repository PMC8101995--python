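"""Excitation drive, recruitment thresholds and the rate law.

The common drive is a trapezoid-like signal in percent of maximal
excitation: a smooth logarithmic rise (1 s), a flat plateau at 100%
(2 s, the analysed steady state) and a time-mirrored logarithmic fall
(1 s).  Motor units are recruited by the size principle as the drive
crosses per-unit thresholds; the instantaneous firing rate grows linearly
from ``minfr`` at threshold to ``meanfr`` at full drive, so that during
the steady state every unit fires around its mean rhythmic rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pool import MotorUnit, MUPool


@dataclass(frozen=True)
class ExcitationTrace:
    """Excitation drive sampled at 1 kHz, in percent of maximal drive."""

    values: np.ndarray  # shape (duration_ms,)

    @property
    def duration_ms(self) -> int:
        return len(self.values)

    def drive_at(self, t_ms: float) -> float:
        """Drive at time ``t_ms`` (nearest-sample lookup, 0 outside)."""
        i = int(round(t_ms))
        if i < 0 or i >= len(self.values):
            return 0.0
        return float(self.values[i])


@dataclass(frozen=True)
class RecruitmentPlan:
    """Recruitment order and per-unit drive thresholds (percent)."""

    order: tuple[int, ...]          # MU indices, first recruited first
    thresholds: dict[int, float]    # MU index -> threshold in percent

    def threshold_of(self, mu_index: int) -> float:
        return self.thresholds[mu_index]


def excitation_signal(level: float = 100.0, rise_ms: int = 1000,
                      plateau_ms: int = 2000, fall_ms: int = 1000,
                      shape: float = 9.0) -> ExcitationTrace:
    """Build the excitation drive: log rise, flat plateau, mirrored log fall.

    The rising part is ``level * log(1 + shape*t/rise) / log(1 + shape)``;
    the falling part is its time mirror.  ``shape`` controls the curvature
    of the ramps (larger = steeper early rise); only the plateau is analysed,
    so ramp shape does not affect any steady-state statistic.
    """
    if level <= 0 or level > 100:
        raise ValueError("level must be in (0, 100]")
    if rise_ms <= 0 or plateau_ms <= 0 or fall_ms <= 0:
        raise ValueError("durations must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    total = rise_ms + plateau_ms + fall_ms
    t = np.arange(total, dtype=float)
    v = np.full(total, float(level))
    rising = t < rise_ms
    v[rising] = level * np.log1p(shape * t[rising] / rise_ms) / np.log1p(shape)
    falling = t > rise_ms + plateau_ms
    trem = total - t[falling]
    v[falling] = level * np.log1p(shape * trem / fall_ms) / np.log1p(shape)
    return ExcitationTrace(values=v)


def recruitment_plan(pool: MUPool, span: float = 90.0) -> RecruitmentPlan:
    """Evenly spaced recruitment thresholds over ``(0, span]`` percent.

    The recruitment order is the pool's own ordering — type blocks S, FR,
    FF, each sorted by increasing peak twitch force — so for the packaged
    pool the order is simply MU 1..57.  Thresholds are ``span * k / N`` for
    the k-th recruited of N units; with the default span of 90% every unit
    is recruited well before the drive reaches its plateau.
    """
    if not 0 < span < 100:
        raise ValueError("span must be in (0, 100)")
    order = tuple(
        u.index
        for t in ("S", "FR", "FF")
        for u in sorted(pool.by_type(t), key=lambda u: (u.Fmax, u.index))
    )
    n = len(order)
    thresholds = {idx: span * (k + 1) / n for k, idx in enumerate(order)}
    return RecruitmentPlan(order=order, thresholds=thresholds)


def instantaneous_rate(mu: MotorUnit, drive: float, threshold: float) -> float:
    """Firing rate (Hz) of ``mu`` at the given drive level.

    Zero below threshold; ``minfr`` at threshold; linear in drive up to
    ``meanfr`` at 100% drive.  At full drive the steady-state rate is thus
    exactly the unit's mean rhythmic rate.
    """
    if drive < threshold:
        return 0.0
    if threshold >= 100.0:
        return mu.minfr
    frac = (drive - threshold) / (100.0 - threshold)
    return mu.minfr + (mu.meanfr - mu.minfr) * min(frac, 1.0)
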