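"""Stochastic spike-train generation and binary representations.

Each motor unit fires as a renewal process: successive interpulse
intervals (IPIs) are drawn uniformly within +/- ``jitter`` ms (default 4)
around the IPI corresponding to the unit's instantaneous rate.  Pulse
times accumulate in continuous time and are then rounded to the 1-ms
sampling grid (fs = 1 kHz).  The analysis window is the 2000-4000 ms
steady state, over which a train is also representable as a 2000-sample
binary series (1 = pulse-active for one sampling period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .excitation import ExcitationTrace, RecruitmentPlan, instantaneous_rate
from .pool import MotorUnit, MUPool

#: steady-state analysis window, half-open, ms
STEADY_STATE = (2000, 4000)


@dataclass(frozen=True)
class SpikeTrain:
    """Pulse times of one MU: strictly increasing integers on the ms grid."""

    mu_index: int
    times: np.ndarray  # int64, strictly increasing, in [0, duration)
    duration_ms: int = 4000

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.int64)
        object.__setattr__(self, "times", t)
        if len(t) and (np.diff(t) < 1).any():
            raise ValueError(f"MU {self.mu_index}: pulse times not strictly increasing")
        if len(t) and (t[0] < 0 or t[-1] >= self.duration_ms):
            raise ValueError(f"MU {self.mu_index}: pulse times outside [0, {self.duration_ms})")

    def in_window(self, window: tuple[int, int] = STEADY_STATE) -> np.ndarray:
        lo, hi = window
        return self.times[(self.times >= lo) & (self.times < hi)]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FiringSet:
    """One SpikeTrain per MU, plus provenance (seed and scenario tag)."""

    trains: dict[int, SpikeTrain]
    seed: int | None = None
    tag: str = "NS"
    duration_ms: int = 4000

    def __getitem__(self, mu_index: int) -> SpikeTrain:
        return self.trains[mu_index]

    def __iter__(self):
        return iter(self.trains.values())

    def __len__(self) -> int:
        return len(self.trains)

    def replace(self, train: SpikeTrain) -> None:
        self.trains[train.mu_index] = train

    def copy(self, tag: str | None = None) -> "FiringSet":
        return FiringSet(trains=dict(self.trains), seed=self.seed,
                         tag=self.tag if tag is None else tag,
                         duration_ms=self.duration_ms)


def generate_train(mu: MotorUnit, excitation: ExcitationTrace,
                   threshold: float, rng: np.random.Generator,
                   jitter: float = 4.0, duration_ms: int = 4000) -> SpikeTrain:
    """Generate one stochastic (non-synchronized) spike train.

    The first pulse is placed at the first supra-threshold sample plus a
    uniform phase within one IPI (decorrelating units at recruitment); each
    later pulse follows after an IPI drawn uniformly from
    ``[1000/rate - jitter, 1000/rate + jitter]``, where ``rate`` is the
    unit's instantaneous rate at the previous pulse time.  Continuous times
    are rounded to the 1-ms grid at the end; a rounding collision pushes the
    later pulse 1 ms forward so the pulse count is preserved.
    """
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    if 1000.0 / mu.meanfr - jitter <= 1.0:
        raise ValueError(
            f"MU {mu.label}: jitter {jitter} too large for mean IPI "
            f"{1000.0 / mu.meanfr:.1f} ms"
        )
    drive = excitation.values
    supra = np.nonzero(drive >= threshold)[0]
    if len(supra) == 0:
        return SpikeTrain(mu.index, np.empty(0, dtype=np.int64), duration_ms)
    onset = int(supra[0])
    rate = instantaneous_rate(mu, float(drive[onset]), threshold)
    if rate <= 0:
        return SpikeTrain(mu.index, np.empty(0, dtype=np.int64), duration_ms)
    times: list[float] = []
    t = onset + rng.uniform(0.0, 1000.0 / rate)
    while t < duration_ms:
        times.append(t)
        rate = instantaneous_rate(mu, excitation.drive_at(t), threshold)
        if rate <= 0:
            break
        ipi = 1000.0 / rate
        t += rng.uniform(ipi - jitter, ipi + jitter)
    grid = np.rint(np.asarray(times)).astype(np.int64)
    for k in range(1, len(grid)):  # resolve rounding collisions
        if grid[k] <= grid[k - 1]:
            grid[k] = grid[k - 1] + 1
    grid = grid[grid < duration_ms]
    return SpikeTrain(mu.index, grid, duration_ms)


def generate_pool_firings(pool: MUPool, excitation: ExcitationTrace,
                          plan: RecruitmentPlan, seed: int,
                          jitter: float = 4.0,
                          duration_ms: int = 4000) -> FiringSet:
    """Generate independent NS trains for every MU in the pool.

    Each unit draws from its own substream keyed by ``(seed, mu index)``,
    so the same seed reproduces the set bit-for-bit and adding or removing
    units does not perturb the remaining trains.
    """
    trains = {}
    for u in pool:
        rng = np.random.default_rng([seed, u.index])
        trains[u.index] = generate_train(
            u, excitation, plan.threshold_of(u.index), rng,
            jitter=jitter, duration_ms=duration_ms,
        )
    return FiringSet(trains=trains, seed=seed, tag="NS",
                     duration_ms=duration_ms)


def binarize(train: SpikeTrain,
             window: tuple[int, int] = STEADY_STATE) -> np.ndarray:
    """Binary sample series of a train over the window (1-ms resolution)."""
    lo, hi = window
    series = np.zeros(hi - lo, dtype=np.int8)
    series[train.in_window(window) - lo] = 1
    return series


def ipi_histogram(train: SpikeTrain,
                  window: tuple[int, int] = STEADY_STATE
                  ) -> pd.Series | None:
    """Normalized IPI histogram (1-ms bins) of a train within the window.

    Returns ``None`` when the window holds fewer than two pulses.
    """
    t = train.in_window(window)
    if len(t) < 2:
        return None
    ipis = np.diff(t)
    counts = pd.Series(ipis).value_counts().sort_index()
    return counts / counts.sum()


# --- tabular interchange (per-pulse rows, the layout of the published
# --- supplementary firing tables) ------------------------------------------

def write_firings(firings: FiringSet, path: str | Path,
                  pool: MUPool | None = None) -> None:
    """Export a FiringSet as CSV rows (mu_index, label, pulse_time_ms)."""
    rows = []
    for train in firings:
        label = pool[train.mu_index].label if pool is not None else ""
        for t in train.times:
            rows.append((train.mu_index, label, int(t)))
    pd.DataFrame(rows, columns=["mu_index", "label", "pulse_time_ms"]).to_csv(
        path, index=False)


def read_firings(path: str | Path, duration_ms: int = 4000,
                 tag: str = "external") -> FiringSet:
    """Read a per-pulse CSV (columns mu_index, pulse_time_ms) as a FiringSet."""
    df = pd.read_csv(path)
    trains = {}
    for idx, grp in df.groupby("mu_index"):
        t = np.sort(grp["pulse_time_ms"].to_numpy(dtype=np.int64))
        trains[int(idx)] = SpikeTrain(int(idx), t, duration_ms)
    return FiringSet(trains=trains, seed=None, tag=tag,
                     duration_ms=duration_ms)
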