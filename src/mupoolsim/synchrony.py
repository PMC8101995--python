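"""Imposed short-term synchronization of spike trains.

Synchronization between a reference unit (MU1) and a target unit (MU2) is
simulated by moving every MU2 pulse that falls within a time window of
+/- ``delta_t`` ms around an MU1 pulse so that it coincides with that MU1
pulse.  Windows of 2, 4 and 6 ms emulate weak, modest and strong
short-term synchrony.  Four pair-selection schemes choose which same-type
unit pairs are synchronized:

* Method 1 — chained neighbours in recruitment (twitch-force) order;
* Method 2 — chained neighbours in mean-firing-rate order;
* Method 3 — unique groups of four, each synchronized to its first unit;
* Method 4 — every unit of a type synchronized to the type's first
  recruited unit.

In the chained methods the already-synchronized pattern of the previous
target serves as the reference for the next pair.  Synchronization is
never induced across types, and pulses are moved, never created or
deleted; moves that would carry a pulse across a boundary of the analysed
steady state are skipped so pulse counts per window are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .firing import STEADY_STATE, FiringSet, SpikeTrain
from .pool import MUPool

SYNC_WINDOWS_MS = (2, 4, 6)


@dataclass(frozen=True)
class SyncSchedule:
    """Ordered (reference, target) pairs for one synchronization method."""

    method: int
    pairs: tuple[tuple[int, int], ...]
    chained: bool

    def __post_init__(self) -> None:
        for ref, tgt in self.pairs:
            if ref == tgt:
                raise ValueError(f"self-pair ({ref}, {tgt}) in schedule")


def sync_pair(reference: SpikeTrain, target: SpikeTrain, delta_t: int,
              protect: tuple[int, int] = STEADY_STATE
              ) -> tuple[SpikeTrain, int]:
    """Shift target pulses onto nearby reference pulses.

    Each target pulse is assigned to its nearest reference pulse (ties go
    to the earlier reference pulse).  A pulse moves when its offset is at
    most ``delta_t`` ms, subject to two rules: at most one target pulse may
    move to any given reference pulse (the nearest claimant wins; on equal
    distance the earlier target), and a move may not carry a pulse across a
    boundary of the ``protect`` window in either direction.  Returns the
    shifted train and the number of pulses actually moved.
    """
    if delta_t < 1:
        raise ValueError("delta_t must be >= 1 ms")
    ref = reference.times
    tgt = target.times.copy()
    if len(ref) == 0 or len(tgt) == 0:
        return target, 0
    # nearest reference pulse for each target pulse (tie -> earlier ref)
    pos = np.searchsorted(ref, tgt)
    left = np.clip(pos - 1, 0, len(ref) - 1)
    right = np.clip(pos, 0, len(ref) - 1)
    d_left = np.abs(tgt - ref[left])
    d_right = np.abs(tgt - ref[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)

    lo, hi = protect
    in_protect = lambda t: (t >= lo) & (t < hi)
    eligible = (dist <= delta_t) & (in_protect(tgt) == in_protect(ref[nearest]))

    # one winner per reference pulse: nearest claimant, earlier target on ties
    claimed: dict[int, int] = {}
    for k in np.nonzero(eligible)[0]:
        r = int(nearest[k])
        if r not in claimed or dist[k] < dist[claimed[r]]:
            claimed[r] = int(k)

    n_shifted = 0
    for r, k in claimed.items():
        if tgt[k] != ref[r]:
            tgt[k] = ref[r]
            n_shifted += 1
    tgt.sort()
    if (np.diff(tgt) < 1).any():
        raise AssertionError("duplicate pulse time after shifting")
    shifted = SpikeTrain(target.mu_index, tgt, target.duration_ms)
    if len(shifted) != len(target):
        raise AssertionError("pulse count changed by shifting")
    return shifted, n_shifted


# verbatim chained pair sequences of Method 2 (mean-firing-rate order)
_METHOD2_CHAINS = {
    "S": [7, 1, 6, 5, 4, 2, 3, 8],
    "FR": [18, 16, 24, 22, 28, 14, 12, 23, 13, 20, 31, 27, 29, 25, 9, 21,
           30, 26, 19, 17, 11, 10, 15],
    "FF": [50, 44, 43, 49, 39, 54, 52, 55, 56, 48, 47, 53, 51, 37, 40, 41,
           57, 45, 35, 33, 46, 32, 34, 38, 36, 42],
}


def schedule_for_method(method: int, pool: MUPool) -> SyncSchedule:
    """Build the (reference, target) pair sequence for Methods 1-4.

    The pair lists are defined for the packaged 57-unit pool and its
    indexing (S = 1-8, FR = 9-31, FF = 32-57).
    """
    if method not in (1, 2, 3, 4):
        raise ValueError(f"method must be 1-4, got {method}")
    blocks = {t: pool.indices_of_type(t) for t in ("S", "FR", "FF")}
    pairs: list[tuple[int, int]] = []
    if method == 1:
        # chained neighbours in recruitment order: 1-2, 2'-3, ...
        for idx in blocks.values():
            pairs.extend(zip(idx, idx[1:]))
        chained = True
    elif method == 2:
        for chain in _METHOD2_CHAINS.values():
            pairs.extend(zip(chain, chain[1:]))
        chained = True
    elif method == 3:
        # unique groups of four, each synchronized to its first unit; the
        # trailing short groups absorb the remainder of each type block
        for idx in blocks.values():
            for g in range(0, len(idx), 4):
                group = idx[g:g + 4]
                pairs.extend((group[0], m) for m in group[1:])
        chained = False
    else:  # method == 4
        for idx in blocks.values():
            pairs.extend((idx[0], m) for m in idx[1:])
        chained = False
    return SyncSchedule(method=method, pairs=tuple(pairs), chained=chained)


def apply_method(firings: FiringSet, schedule: SyncSchedule, delta_t: int,
                 protect: tuple[int, int] = STEADY_STATE
                 ) -> tuple[FiringSet, list[tuple[int, int, int]]]:
    """Apply a synchronization schedule to a FiringSet.

    Pairs are processed in schedule order against the current (possibly
    already modified) state, which realizes the chained reference rule; for
    the non-chained methods the references are never modified, so the order
    is immaterial.  Returns the synchronized set and a per-pair log of
    ``(reference, target, n_shifted)``.
    """
    out = firings.copy(tag=f"M{schedule.method}_dt{delta_t}")
    log: list[tuple[int, int, int]] = []
    for ref, tgt in schedule.pairs:
        if ref not in out.trains or tgt not in out.trains:
            raise KeyError(f"schedule references absent MU ({ref}, {tgt})")
        shifted, n = sync_pair(out[ref], out[tgt], delta_t, protect)
        out.replace(shifted)
        log.append((ref, tgt, n))
    return out, log
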