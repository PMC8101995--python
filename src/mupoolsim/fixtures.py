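"""Hand-checkable fixtures and brute-force oracles for the test suite.

These helpers are deliberately naive (O(n^2) searches, explicit loops) so
they can serve as independent cross-checks of the vectorised metric
implementations, plus generators of small synthetic train pairs with known
analytic expectations.
"""

from __future__ import annotations

import numpy as np

from .firing import STEADY_STATE, SpikeTrain
from .syncmetrics import CrossIntervalSet


def make_renewal_pair(rate1: float, rate2: float, duration_ms: int,
                      seed: int, jitter: float = 4.0
                      ) -> tuple[SpikeTrain, SpikeTrain]:
    """Two independent uniform-jitter renewal trains on the 1-ms grid.

    For independent trains the probability that a reference pulse finds a
    partner pulse in the same 1-ms sample is approximately 1 ms divided by
    the partner's mean interpulse interval.
    """
    if rate1 <= 0 or rate2 <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)

    def one(rate: float, mu_index: int) -> SpikeTrain:
        ipi = 1000.0 / rate
        times = []
        t = rng.uniform(0.0, ipi)
        while t < duration_ms:
            times.append(t)
            t += rng.uniform(max(ipi - jitter, 1.0), ipi + jitter)
        grid = np.rint(times).astype(np.int64)
        for k in range(1, len(grid)):
            if grid[k] <= grid[k - 1]:
                grid[k] = grid[k - 1] + 1
        return SpikeTrain(mu_index, grid[grid < duration_ms],
                          duration_ms=max(duration_ms, 1))

    return one(rate1, 1), one(rate2, 2)


def brute_force_ci(reference: SpikeTrain, partner: SpikeTrain,
                   window: tuple[int, int] = STEADY_STATE
                   ) -> CrossIntervalSet:
    """Exhaustive nearest-neighbour cross intervals (oracle).

    Same tie rule as the production implementation: equidistant partner
    pulses resolve to the earlier one.
    """
    t1 = reference.in_window(window)
    t2 = partner.in_window(window)
    values = []
    for x in t1:
        best = None
        for y in t2:  # earlier pulses first; strict improvement keeps ties
            if best is None or abs(x - y) < abs(x - best):
                best = y
        if best is not None:
            values.append(int(x - best))
    return CrossIntervalSet(reference.mu_index, partner.mu_index,
                            np.asarray(values, dtype=np.int64))


def brute_force_coincidences(a: SpikeTrain, b: SpikeTrain,
                             window: tuple[int, int] = STEADY_STATE) -> int:
    """Count of shared pulse times within the window (oracle for corMU)."""
    return len(set(map(int, a.in_window(window)))
               & set(map(int, b.in_window(window))))


def brute_force_shift_count(reference: SpikeTrain, target: SpikeTrain,
                            delta_t: int,
                            protect: tuple[int, int] = STEADY_STATE) -> int:
    """Expected number of moved pulses under the pair-shifting rule (oracle).

    Explicit re-statement of the rule: nearest reference per target pulse
    (tie to the earlier reference), one winner per reference pulse (nearest
    claimant, earlier target on ties), no moves across a protect-window
    boundary, and pulses already on their reference do not count as moved.
    """
    ref = list(map(int, reference.times))
    tgt = list(map(int, target.times))
    lo, hi = protect
    inw = lambda t: lo <= t < hi
    assign: dict[int, tuple[int, int]] = {}  # ref time -> (dist, target time)
    for x in tgt:
        best = None
        for r in ref:
            if best is None or abs(x - r) < abs(x - best):
                best = r
        if best is None or abs(x - best) > delta_t or inw(x) != inw(best):
            continue
        d = abs(x - best)
        if best not in assign or d < assign[best][0]:
            assign[best] = (d, x)
    return sum(1 for r, (d, x) in assign.items() if x != r)
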