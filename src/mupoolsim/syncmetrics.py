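"""Synchronization indices: binary-series correlation and cross intervals.

Two complementary indices quantify short-term synchrony over the 2000-4000
ms steady state:

* ``corMU`` — the normalized correlation of two 1-ms binary firing series,
  ``100 * sum(a*b) / sqrt(sum(a^2) * sum(b^2))``.  For binary series this is
  the coincidence count normalized by the geometric mean of the pulse
  counts, so it does not depend on record length or firing rate.

* ``CISI`` — the cross-interval synchronization index.  For a reference
  unit, the cross interval to a partner is the signed time difference from
  each reference pulse to its nearest partner pulse; the central-bin
  probability (|CI| < 0.5 ms, i.e. CI = 0 on the integer grid) measures
  pairwise coincidence, and CISI averages it over all N-1 partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .firing import STEADY_STATE, FiringSet, SpikeTrain, binarize
from .pool import MU_TYPES, MUPool

#: histogram support for cross intervals, ms
CI_HIST_RANGE = 15


@dataclass(frozen=True)
class CrossIntervalSet:
    """Signed nearest-neighbour time differences, one per reference pulse."""

    reference: int
    partner: int
    values: np.ndarray  # int64 ms; empty when the partner has no pulses


@dataclass(frozen=True)
class SyncSummary:
    """Pairwise corMU matrix, per-MU CISI, and type-level aggregates."""

    indices: tuple[int, ...]            # MU indices, matrix row order
    cor_matrix: np.ndarray              # percent, symmetric, diagonal 100
    cisi_values: pd.Series              # percent, indexed by MU index
    aggregates: pd.DataFrame            # rows corMU/CISI x columns type


def cor_mu(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized binary-series correlation, in percent.

    Defined as 0 when either series has no pulses.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na = int((a * a).sum())
    nb = int((b * b).sum())
    if na == 0 or nb == 0:
        return 0.0
    return 100.0 * float((a * b).sum()) / np.sqrt(na * nb)


def cor_matrix(firings: FiringSet,
               window: tuple[int, int] = STEADY_STATE) -> np.ndarray:
    """Pairwise corMU matrix over all trains, ordered by MU index."""
    idx = sorted(firings.trains)
    B = np.stack([binarize(firings[i], window) for i in idx]).astype(float)
    counts = B.sum(axis=1)
    coinc = B @ B.T
    denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom > 0, 100.0 * coinc / denom, 0.0)
    return m


def cross_intervals(reference: SpikeTrain, partner: SpikeTrain,
                    window: tuple[int, int] = STEADY_STATE
                    ) -> CrossIntervalSet:
    """Nearest-neighbour cross intervals from reference to partner pulses.

    For each reference pulse ``t1`` in the window the interval is
    ``t1 - t2`` with ``t2`` the partner pulse in the window minimizing
    ``|t1 - t2|``; equidistant partner pulses resolve to the earlier one
    (yielding a positive interval).  Negative, zero and positive values mean
    the reference pulse precedes, coincides with, or follows its neighbour.
    """
    t1 = reference.in_window(window)
    t2 = partner.in_window(window)
    if len(t2) == 0 or len(t1) == 0:
        return CrossIntervalSet(reference.mu_index, partner.mu_index,
                                np.empty(0, dtype=np.int64))
    pos = np.searchsorted(t2, t1)
    left = np.clip(pos - 1, 0, len(t2) - 1)
    right = np.clip(pos, 0, len(t2) - 1)
    d_left = np.abs(t1 - t2[left])
    d_right = np.abs(t1 - t2[right])
    nearest = np.where(d_left <= d_right, t2[left], t2[right])
    return CrossIntervalSet(reference.mu_index, partner.mu_index, t1 - nearest)


def ci_histogram(ci: CrossIntervalSet) -> pd.Series:
    """Cross-interval histogram: 1-ms bins centred on -15..+15 ms.

    Bin values are counts divided by the number of reference pulses;
    intervals beyond +/-15 ms fall outside every bin, so the values sum to
    1 exactly when all intervals lie within the histogram range.
    """
    if len(ci.values) == 0:
        raise ValueError("empty cross-interval set")
    centers = np.arange(-CI_HIST_RANGE, CI_HIST_RANGE + 1)
    counts = np.array([(ci.values == c).sum() for c in centers], dtype=float)
    return pd.Series(counts / len(ci.values), index=centers)


def central_bin_prob(ci: CrossIntervalSet) -> float:
    """Probability of pulse coincidence: share of intervals in [-0.5, 0.5)."""
    if len(ci.values) == 0:
        raise ValueError("empty cross-interval set")
    return float((ci.values == 0).sum()) / len(ci.values)


def cisi(firings: FiringSet, mu_index: int,
         window: tuple[int, int] = STEADY_STATE) -> float:
    """Cross-interval synchronization index of one MU, in percent.

    Averages the central-bin coincidence probability over all N-1 partner
    units of the set.
    """
    ref = firings[mu_index]
    if len(ref.in_window(window)) == 0:
        raise ValueError(f"MU {mu_index} has no steady-state pulses")
    probs = []
    for j, partner in sorted(firings.trains.items()):
        if j == mu_index:
            continue
        ci = cross_intervals(ref, partner, window)
        probs.append(central_bin_prob(ci) if len(ci.values) else 0.0)
    return 100.0 * float(np.mean(probs))


def summarize_sync(firings: FiringSet, pool: MUPool,
                   window: tuple[int, int] = STEADY_STATE) -> SyncSummary:
    """Compute both indices and their type-level mean +/- SD aggregates.

    corMU aggregates average over unordered pairs — within-type pairs for
    the S/FR/FF columns and all pairs (cross-type included) for the "all"
    column; CISI aggregates average the per-MU values over each type's
    units.  SDs are sample standard deviations.
    """
    idx = sorted(firings.trains)
    m = cor_matrix(firings, window)
    pos = {mu: k for k, mu in enumerate(idx)}
    cisi_vals = pd.Series({i: cisi(firings, i, window) for i in idx})

    def pair_values(members: list[int]) -> np.ndarray:
        ks = [pos[i] for i in members]
        sub = m[np.ix_(ks, ks)]
        iu = np.triu_indices(len(ks), k=1)
        return sub[iu]

    rows = {}
    for t in MU_TYPES:
        members = [i for i in idx if pool[i].mu_type == t]
        pv = pair_values(members)
        cv = cisi_vals[members]
        rows[t] = {
            "corMU_mean": pv.mean(), "corMU_sd": pv.std(ddof=1),
            "CISI_mean": cv.mean(), "CISI_sd": cv.std(ddof=1),
        }
    pv = pair_values(idx)
    rows["all"] = {
        "corMU_mean": pv.mean(), "corMU_sd": pv.std(ddof=1),
        "CISI_mean": cisi_vals.mean(), "CISI_sd": cisi_vals.std(ddof=1),
    }
    agg = pd.DataFrame(rows).T
    return SyncSummary(indices=tuple(idx), cor_matrix=m,
                       cisi_values=cisi_vals, aggregates=agg)
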