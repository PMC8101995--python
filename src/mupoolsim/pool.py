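"""Motor-unit pool: contractile and firing parameters of the simulated muscle.

The packaged pool describes 57 motor units (MUs) of the rat medial
gastrocnemius — 8 slow (S), 23 fast fatigue-resistant (FR) and 26 fast
fatigable (FF) units — each characterised by its twitch time course
(contraction time ``Tc``, half-relaxation time ``Thr``, twitch duration
``Ttw``), its force scale (peak twitch force ``Fmax``, maximal fused-tetanus
force ``Fmftf``) and its rhythmic firing rates (``minfr``, ``meanfr``,
``maxfr``).  Units are numbered 1-57 in recruitment order: within each type
they are sorted by increasing peak twitch force (size principle).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

MU_TYPES = ("S", "FR", "FF")

#: column order of the tabular interchange format
POOL_COLUMNS = [
    "index", "label", "type", "Tc", "Thr", "Ttw",
    "Fmax", "Fmftf", "meanfr", "minfr", "maxfr",
]

_NUMERIC = ["Tc", "Thr", "Ttw", "Fmax", "Fmftf", "meanfr", "minfr", "maxfr"]

#: expected composition of the packaged pool
BUILTIN_COUNTS = {"S": 8, "FR": 23, "FF": 26}


class PoolLoadError(ValueError):
    """Raised when a motor-unit table cannot be parsed or validated."""


@dataclass(frozen=True)
class MotorUnit:
    """One motor unit: twitch, tetanus and firing-rate parameters.

    Times are in ms, forces in mN, rates in Hz.
    """

    index: int
    label: str
    mu_type: str
    Tc: float
    Thr: float
    Ttw: float
    Fmax: float
    Fmftf: float
    meanfr: float
    minfr: float
    maxfr: float

    def __post_init__(self) -> None:
        if self.mu_type not in MU_TYPES:
            raise PoolLoadError(
                f"unit {self.label!r}: unknown type {self.mu_type!r}"
            )


class MUPool:
    """Ordered collection of :class:`MotorUnit`, indexed by MU number."""

    def __init__(self, units: Iterable[MotorUnit], builtin: bool = False):
        self.units: list[MotorUnit] = list(units)
        self.builtin = builtin
        labels = [u.label for u in self.units]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise PoolLoadError(f"duplicate unit labels: {dup}")
        self._by_index = {u.index: u for u in self.units}
        if len(self._by_index) != len(self.units):
            raise PoolLoadError("duplicate unit indices")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[MotorUnit]:
        return iter(self.units)

    def __getitem__(self, index: int) -> MotorUnit:
        return self._by_index[index]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MUPool) and self.units == other.units

    @property
    def counts(self) -> dict[str, int]:
        c = {t: 0 for t in MU_TYPES}
        for u in self.units:
            c[u.mu_type] += 1
        return c

    def by_type(self, mu_type: str) -> list[MotorUnit]:
        return [u for u in self.units if u.mu_type == mu_type]

    def indices_of_type(self, mu_type: str) -> list[int]:
        return [u.index for u in self.units if u.mu_type == mu_type]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index": u.index, "label": u.label, "type": u.mu_type,
                "Tc": u.Tc, "Thr": u.Thr, "Ttw": u.Ttw, "Fmax": u.Fmax,
                "Fmftf": u.Fmftf, "meanfr": u.meanfr, "minfr": u.minfr,
                "maxfr": u.maxfr,
            }
            for u in self.units
        ]
        return pd.DataFrame(rows, columns=POOL_COLUMNS)


def _pool_from_frame(df: pd.DataFrame, builtin: bool = False) -> MUPool:
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise PoolLoadError(f"missing columns: {missing}")
    units = []
    for _, row in df.iterrows():
        try:
            vals = {c: float(row[c]) for c in _NUMERIC}
            idx = int(row["index"])
        except (TypeError, ValueError) as exc:
            raise PoolLoadError(
                f"non-numeric cell in row with label {row['label']!r}: {exc}"
            ) from exc
        units.append(
            MotorUnit(index=idx, label=str(row["label"]),
                      mu_type=str(row["type"]), **vals)
        )
    return MUPool(units, builtin=builtin)


def load_pool(source: str | Path = "builtin") -> MUPool:
    """Load a motor-unit pool from a CSV table or the packaged parameter set.

    Parameters
    ----------
    source:
        Path to a CSV file with columns :data:`POOL_COLUMNS`, or the token
        ``"builtin"`` for the packaged 57-unit rat medial gastrocnemius set.
    """
    if isinstance(source, str) and source == "builtin":
        ref = importlib.resources.files("mupoolsim.data") / "motor_units.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
        pool = _pool_from_frame(df, builtin=True)
        report = validate_pool(pool)
        if report:  # packaged data must be internally consistent
            raise PoolLoadError(f"packaged pool failed validation: {report}")
        return pool
    df = pd.read_csv(source)
    return _pool_from_frame(df)


def write_pool(pool: MUPool, path: str | Path) -> None:
    """Write a pool as a CSV table readable by :func:`load_pool`."""
    pool.to_frame().to_csv(path, index=False)


def validate_pool(pool: MUPool) -> list[str]:
    """Check pool invariants; return a human-readable violation list.

    An empty list means the pool is valid.  Checked per unit: positivity of
    all parameters, ``minfr < meanfr < maxfr``, ``Fmax < Fmftf`` and
    ``Ttw >= Tc``.  For pools flagged as builtin, additionally the exact
    57-unit composition and the within-type ordering by increasing ``Fmax``.
    """
    report: list[str] = []
    for u in pool:
        for name in _NUMERIC:
            if not getattr(u, name) > 0:
                report.append(f"{u.label}: {name} must be positive")
        if not (u.minfr < u.meanfr < u.maxfr):
            report.append(f"{u.label}: requires minfr < meanfr < maxfr")
        if not u.Fmax < u.Fmftf:
            report.append(f"{u.label}: requires Fmax < Fmftf")
        if not u.Ttw >= u.Tc:
            report.append(f"{u.label}: requires Ttw >= Tc")
    if pool.builtin:
        if len(pool) != 57:
            report.append(f"builtin pool must have 57 units, got {len(pool)}")
        counts = pool.counts
        for t, n in BUILTIN_COUNTS.items():
            if counts.get(t, 0) != n:
                report.append(
                    f"builtin pool must have {n} {t} units, got {counts.get(t, 0)}"
                )
        for t in MU_TYPES:
            block = pool.by_type(t)
            for a, b in zip(block, block[1:]):
                if b.Fmax < a.Fmax:
                    report.append(
                        f"{b.label}: Fmax not nondecreasing within type {t}"
                    )
    return report
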