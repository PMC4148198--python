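"""Binary mossy-fiber stimulus patterns and their spike-train realizations.

Each stimulus pattern designates an exact fraction of the MF inputs as
active: round(p_mf * n_mf) fibers chosen uniformly (independent patterns) or
as spatial clusters of neighboring rosettes (correlated patterns). During a
simulated trial each active MF fires a homogeneous Poisson train at 80 Hz
and each inactive MF at 10 Hz, the rate regime observed for sustained
rate-coded MF input in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StimulusSet",
    "SpikeTrainSet",
    "make_patterns",
    "make_correlated_patterns",
    "poissonize",
]


@dataclass
class StimulusSet:
    n_mf: int
    patterns: np.ndarray  # (N, n_mf) uint8, pairwise distinct
    p_mf: float
    correlation_group_size: int = 1
    seed: int = 0

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.patterns, fmt="%d", delimiter=",")


@dataclass
class SpikeTrainSet:
    times: list  # per-MF arrays of spike times (ms), strictly increasing
    active_rate: float  # Hz
    inactive_rate: float  # Hz
    duration: float  # ms
    seed: int | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mf_id\ttime_ms\n")
            for i, t in enumerate(self.times):
                for x in t:
                    fh.write(f"{i}\t{x:.5f}\n")


def _n_active(n_mf: int, p_mf: float) -> int:
    return int(round(p_mf * n_mf))


def make_patterns(
    n_mf: int, n_patterns: int, p_mf: float, seed: int | np.random.Generator = 0
) -> StimulusSet:
    """N pairwise-distinct patterns, each activating round(p_mf * n_mf) MFs."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    k = _n_active(n_mf, p_mf)
    if n_patterns > comb(n_mf, k):
        raise ValueError(
            f"only C({n_mf},{k}) distinct patterns exist at p_mf={p_mf}"
        )
    seen: set[bytes] = set()
    rows = np.zeros((n_patterns, n_mf), dtype=np.uint8)
    i = 0
    attempts = 0
    cap = 1000 * n_patterns + 1000
    while i < n_patterns:
        attempts += 1
        if attempts > cap:  # pragma: no cover - combinatorially unreachable
            raise RuntimeError("pattern sampling stalled")
        row = np.zeros(n_mf, dtype=np.uint8)
        if k:
            row[rng.choice(n_mf, size=k, replace=False)] = 1
        key = row.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows[i] = row
        i += 1
    return StimulusSet(
        n_mf=n_mf,
        patterns=rows,
        p_mf=p_mf,
        correlation_group_size=1,
        seed=seed if isinstance(seed, int) else 0,
    )


def make_correlated_patterns(
    n_mf: int,
    n_patterns: int,
    p_mf: float,
    group_size: int = 5,
    geometry: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> StimulusSet:
    """Spatially correlated patterns: neighboring MFs activated in groups.

    Active fibers are accumulated by repeatedly picking an inactive seed
    rosette and switching on it plus its ``group_size - 1`` nearest neighbors
    (3D Euclidean distance between rosette positions) until the target active
    count round(p_mf * n_mf) is reached or exceeded, so the realized count is
    within ``group_size`` of the target.
    """
    if group_size == 1:
        return make_patterns(n_mf, n_patterns, p_mf, seed)
    if geometry is None:
        raise ValueError("rosette geometry required for correlated patterns")
    geometry = np.asarray(geometry, dtype=float)
    if len(geometry) != n_mf:
        raise ValueError("geometry must give one position per MF")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    k = _n_active(n_mf, p_mf)
    tree = cKDTree(geometry)
    _, neighbors = tree.query(geometry, k=min(group_size, n_mf))
    neighbors = np.atleast_2d(neighbors)

    seen: set[bytes] = set()
    rows = np.zeros((n_patterns, n_mf), dtype=np.uint8)
    i = 0
    attempts = 0
    cap = 1000 * n_patterns + 1000
    while i < n_patterns:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                "could not draw enough distinct correlated patterns"
            )
        row = np.zeros(n_mf, dtype=np.uint8)
        while row.sum() < k:
            inactive = np.flatnonzero(row == 0)
            seed_ros = inactive[rng.integers(len(inactive))]
            row[neighbors[seed_ros]] = 1
        key = row.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows[i] = row
        i += 1
    return StimulusSet(
        n_mf=n_mf,
        patterns=rows,
        p_mf=p_mf,
        correlation_group_size=group_size,
        seed=seed if isinstance(seed, int) else 0,
    )


def poissonize(
    pattern: np.ndarray,
    active_rate: float = 80.0,
    inactive_rate: float = 10.0,
    duration: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> SpikeTrainSet:
    """Homogeneous Poisson spike trains for one binary MF pattern.

    Active bits fire at ``active_rate`` Hz, inactive bits at
    ``inactive_rate`` Hz, independently across fibers, over ``duration`` ms.
    """
    if active_rate < 0 or inactive_rate < 0:
        raise ValueError("rates must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pattern = np.asarray(pattern).ravel()
    times = []
    for bit in pattern:
        rate = active_rate if bit else inactive_rate
        n = rng.poisson(rate * duration / 1000.0)
        t = np.sort(rng.random(n) * duration)
        # continuous times: ties have measure zero, but enforce the invariant
        times.append(np.unique(t))
    return SpikeTrainSet(
        times=times,
        active_rate=active_rate,
        inactive_rate=inactive_rate,
        duration=duration,
        seed=seed if isinstance(seed, int) else None,
    )
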