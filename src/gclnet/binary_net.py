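"""Uniform binary network (UBN) model of the granule cell layer.

A random bipartite graph of binary mossy fibers (MFs) and linear-threshold
binary granule cells (GCs): each GC is connected to ``d`` MF inputs chosen
uniformly without replacement and outputs 1 when the number of active inputs
reaches its integer threshold phi. The model is noise-free: a binary MF
pattern maps deterministically to a binary GC pattern.

Threshold policies
------------------
``absolute``        a fixed integer phi.
``fixed_relative``  phi = ceil(fraction * d), default fraction 0.75.
``nadt``            network-activity-dependent threshold: phi ramps
                    piecewise-constantly from 1 to d over the first
                    1/nadt_scale of the p(MF) range (e.g. NADT = 2 reaches d
                    at p(MF) = 0.5).
``hit_nadt``        high initial threshold combined with NADT: the ramp is
                    floored at ceil(initial_threshold_fraction * d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UniformGraph",
    "ThresholdPolicy",
    "build_uniform_graph",
    "threshold_at",
    "transform",
    "p_gc_analytic",
]


@dataclass
class UniformGraph:
    n_mf: int
    n_gc: int
    d: int
    adjacency: np.ndarray  # (n_gc, d) distinct MF indices per GC
    seed: int | None = None

    def dense_matrix(self, dtype=np.float32) -> np.ndarray:
        """(n_gc, n_mf) 0/1 connection matrix."""
        a = np.zeros((self.n_gc, self.n_mf), dtype=dtype)
        rows = np.repeat(np.arange(self.n_gc), self.d)
        a[rows, self.adjacency.ravel()] = 1
        return a


@dataclass(frozen=True)
class ThresholdPolicy:
    kind: str = "fixed_relative"
    absolute_value: int = 1
    relative_fraction: float = 0.75
    nadt_scale: float = 1.0
    initial_threshold_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.kind not in {"absolute", "fixed_relative", "nadt", "hit_nadt"}:
            raise ValueError(f"unknown threshold kind {self.kind!r}")

    def __call__(self, d: int, p_mf: float) -> int:
        return threshold_at(self, d, p_mf)


def threshold_at(policy: ThresholdPolicy, d: int, p_mf: float) -> int:
    """Integer firing threshold phi in [1, d] for a given MF activity level."""
    if not 0.0 <= p_mf <= 1.0:
        raise ValueError("p_mf must lie in [0, 1]")
    if policy.kind == "absolute":
        phi = policy.absolute_value
    elif policy.kind == "fixed_relative":
        phi = int(np.ceil(policy.relative_fraction * d))
    elif policy.kind == "nadt":
        phi = int(np.ceil(d * min(policy.nadt_scale * p_mf, 1.0)))
    else:  # hit_nadt: ramp from the high initial threshold up to d
        floor = int(np.ceil(policy.initial_threshold_fraction * d))
        frac = min(policy.nadt_scale * p_mf, 1.0)
        phi = int(np.ceil(floor + (d - floor) * frac))
        phi = max(phi, floor)
    return int(min(max(phi, 1), d))


def build_uniform_graph(
    n_mf: int, n_gc: int, d: int, seed: int | np.random.Generator = 0
) -> UniformGraph:
    """Random bipartite graph: d distinct MF parents per GC, iid across GCs."""
    if not 1 <= d <= n_mf:
        raise ValueError("require 1 <= d <= n_mf")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # sample-without-replacement via partial argsort of iid uniforms
    keys = rng.random((n_gc, n_mf))
    adjacency = np.argpartition(keys, d - 1, axis=1)[:, :d].copy()
    return UniformGraph(
        n_mf=n_mf,
        n_gc=n_gc,
        d=d,
        adjacency=adjacency,
        seed=seed if isinstance(seed, int) else None,
    )


def transform(
    graph: UniformGraph, phi: int, pattern: np.ndarray
) -> np.ndarray:
    """Deterministic MF -> GC pattern map.

    ``pattern`` may be one pattern of length n_mf or a (N, n_mf) batch; the
    output is 0/1 with a GC active iff at least phi of its parents are active.
    """
    if not 1 <= phi <= graph.d:
        raise ValueError("phi must lie in [1, d]")
    pattern = np.asarray(pattern)
    single = pattern.ndim == 1
    batch = np.atleast_2d(pattern)
    if batch.shape[1] != graph.n_mf:
        raise ValueError("pattern length does not match n_mf")
    sums = batch.astype(np.float32) @ graph.dense_matrix().T
    out = (sums >= phi - 0.5).astype(np.uint8)
    return out[0] if single else out


def p_gc_analytic(d: int, phi: int, p_mf: float | np.ndarray) -> float | np.ndarray:
    """GC activation probability: binomial tail P(Binom(d, p_mf) >= phi)."""
    p = np.asarray(p_mf, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_mf must lie in [0, 1]")
    out = stats.binom.sf(phi - 1, d, p)
    return float(out) if np.isscalar(p_mf) else out
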