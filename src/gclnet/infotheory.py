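"""Information transmitted by the binary granule-cell population.

Because the uniform binary network is noise-free, the Shannon information
between events and the GC population equals the entropy of the distribution
of GC output patterns, H = -sum_k p(k) log2 p(k) over the G unique GC
patterns. Two estimators are provided:

* exact weighted enumeration of all 2^n_mf inputs (small networks), giving
  the event-count-unlimited entropy under Bernoulli(p) inputs;
* Monte-Carlo event sampling: N input patterns drawn at Bernoulli(p) —
  non-repeating by default, so the event information is exactly log2 N —
  pushed through the network, with the plug-in entropy of the GC images
  averaged over repetitions (fresh network instantiation per repetition).

A "lossless" region is a stretch of the p(MF) grid where the GC population
keeps more than a stated fraction (99% by default) of the event information
log2 N; the "sparse encodable" range additionally requires p(GC) < p(MF).
At p(MF) = 0 or 1 a single input pattern exists, so every network is
trivially lossy there; coverage statistics therefore consider only
non-degenerate grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binary_net import (
    ThresholdPolicy,
    UniformGraph,
    build_uniform_graph,
    p_gc_analytic,
    threshold_at,
)

__all__ = [
    "EventEnsemble",
    "EntropyCurve",
    "RangeResult",
    "entropy_from_counts",
    "sample_event_patterns",
    "event_entropy",
    "exact_asymptotic_entropy",
    "entropy_curve",
    "lossless_intervals",
    "sparse_encodable_range",
    "grid_coverage",
    "average_activation",
    "pareto_best",
]


@dataclass(frozen=True)
class EventEnsemble:
    """An ensemble of sensory-motor events presented as binary MF patterns."""

    n_events: int
    p_mf: float
    seed: int = 0
    distinct: bool = True  # events are non-repeating input patterns

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.p_mf <= 1.0:
            raise ValueError("p_mf must lie in [0, 1]")


@dataclass
class EntropyCurve:
    p_mf_grid: np.ndarray
    entropy_bits: np.ndarray
    entropy_sd: np.ndarray
    p_gc: np.ndarray  # exact binomial-tail activation probability
    n_events: int
    d: int | None = None
    policy: ThresholdPolicy | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "p_mf": self.p_mf_grid,
                "entropy_bits": self.entropy_bits,
                "entropy_sd": self.entropy_sd,
                "p_gc": self.p_gc,
            }
        )


@dataclass
class RangeResult:
    intervals: list = field(default_factory=list)  # [p_lo, p_hi] pairs
    total_measure: float = 0.0
    avg_output_sparseness: float = 0.0


def entropy_from_counts(counts, miller_madow: bool = False) -> float:
    """Plug-in Shannon entropy (bits) of pattern multiplicities.

    ``counts`` are the positive multiplicities of the unique GC patterns
    over N events; the optional Miller-Madow term (G-1)/(2 N ln 2) corrects
    small-sample downward bias.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty counts")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    n = counts.sum()
    h = np.log2(n) - float(counts @ np.log2(counts)) / n
    if miller_madow:
        h += (counts.size - 1) / (2.0 * n * np.log(2.0))
    return float(h)


def _pack_rows(bits: np.ndarray) -> np.ndarray:
    """Pack 0/1 rows into a 1-D void view usable with np.unique."""
    packed = np.packbits(bits, axis=1)
    return packed.view([("", packed.dtype)] * packed.shape[1]).ravel()


def sample_event_patterns(
    n_mf: int,
    n_events: int,
    p_mf: float,
    rng: np.random.Generator,
    distinct: bool = True,
    strict: bool = True,
    max_draw_factor: int = 30,
) -> np.ndarray:
    """Draw binary MF event patterns at Bernoulli(p_mf).

    With ``distinct`` the events are non-repeating: duplicate draws are
    rejected. If fewer than ``n_events`` distinct patterns can be collected
    within the attempt budget (or exist at all), ``strict`` raises; otherwise
    the achievable set is returned, which is how entropy saturates below
    log2 N near the degenerate ends of the activity range.
    """
    if p_mf in (0.0, 1.0):
        if distinct and n_events > 1:
            if strict:
                raise ValueError(
                    "only one distinct pattern exists at this p_mf"
                )
            n_events = 1
        value = 0 if p_mf == 0.0 else 1
        return np.full((n_events, n_mf), value, dtype=np.uint8)

    if not distinct:
        return (rng.random((n_events, n_mf)) < p_mf).astype(np.uint8)

    collected: list[np.ndarray] = []
    seen: set[bytes] = set()
    budget = max(max_draw_factor * n_events, 1024)
    drawn = 0
    while len(seen) < n_events and drawn < budget:
        batch = min(max(n_events - len(seen), 1024), budget - drawn)
        rows = (rng.random((batch, n_mf)) < p_mf).astype(np.uint8)
        drawn += batch
        packed = np.packbits(rows, axis=1)
        for i in range(rows.shape[0]):
            key = packed[i].tobytes()
            if key not in seen:
                seen.add(key)
                collected.append(rows[i])
                if len(seen) == n_events:
                    break
    if len(seen) < n_events and strict:
        raise ValueError(
            f"could not draw {n_events} distinct patterns at p_mf={p_mf}"
        )
    return np.asarray(collected, dtype=np.uint8)


def _gc_image_entropy(
    dense: np.ndarray, phi: int, patterns: np.ndarray, miller_madow: bool
) -> tuple[float, float]:
    """Entropy of the GC images of ``patterns`` and their mean activity."""
    sums = patterns.astype(np.float32) @ dense.T
    out = (sums >= phi - 0.5).astype(np.uint8)
    _, counts = np.unique(_pack_rows(out), return_counts=True)
    return entropy_from_counts(counts, miller_madow), float(out.mean())


def event_entropy(
    graph: UniformGraph,
    policy: ThresholdPolicy,
    ensemble: EventEnsemble,
    reps: int = 1,
    strict: bool = True,
    reinstantiate: bool = False,
    miller_madow: bool = False,
) -> tuple[float, float]:
    """Mean and sd of the GC-population entropy over ``reps`` repetitions.

    Each repetition draws a fresh event sample (and, with ``reinstantiate``,
    a fresh random graph of the same shape) and applies the plug-in entropy
    to the GC images. The result is capped at log2 N by construction when
    events are distinct.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(ensemble.seed)
    phi = threshold_at(policy, graph.d, ensemble.p_mf)
    values = []
    dense = graph.dense_matrix()
    for _ in range(reps):
        if reinstantiate:
            g = build_uniform_graph(graph.n_mf, graph.n_gc, graph.d, rng)
            dense = g.dense_matrix()
        patterns = sample_event_patterns(
            graph.n_mf,
            ensemble.n_events,
            ensemble.p_mf,
            rng,
            distinct=ensemble.distinct,
            strict=strict,
        )
        h, _ = _gc_image_entropy(dense, phi, patterns, miller_madow)
        values.append(h)
    values = np.asarray(values)
    return float(values.mean()), float(values.std(ddof=1) if reps > 1 else 0.0)


def exact_asymptotic_entropy(
    graph: UniformGraph, phi: int, p_mf: float, max_n_mf: int = 20
) -> float:
    """Exact GC-population entropy under Bernoulli(p_mf) inputs.

    Enumerates all 2^n_mf input patterns with their probabilities and sums
    the induced GC-pattern distribution; this is the infinite-event limit of
    the Monte-Carlo estimate without the log2 N cap.
    """
    n = graph.n_mf
    if n > max_n_mf:
        raise ValueError("use Monte Carlo: n_mf too large for enumeration")
    if p_mf in (0.0, 1.0):
        return 0.0
    codes = np.arange(2**n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)
    k = bits.sum(axis=1)
    logw = k * np.log(p_mf) + (n - k) * np.log1p(-p_mf)
    w = np.exp(logw)
    sums = bits.astype(np.float32) @ graph.dense_matrix().T
    out = (sums >= phi - 0.5).astype(np.uint8)
    _, inverse = np.unique(_pack_rows(out), return_inverse=True)
    probs = np.bincount(inverse, weights=w)
    probs = probs[probs > 0]
    return float(-(probs @ np.log2(probs)))


def entropy_curve(
    n_mf: int,
    n_gc: int,
    d: int,
    policy: ThresholdPolicy,
    p_grid: np.ndarray | int = 101,
    n_events: int = 2**14,
    reps: int = 5,
    seed: int = 0,
    distinct: bool = True,
    miller_madow: bool = False,
) -> EntropyCurve:
    """GC-population entropy and p(GC) across the MF activity grid.

    Each repetition uses a fresh random graph instantiation and a fresh event
    sample; near the grid ends the achievable number of distinct events may
    fall below ``n_events``, which caps the entropy there. ``p_gc`` is the
    exact binomial-tail activation probability at each grid point.
    """
    if isinstance(p_grid, int):
        p_grid = np.round(np.linspace(0.0, 1.0, p_grid), 10)
    p_grid = np.asarray(p_grid, dtype=float)
    rng = np.random.default_rng(seed)

    h_mean = np.empty(len(p_grid))
    h_sd = np.empty(len(p_grid))
    p_gc = np.empty(len(p_grid))
    samples = np.empty((reps, len(p_grid)))

    graphs = [build_uniform_graph(n_mf, n_gc, d, rng) for _ in range(reps)]
    denses = [g.dense_matrix() for g in graphs]
    for j, p in enumerate(p_grid):
        phi = threshold_at(policy, d, p)
        p_gc[j] = p_gc_analytic(d, phi, p)
        for r in range(reps):
            patterns = sample_event_patterns(
                n_mf, n_events, p, rng, distinct=distinct, strict=False
            )
            samples[r, j], _ = _gc_image_entropy(
                denses[r], phi, patterns, miller_madow
            )
    h_mean[:] = samples.mean(axis=0)
    h_sd[:] = samples.std(axis=0, ddof=1) if reps > 1 else 0.0
    return EntropyCurve(
        p_mf_grid=p_grid,
        entropy_bits=h_mean,
        entropy_sd=h_sd,
        p_gc=p_gc,
        n_events=n_events,
        d=d,
        policy=policy,
    )


def _policy_breakpoints(d: int, policy: ThresholdPolicy) -> np.ndarray:
    """p values where the (piecewise-constant) threshold may step."""
    if policy.kind in ("absolute", "fixed_relative"):
        inner = []
    elif policy.kind == "nadt":
        inner = [k / (d * policy.nadt_scale) for k in range(1, d + 1)]
    else:  # hit_nadt
        phi0 = int(np.ceil(policy.initial_threshold_fraction * d))
        span = d - phi0
        inner = (
            [(k) / (span * policy.nadt_scale) for k in range(1, span + 1)]
            if span > 0
            else []
        )
    pts = [0.0] + [p for p in inner if 0.0 < p < 1.0] + [1.0]
    return np.unique(pts)


def average_activation(d: int, policy: ThresholdPolicy, n_nodes: int = 64) -> float:
    """Average of p(GC) over p(MF) in [0, 1], to quadrature precision.

    The threshold is piecewise constant in p, so the integrand is a
    polynomial binomial tail on each segment; Gauss-Legendre with 64 nodes
    integrates it exactly. This removes grid-discretization noise from the
    averaged output sparseness, which otherwise breaks exact ties between
    connectivities (e.g. d = 3 and d = 11 at the 0.75 relative threshold
    both average p(GC) = 1/4).
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    breaks = _policy_breakpoints(d, policy)
    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        phi = threshold_at(policy, d, (a + b) / 2.0)
        p = (a + b) / 2.0 + (b - a) / 2.0 * nodes
        total += (b - a) / 2.0 * float(weights @ p_gc_analytic(d, phi, p))
    return total


def _intervals_from_mask(p_grid: np.ndarray, mask: np.ndarray) -> list:
    intervals = []
    start = None
    for j, ok in enumerate(mask):
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            intervals.append([float(p_grid[start]), float(p_grid[j - 1])])
            start = None
    if start is not None:
        intervals.append([float(p_grid[start]), float(p_grid[-1])])
    return intervals


def _sparseness(curve: EntropyCurve) -> float:
    if curve.policy is not None and curve.d is not None:
        return float(1.0 - average_activation(curve.d, curve.policy))
    return float(1.0 - curve.p_gc.mean())


def lossless_intervals(curve: EntropyCurve, fraction: float = 0.99) -> RangeResult:
    """Maximal grid intervals where entropy >= fraction * log2(n_events)."""
    cap = np.log2(curve.n_events)
    mask = curve.entropy_bits >= fraction * cap
    intervals = _intervals_from_mask(curve.p_mf_grid, mask)
    return RangeResult(
        intervals=intervals,
        total_measure=float(sum(hi - lo for lo, hi in intervals)),
        avg_output_sparseness=_sparseness(curve),
    )


def sparse_encodable_range(
    curve: EntropyCurve, fraction: float = 0.99
) -> RangeResult:
    """Grid intervals that are both lossless and sparser than the input.

    The sparseness condition p(GC) < p(MF) is evaluated on the exact
    activation probability (strictly, so an identity relay yields an empty
    range).
    """
    cap = np.log2(curve.n_events)
    mask = (curve.entropy_bits >= fraction * cap) & (
        curve.p_gc < curve.p_mf_grid - 1e-9
    )
    intervals = _intervals_from_mask(curve.p_mf_grid, mask)
    return RangeResult(
        intervals=intervals,
        total_measure=float(sum(hi - lo for lo, hi in intervals)),
        avg_output_sparseness=_sparseness(curve),
    )


def grid_coverage(curve: EntropyCurve, fraction: float = 0.99) -> float:
    """Share of non-degenerate grid points (0 < p < 1) that are lossless."""
    cap = np.log2(curve.n_events)
    interior = (curve.p_mf_grid > 0.0) & (curve.p_mf_grid < 1.0)
    if not interior.any():
        return 0.0
    ok = curve.entropy_bits[interior] >= fraction * cap
    return float(ok.mean())


def pareto_best(results: list, eps: float = 1e-9) -> list:
    """Non-dominated subset under (range measure, output sparseness), both maximized.

    ``results`` is a list of (label, RangeResult) or (d, policy, RangeResult)
    tuples; the RangeResult is taken from the last position. Differences
    below ``eps`` are treated as ties, so exactly tied metrics do not keep a
    strictly worse configuration on the front.
    """
    if not results:
        raise ValueError("need at least one result")
    metrics = [
        (item[-1].total_measure, item[-1].avg_output_sparseness)
        for item in results
    ]
    front = []
    for i, (mi, si) in enumerate(metrics):
        dominated = any(
            (mj >= mi - eps and sj >= si - eps)
            and (mj > mi + eps or sj > si + eps)
            for j, (mj, sj) in enumerate(metrics)
            if j != i
        )
        if not dominated:
            front.append(results[i])
    return front
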