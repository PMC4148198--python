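"""Anatomically constrained local granule-cell-layer network.

Builds a 3D model of the local mossy-fiber (MF) rosette to granule cell (GC)
circuit: GCs placed at the measured density inside a sphere, rosettes at
their measured density in a slightly larger sphere (a margin shell avoids
edge effects), and each GC wired to ``d`` distinct rosettes with a dendritic
length close to 15 um and never above 30 um.

Densities are given per mm^3 (as printed in the anatomical literature) and
converted internally; all coordinates and lengths are in micrometres with
the origin at the sphere centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AnatomyParams",
    "LocalNetwork",
    "ConnectivityStats",
    "generate_fields",
    "wire_dendrites",
    "summarize",
    "build_local_network",
]

#: cubic micrometres per cubic millimetre
_UM3_PER_MM3 = 1e9


def _sphere_volume(radius_um: float) -> float:
    return 4.0 / 3.0 * np.pi * radius_um**3


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of the local GCL field.

    Defaults are the measured rat values: GC density 1.9e6 mm^-3, glomerulus
    (rosette) density 6.6e5 mm^-3, a 40-um-radius ball, four dendrites per
    GC targeting 15 um and capped at 30 um.
    """

    gc_density: float = 1.9e6           # cells / mm^3
    rosette_density: float = 6.6e5      # rosettes / mm^3
    field_radius: float = 40.0          # um
    margin: float = 20.0                # um, extra rosette shell
    dendrites_per_gc: int = 4
    target_dendrite_length: float = 15.0  # um
    max_dendrite_length: float = 30.0     # um
    length_sigma: float = 2.0           # um, width of the length-selection weight
    fixed_counts: bool = False          # pin counts to round(density * volume)
    pinned_gc_count: int | None = None      # replicate a specific instantiation
    pinned_rosette_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gc_density <= 0 or self.rosette_density <= 0:
            raise ValueError("densities must be positive")
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.dendrites_per_gc < 1:
            raise ValueError("dendrites_per_gc must be >= 1")
        if self.target_dendrite_length > self.max_dendrite_length:
            raise ValueError("target dendrite length exceeds the maximum")

    @property
    def expected_gc_count(self) -> float:
        return self.gc_density / _UM3_PER_MM3 * _sphere_volume(self.field_radius)

    @property
    def expected_rosette_count(self) -> float:
        return (
            self.rosette_density
            / _UM3_PER_MM3
            * _sphere_volume(self.field_radius + self.margin)
        )


@dataclass
class LocalNetwork:
    """Bipartite rosette -> GC connectivity with 3D geometry.

    ``edge_gc[i]``, ``edge_rosette[i]`` and ``edge_length[i]`` describe the
    i-th dendrite; every GC owns exactly ``d`` consecutive edges.
    """

    rosette_positions: np.ndarray  # (n_rosette, 3) um
    gc_positions: np.ndarray       # (n_gc, 3) um
    edge_gc: np.ndarray            # (n_gc * d,) int
    edge_rosette: np.ndarray       # (n_gc * d,) int
    edge_length: np.ndarray        # (n_gc * d,) um
    d: int
    field_radius: float | None = None

    @property
    def n_gc(self) -> int:
        return len(self.gc_positions)

    @property
    def n_rosette(self) -> int:
        return len(self.rosette_positions)

    def adjacency(self) -> np.ndarray:
        """(n_gc, d) array of rosette indices per GC."""
        order = np.lexsort((self.edge_rosette, self.edge_gc))
        return self.edge_rosette[order].reshape(self.n_gc, self.d)

    def validate(self) -> None:
        adj = self.adjacency()
        if not all(len(set(row)) == self.d for row in adj):
            raise ValueError("a GC has duplicate rosette parents")
        if self.edge_rosette.max(initial=-1) >= self.n_rosette:
            raise ValueError("rosette index out of range")
        if self.edge_gc.max(initial=-1) >= self.n_gc:
            raise ValueError("gc index out of range")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "d": self.d,
                "field_radius": self.field_radius,
                "rosette_positions": self.rosette_positions.tolist(),
                "gc_positions": self.gc_positions.tolist(),
                "edges": [
                    [int(g), int(r), float(l)]
                    for g, r, l in zip(
                        self.edge_gc, self.edge_rosette, self.edge_length
                    )
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LocalNetwork":
        obj = json.loads(text)
        edges = np.asarray(obj["edges"], dtype=float)
        return cls(
            rosette_positions=np.asarray(obj["rosette_positions"], dtype=float),
            gc_positions=np.asarray(obj["gc_positions"], dtype=float),
            edge_gc=edges[:, 0].astype(int),
            edge_rosette=edges[:, 1].astype(int),
            edge_length=edges[:, 2],
            d=int(obj["d"]),
            field_radius=obj.get("field_radius"),
        )

    def to_edge_tsv(self, path) -> None:
        """Flat TSV edge list (gc_id, rosette_id, length_um), 0-based."""
        with open(path, "w") as fh:
            fh.write("gc_id\trosette_id\tlength_um\n")
            for g, r, l in zip(self.edge_gc, self.edge_rosette, self.edge_length):
                fh.write(f"{int(g)}\t{int(r)}\t{l:.4f}\n")


@dataclass
class ConnectivityStats:
    n_gc: int
    n_rosette: int  # rosettes inside the central field
    dendrite_length_bin_edges: np.ndarray
    dendrite_length_counts: np.ndarray
    gcs_per_rosette_values: np.ndarray
    gcs_per_rosette_counts: np.ndarray
    mean_gcs_per_rosette: float
    expansion_ratio: float


def _uniform_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a ball: uniform direction, radius ~ r^3 inverse CDF."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return u * r[:, None]


def generate_fields(
    params: AnatomyParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Place rosettes and GCs at their anatomical densities.

    GCs fill the central sphere of ``field_radius``; rosettes fill the larger
    sphere of ``field_radius + margin``. Counts are Poisson draws around
    density x volume (or pinned to the rounded expectation when
    ``fixed_counts`` is set).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mu_gc = params.expected_gc_count
    mu_ros = params.expected_rosette_count
    if round(mu_gc) < 1 or round(mu_ros) < 1:
        raise ValueError("degenerate field: expected counts below one")
    if params.fixed_counts:
        n_gc, n_ros = int(round(mu_gc)), int(round(mu_ros))
    else:
        n_gc = int(rng.poisson(mu_gc))
        n_ros = int(rng.poisson(mu_ros))
        if n_gc < 1 or n_ros < 1:
            raise ValueError("degenerate field: zero cells drawn")
    if params.pinned_gc_count is not None:
        n_gc = params.pinned_gc_count
    if params.pinned_rosette_count is not None:
        n_ros = params.pinned_rosette_count
    rosettes = _uniform_ball(n_ros, params.field_radius + params.margin, rng)
    gcs = _uniform_ball(n_gc, params.field_radius, rng)
    return rosettes, gcs


def wire_dendrites(
    rosettes: np.ndarray,
    gcs: np.ndarray,
    d: int,
    target_len: float = 15.0,
    max_len: float = 30.0,
    seed: int | np.random.Generator = 0,
    length_sigma: float = 2.0,
    field_radius: float | None = None,
    retry_cap: int = 50,
) -> LocalNetwork:
    """Wire each GC to ``d`` distinct rosettes within ``max_len``.

    Candidate rosettes are sampled without replacement with weight
    exp(-(len - target)^2 / (2 sigma^2)), concentrating dendritic lengths
    near the target. A GC with fewer than ``d`` reachable rosettes is given a
    fresh uniform position (up to ``retry_cap`` times) before failing.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rosettes = np.asarray(rosettes, dtype=float)
    gcs = np.array(gcs, dtype=float, copy=True)
    if field_radius is None:
        field_radius = float(np.linalg.norm(gcs, axis=1).max()) if len(gcs) else 0.0
    if len(rosettes) < d:
        raise ValueError("unwireable cell: fewer rosettes than dendrites")

    tree = cKDTree(rosettes)
    n_gc = len(gcs)
    edge_gc = np.repeat(np.arange(n_gc), d)
    edge_rosette = np.empty(n_gc * d, dtype=int)
    edge_length = np.empty(n_gc * d, dtype=float)

    for i in range(n_gc):
        for attempt in range(retry_cap + 1):
            idx = tree.query_ball_point(gcs[i], max_len)
            if len(idx) >= d:
                break
            if attempt == retry_cap:
                raise ValueError("unwireable cell")
            gcs[i] = _uniform_ball(1, field_radius, rng)[0]
        idx = np.asarray(idx)
        dist = np.linalg.norm(rosettes[idx] - gcs[i], axis=1)
        w = np.exp(-((dist - target_len) ** 2) / (2.0 * length_sigma**2))
        w_sum = w.sum()
        if w_sum <= 0 or not np.isfinite(w_sum):
            w = np.ones_like(w)
        chosen = rng.choice(len(idx), size=d, replace=False, p=w / w.sum())
        sl = slice(i * d, (i + 1) * d)
        edge_rosette[sl] = idx[chosen]
        edge_length[sl] = dist[chosen]

    return LocalNetwork(
        rosette_positions=rosettes,
        gc_positions=gcs,
        edge_gc=edge_gc,
        edge_rosette=edge_rosette,
        edge_length=edge_length,
        d=d,
        field_radius=field_radius,
    )


def build_local_network(params: AnatomyParams) -> LocalNetwork:
    """Generate fields and wire dendrites in one deterministic step."""
    rng = np.random.default_rng(params.seed)
    rosettes, gcs = generate_fields(params, rng)
    return wire_dendrites(
        rosettes,
        gcs,
        params.dendrites_per_gc,
        target_len=params.target_dendrite_length,
        max_len=params.max_dendrite_length,
        seed=rng,
        length_sigma=params.length_sigma,
        field_radius=params.field_radius,
    )


def summarize(
    net: LocalNetwork, field_radius: float | None = None
) -> ConnectivityStats:
    """Connectivity statistics of a wired local network.

    ``n_rosette`` counts rosettes inside the central field (the GC sphere),
    matching how the local circuit is described anatomically; the
    dendrites-per-rosette histogram covers every rosette in the model so its
    mass equals the total edge count n_gc * d.
    """
    radius = field_radius if field_radius is not None else net.field_radius
    if radius is not None:
        central = np.linalg.norm(net.rosette_positions, axis=1) <= radius + 1e-9
        n_central = int(central.sum())
    else:
        n_central = net.n_rosette
    if n_central == 0:
        raise ValueError("no rosettes in the central field")

    degrees = np.bincount(net.edge_rosette, minlength=net.n_rosette)
    values, counts = np.unique(degrees, return_counts=True)

    max_len = float(np.ceil(net.edge_length.max())) if len(net.edge_length) else 1.0
    edges = np.arange(0.0, max_len + 1.0)
    hist, _ = np.histogram(net.edge_length, bins=edges)

    total_edges = net.n_gc * net.d
    return ConnectivityStats(
        n_gc=net.n_gc,
        n_rosette=n_central,
        dendrite_length_bin_edges=edges,
        dendrite_length_counts=hist,
        gcs_per_rosette_values=values,
        gcs_per_rosette_counts=counts,
        mean_gcs_per_rosette=total_edges / n_central,
        expansion_ratio=net.n_gc / n_central,
    )
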