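"""Seeded synthetic fixtures: multi-route pathway ensembles, Gaussian
"conformation" blobs, and small weighted-ensemble trajectory trees.

The route dynamics are Markovian: a trajectory dwells in each state of
its route for a geometric number of frames (mean ``dwell_mean``) and,
with probability ``noise_rate`` per frame, makes a one-frame excursion
to an off-route intermediate state. The default ensemble has six
states, two routes between source and target, and an 0.875 / 0.125
route split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .extract import TrajectoryTree

__all__ = [
    "RouteSpec",
    "SyntheticEnsemble",
    "generate_pathway_ensemble",
    "generate_blobs",
    "generate_we_tree",
    "default_route_spec",
    "default_blob_centroids",
]


@dataclass(frozen=True)
class RouteSpec:
    """Ground-truth definition of a multi-route transition ensemble."""

    states: tuple[int, ...]
    routes: tuple[tuple[tuple[int, ...], float], ...]  # (state sequence, probability)
    dwell_mean: float = 1.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.routes:
            raise ValueError("need at least one route")
        probs = [p for _, p in self.routes]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("route probabilities must be non-negative and sum to 1")
        starts = {r[0] for r, _ in self.routes}
        ends = {r[-1] for r, _ in self.routes}
        if len(starts) != 1 or len(ends) != 1:
            raise ValueError("every route must share the same source and target")
        if starts == ends:
            raise ValueError("source and target must differ")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        for route, _ in self.routes:
            missing = set(route) - set(self.states)
            if missing:
                raise ValueError(f"route states {missing} not declared in states")

    @property
    def source_id(self) -> int:
        return self.routes[0][0][0]

    @property
    def target_id(self) -> int:
        return self.routes[0][0][-1]

    def off_route_states(self, route: Sequence[int]) -> list[int]:
        return [s for s in self.states if s not in set(route)]


def default_route_spec(seed: int = 0) -> RouteSpec:
    """Six states, two routes, 0.875/0.125 split."""
    return RouteSpec(
        states=(0, 1, 2, 3, 4, 5),
        routes=(((0, 1, 2, 5), 0.875), ((0, 3, 4, 5), 0.125)),
        dwell_mean=3.0,
        noise_rate=0.05,
        seed=seed,
    )


def default_blob_centroids() -> np.ndarray:
    """Six well-separated 2-D centroids in a remapped angle space."""
    return np.array(
        [
            [-150.0, 150.0],
            [-150.0, -60.0],
            [-70.0, 135.0],
            [60.0, -70.0],
            [25.0, 60.0],
            [140.0, -100.0],
        ]
    )


@dataclass
class SyntheticEnsemble:
    """Generated trajectories plus ground truth."""

    spec: RouteSpec
    trajectories: list[np.ndarray]
    route_labels: np.ndarray  # index into spec.routes per trajectory
    weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.weights is None:
            n = len(self.trajectories)
            self.weights = np.full(n, 1.0 / n)


def _geometric(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def _simulate_trajectory(rng: np.random.Generator, spec: RouteSpec, route: Sequence[int]) -> np.ndarray:
    """Source dwell, route traversal with dwells and noise, first target entry."""
    labels: list[int] = []
    off_route = spec.off_route_states(route)
    labels.extend([route[0]] * _geometric(rng, spec.dwell_mean))
    for state in route[1:-1]:
        for _ in range(_geometric(rng, spec.dwell_mean)):
            labels.append(state)
            if off_route and rng.random() < spec.noise_rate:
                labels.append(int(off_route[rng.integers(len(off_route))]))
    labels.append(route[-1])
    return np.array(labels, dtype=np.int64)


def generate_pathway_ensemble(
    spec: RouteSpec, n_paths: int, seed: int | None = None
) -> SyntheticEnsemble:
    """Sample ``n_paths`` trajectories with recorded ground-truth routes."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    probs = np.array([p for _, p in spec.routes])
    route_idx = rng.choice(len(spec.routes), size=n_paths, p=probs)
    trajectories = [_simulate_trajectory(rng, spec, spec.routes[i][0]) for i in route_idx]
    return SyntheticEnsemble(spec=spec, trajectories=trajectories, route_labels=route_idx)


def generate_blobs(
    centroids, sigma: float, n_per: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clouds with generating labels."""
    cents = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(np.unique(cents, axis=0)) != len(cents):
        raise ValueError("centroids must be distinct")
    rng = np.random.default_rng(seed)
    features = np.concatenate(
        [c + sigma * rng.standard_normal((n_per, cents.shape[1])) for c in cents]
    )
    labels = np.repeat(np.arange(len(cents)), n_per)
    return features, labels


class _Walker:
    """Hidden dynamic state of one WE walker."""

    __slots__ = ("route", "pos", "weight")

    def __init__(self, route: tuple[int, ...], pos: int, weight: float):
        self.route = route
        self.pos = pos
        self.weight = weight

    def copy(self, weight: float | None = None) -> "_Walker":
        return _Walker(self.route, self.pos, self.weight if weight is None else weight)

    def step(self, rng: np.random.Generator, spec: RouteSpec) -> int:
        """Emit one frame label and possibly advance along the route."""
        if self.pos == len(self.route) - 1:
            return int(self.route[-1])  # absorbed in target
        off_route = spec.off_route_states(self.route)
        if off_route and rng.random() < spec.noise_rate:
            return int(off_route[rng.integers(len(off_route))])
        label = int(self.route[self.pos])
        if rng.random() < 1.0 / spec.dwell_mean:
            self.pos += 1
        return label


def generate_we_tree(
    spec: RouteSpec,
    n_iterations: int,
    segs_per_iteration: int,
    tau_frames: int,
    seed: int | None = None,
) -> TrajectoryTree:
    """Simulate a binary split/merge weighted-ensemble tree.

    Per-iteration weights always sum to 1: each iteration (with >= 3
    walkers) the heaviest walker is split into two half-weight children
    and the two lightest are merged into one survivor chosen with
    probability proportional to weight. With one walker per iteration
    the result is a flat chain equivalent to a cMD label series.
    """
    if min(n_iterations, segs_per_iteration, tau_frames) < 1:
        raise ValueError("n_iterations, segs_per_iteration, tau_frames must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    probs = np.array([p for _, p in spec.routes])
    m = segs_per_iteration
    walkers = [
        _Walker(spec.routes[int(rng.choice(len(spec.routes), p=probs))][0], 0, 1.0 / m)
        for _ in range(m)
    ]
    parents = [-1] * m
    tree = TrajectoryTree(tau_frames=tau_frames)
    for it in range(1, n_iterations + 1):
        for sid, w in enumerate(walkers):
            labels = [w.step(rng, spec) for _ in range(tau_frames)]
            tree.add_segment(it, sid, parents[sid], w.weight, labels)
        if it == n_iterations:
            break
        children = [(w.copy(), sid) for sid, w in enumerate(walkers)]
        if m >= 3:
            by_weight = sorted(range(m), key=lambda i: (children[i][0].weight, i))
            heavy = by_weight[-1]
            lo1, lo2 = by_weight[0], by_weight[1]
            w1, w2 = children[lo1][0].weight, children[lo2][0].weight
            keep = lo1 if rng.random() < w1 / (w1 + w2) else lo2
            drop = lo2 if keep == lo1 else lo1
            children[keep][0].weight = w1 + w2
            half = children[heavy][0].weight / 2.0
            children[heavy][0].weight = half
            extra = (children[heavy][0].copy(half), children[heavy][1])
            children[drop] = extra
        walkers = [c[0] for c in children]
        parents = [c[1] for c in children]
    return tree
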