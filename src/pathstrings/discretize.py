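"""Assign trajectory frames to discrete states.

Three assignment modes are supported:

* ``rectilinear`` — a grid of per-dimension bin edges plus one state
  point per named state; a frame gets the state id of the state point
  sharing its bin, or the unassigned sentinel (-1) if its bin holds no
  state point.
* ``hook`` — a user-supplied function mapping a frame batch to labels.
* ``two_stage`` — average-linkage agglomerative clustering of a feature
  subset at a distance threshold, followed by a k-nearest-neighbors
  classifier (default k=5) that labels the remaining frames. This keeps
  the memory cost of clustering bounded by the subset size.

Angle features on a periodic domain should be remapped first with
:func:`remap_periodic` so plain Euclidean distances are valid.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "UNASSIGNED",
    "LabelArray",
    "StateMap",
    "TwoStageModel",
    "remap_periodic",
    "assign_rectilinear",
    "assign_hook",
    "fit_two_stage",
    "predict_two_stage",
    "cluster_centroids",
]

#: Sentinel label for frames in bins without a state point.
UNASSIGNED = -1


def remap_periodic(values, period: float, new_min: float) -> np.ndarray:
    """Shift periodic values by whole periods into [new_min, new_min + period).

    Frame order is preserved; the map is a bijection on one period and
    idempotent on values already in range.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    v = np.asarray(values, dtype=float)
    return (v - new_min) % period + new_min


@dataclass
class LabelArray:
    """Per-frame integer state labels (UNASSIGNED = -1 sentinel allowed)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def __len__(self) -> int:
        return self.labels.size

    def __iter__(self):
        return iter(self.labels)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.labels, dtype=dtype)

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".csv"):
            np.savetxt(path, self.labels, fmt="%d")
        else:
            np.save(path, self.labels)

    @classmethod
    def load(cls, path) -> "LabelArray":
        path = str(path)
        if path.endswith(".csv"):
            return cls(np.loadtxt(path, dtype=np.int64, ndmin=1))
        return cls(np.load(path))


@dataclass
class StateMap:
    """Source/target/intermediate state definitions over feature space.

    In rectilinear mode, ``bin_edges`` holds one strictly increasing edge
    list per feature dimension and ``state_points`` one representative
    coordinate per state id; the bin containing a point defines the
    state. ``periodic_shift`` optionally remaps each dimension with
    (period, new_min) before binning (None entries leave a dimension
    untouched).
    """

    mode: str
    source_id: int
    target_id: int
    bin_edges: list[np.ndarray] = field(default_factory=list)
    state_points: dict[int, np.ndarray] = field(default_factory=dict)
    periodic_shift: list[tuple[float, float] | None] | None = None
    _bin_to_state: dict[tuple, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in {"rectilinear", "hook", "two_stage"}:
            raise ValueError(f"unknown StateMap mode {self.mode!r}")
        if self.source_id == self.target_id:
            raise ValueError("source and target states must differ")
        if self.mode != "rectilinear":
            return
        self.bin_edges = [np.asarray(e, dtype=float) for e in self.bin_edges]
        for d, edges in enumerate(self.bin_edges):
            if edges.size < 2 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"bin edges for dimension {d} must be strictly increasing")
        self.state_points = {int(k): np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.state_points.items()}
        for sid in (self.source_id, self.target_id):
            if sid not in self.state_points:
                raise ValueError(f"state {sid} has no state point")
        self._bin_to_state = {}
        for sid, point in self.state_points.items():
            if point.size != len(self.bin_edges):
                raise ValueError(f"state point {sid} dimensionality mismatch")
            idx = self._bin_index(point, frame=None)
            if idx in self._bin_to_state:
                raise ValueError(
                    f"states {self._bin_to_state[idx]} and {sid} fall in the same bin {idx}"
                )
            self._bin_to_state[idx] = sid

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)

    def _bin_index(self, coords: np.ndarray, frame: int | None) -> tuple:
        idx = []
        for d, edges in enumerate(self.bin_edges):
            x = coords[d]
            if x < edges[0] or x > edges[-1]:
                where = "state point" if frame is None else f"frame {frame}"
                raise ValueError(
                    f"{where} coordinate {x} falls outside the bin grid in dimension {d} "
                    f"[{edges[0]}, {edges[-1]}]"
                )
            i = int(np.searchsorted(edges, x, side="right")) - 1
            i = min(i, edges.size - 2)  # value on the last edge -> last bin
            idx.append(i)
        return tuple(idx)

    @classmethod
    def from_toml(cls, path) -> "StateMap":
        """Load a rectilinear state map from a TOML config.

        Expected keys: ``mode``, ``source``, ``target``, ``bin_edges``
        (list of per-dimension edge lists), ``state_points`` (table of
        state-id -> coordinates), optional ``periodic_shift`` (list of
        [period, new_min] or empty list per dimension).
        """
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        return cls.from_config(cfg)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "StateMap":
        shift = None
        if "periodic_shift" in cfg:
            shift = [tuple(s) if s else None for s in cfg["periodic_shift"]]
        return cls(
            mode=cfg.get("mode", "rectilinear"),
            source_id=int(cfg["source"]),
            target_id=int(cfg["target"]),
            bin_edges=cfg.get("bin_edges", []),
            state_points={int(k): v for k, v in cfg.get("state_points", {}).items()},
            periodic_shift=shift,
        )

    def apply_periodic_shift(self, features: np.ndarray) -> np.ndarray:
        if self.periodic_shift is None:
            return features
        out = np.array(features, dtype=float, copy=True)
        for d, shift in enumerate(self.periodic_shift):
            if shift is not None:
                period, new_min = shift
                out[:, d] = remap_periodic(out[:, d], period, new_min)
        return out


def _as_frames(features) -> np.ndarray:
    """Coerce to (n_frames, n_dims); a 1-D array is a scalar per frame."""
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 1:
        return feats.reshape(-1, 1)
    return np.atleast_2d(feats)


def assign_rectilinear(features, state_map: StateMap) -> LabelArray:
    """Label each frame with the state of the bin it falls into.

    Frames in bins without a state point get UNASSIGNED. A frame outside
    the grid raises, naming the frame index.
    """
    if state_map.mode != "rectilinear":
        raise ValueError("assign_rectilinear requires a rectilinear StateMap")
    feats = _as_frames(features)
    if feats.shape[1] != state_map.ndim:
        raise ValueError(
            f"feature dimensionality {feats.shape[1]} does not match grid ({state_map.ndim})"
        )
    feats = state_map.apply_periodic_shift(feats)
    labels = np.full(feats.shape[0], UNASSIGNED, dtype=np.int64)
    for i, row in enumerate(feats):
        idx = state_map._bin_index(row, frame=i)
        labels[i] = state_map._bin_to_state.get(idx, UNASSIGNED)
    return LabelArray(labels)


def assign_hook(features, hook: Callable, valid_states: Sequence[int] | None = None) -> LabelArray:
    """Label frames with a user function; validate against the state set."""
    feats = np.asarray(features)
    labels = np.asarray(hook(feats))
    if labels.shape[0] != feats.shape[0]:
        raise ValueError(
            f"hook returned {labels.shape[0]} labels for {feats.shape[0]} frames"
        )
    labels = labels.astype(np.int64, casting="unsafe")
    if valid_states is not None:
        allowed = set(int(s) for s in valid_states) | {UNASSIGNED}
        bad = sorted(set(labels.tolist()) - allowed)
        if bad:
            raise ValueError(f"hook produced labels outside the declared state set: {bad}")
    return LabelArray(labels)


@dataclass
class TwoStageModel:
    """Cluster-then-classify model: agglomerative labels + kNN classifier."""

    distance_threshold: float
    n_neighbors: int
    linkage: str
    training_features: np.ndarray
    training_labels: np.ndarray
    centroids: dict[int, np.ndarray]
    _knn: KNeighborsClassifier

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def cluster_centroids(features, labels) -> dict[int, np.ndarray]:
    """Per-cluster mean coordinates."""
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    return {int(c): feats[labels == c].mean(axis=0) for c in np.unique(labels)}


def fit_two_stage(
    subset_features,
    distance_threshold: float,
    linkage: str = "average",
    n_neighbors: int = 5,
) -> TwoStageModel:
    """Cluster a feature subset and fit the kNN classifier on its labels.

    The agglomerative stage uses Euclidean dissimilarity with the given
    linkage (average by default) cut at ``distance_threshold``. Clusters
    are relabeled 0..k-1 by first occurrence so labels are deterministic.
    A threshold yielding a single cluster emits a warning (at least
    three states are expected downstream).
    """
    feats = _as_frames(subset_features)
    if feats.shape[0] < n_neighbors:
        raise ValueError(
            f"subset has {feats.shape[0]} rows but n_neighbors={n_neighbors}"
        )
    agg = AgglomerativeClustering(
        n_clusters=None,
        distance_threshold=float(distance_threshold),
        metric="euclidean",
        linkage=linkage,
    )
    raw = agg.fit_predict(feats)
    # relabel by first occurrence for run-to-run stability
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    n_clusters = len(remap)
    if n_clusters == 1:
        warnings.warn(
            "two-stage clustering produced a single cluster; "
            "lower the distance threshold (>= 3 states are recommended)",
            UserWarning,
            stacklevel=2,
        )
    knn = KNeighborsClassifier(n_neighbors=n_neighbors)
    knn.fit(feats, labels)
    return TwoStageModel(
        distance_threshold=float(distance_threshold),
        n_neighbors=n_neighbors,
        linkage=linkage,
        training_features=feats,
        training_labels=labels,
        centroids=cluster_centroids(feats, labels),
        _knn=knn,
    )


def predict_two_stage(model: TwoStageModel, features) -> LabelArray:
    """Label frames by k-nearest-neighbor vote among the training subset.

    Votes tie-break toward the smallest cluster id. An empty input
    yields an empty LabelArray.
    """
    feats = _as_frames(features) if np.asarray(features).size else np.empty(
        (0, model.training_features.shape[1])
    )
    if feats.size == 0:
        return LabelArray(np.empty(0, dtype=np.int64))
    if feats.shape[1] != model.training_features.shape[1]:
        raise ValueError(
            f"feature dimensionality {feats.shape[1]} does not match model "
            f"({model.training_features.shape[1]})"
        )
    return LabelArray(model._knn.predict(feats))
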