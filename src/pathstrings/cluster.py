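"""Ward clustering of pathway distances and pathway-class summaries.

The pairwise distance matrix (d = 1 - similarity) is clustered with
Ward linkage; classes are read off the dendrogram at a cut height, by
default the midpoint of the largest gap between consecutive merge
heights. Classes are numbered 1..k by decreasing total pathway weight.

Note the distances are ordinal, not a Euclidean embedding; Ward is
applied to them as-is, which is the intended behavior of this workflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .extract import Pathway
from .similarity import DistanceMatrix, condense, pairwise_distances

__all__ = [
    "LinkageTree",
    "ClassReport",
    "ward_linkage",
    "suggest_cut",
    "assign_classes",
    "class_probabilities",
    "duration_histograms",
    "network_edges",
    "network_node_weights",
    "classify_pathways",
]

#: Workflow guardrails (warnings, not errors).
MIN_STATES = 3
MIN_PATHWAYS = 50
MIN_CLASS_SIZE = 10


@dataclass(frozen=True)
class LinkageTree:
    """Hierarchical merge tree (scipy linkage matrix wrapper)."""

    Z: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")
        object.__setattr__(self, "Z", Z)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.Z, columns=["cluster_a", "cluster_b", "merge_height", "size"]).to_csv(
            path, index=False
        )


def ward_linkage(d: DistanceMatrix) -> LinkageTree:
    """Ward-linkage agglomeration of a precomputed distance matrix."""
    if d.n < 2:
        raise ValueError("need at least 2 pathways to cluster")
    Z = linkage(d.condensed(), method="ward")
    return LinkageTree(Z=Z, n_leaves=d.n)


def suggest_cut(tree: LinkageTree) -> tuple[float, int]:
    """Cut at the midpoint of the largest gap between merge heights.

    Ties in gap size break toward fewer classes (cutting too low tends
    to produce classes with redundant features). Degenerate trees where
    all merge heights coincide return a single class with a warning.
    The returned values are advisory; either can be overridden.
    """
    h = tree.heights
    if np.isclose(h.max(), h.min()):
        warnings.warn(
            "all merge heights are equal; no natural class separation exists",
            UserWarning,
            stacklevel=2,
        )
        return float(h.max()), 1
    gaps = np.diff(h)
    # argmax of reversed array -> latest maximal gap -> fewest classes
    i = gaps.size - 1 - int(np.argmax(gaps[::-1]))
    cut = float((h[i] + h[i + 1]) / 2.0)
    n_classes = tree.n_leaves - (i + 1)
    return cut, n_classes


def cut_for_n_classes(tree: LinkageTree, n_classes: int) -> float:
    """Height whose cut yields exactly ``n_classes`` flat clusters."""
    if not 1 <= n_classes <= tree.n_leaves:
        raise ValueError(f"n_classes must be in [1, {tree.n_leaves}]")
    h = tree.heights
    n = tree.n_leaves
    if n_classes == 1:
        return float(h[-1])
    # cutting between merge i-1 and i leaves n - i clusters
    i = n - n_classes
    lo = h[i - 1] if i > 0 else 0.0
    if lo >= h[i]:
        raise ValueError(
            f"exactly {n_classes} classes is unattainable: merge heights tie at {h[i]}"
        )
    return float((lo + h[i]) / 2.0)


def assign_classes(tree: LinkageTree, cut_height: float, weights=None) -> np.ndarray:
    """Flat class labels (1..k) at a cut, numbered by decreasing weight.

    ``weights`` defaults to uniform; ties in total weight break by the
    original flat-cluster label for determinism.
    """
    raw = fcluster(tree.Z, t=cut_height, criterion="distance")
    if weights is None:
        w = np.ones(tree.n_leaves)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != tree.n_leaves:
            raise ValueError("weights length must equal the number of pathways")
    totals = {int(c): float(w[raw == c].sum()) for c in np.unique(raw)}
    order = sorted(totals, key=lambda c: (-totals[c], c))
    remap = {c: rank + 1 for rank, c in enumerate(order)}
    return np.array([remap[int(c)] for c in raw], dtype=np.int64)


def class_probabilities(pathways: Sequence[Pathway], class_of) -> dict[int, float]:
    """Per-class summed pathway weight over total weight."""
    labels = np.asarray(class_of)
    w = np.array([p.weight for p in pathways], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total pathway weight is zero")
    return {int(c): float(w[labels == c].sum() / total) for c in np.unique(labels)}


def duration_histograms(pathways: Sequence[Pathway], class_of) -> dict[int, list[int]]:
    """Per-class event-duration (barrier-crossing) frame counts."""
    labels = np.asarray(class_of)
    out: dict[int, list[int]] = {}
    for p, c in zip(pathways, labels):
        out.setdefault(int(c), []).append(p.event_duration_frames)
    return out


def _condensed_symbols(p: Pathway, condense_level: int | None) -> tuple[int, ...]:
    if condense_level is None or condense_level < 1:
        return p.symbols
    return condense(p.symbols, condense_level)


def network_edges(
    pathways: Sequence[Pathway],
    class_of=None,
    condense_level: int | None = 2,
) -> dict[int | None, list[tuple[int, int, float]]]:
    """Directed state-transition edges over condensed strings, per class.

    Edge weight is the summed weight of pathways traversing that edge
    (each pathway counted once per distinct edge). When ``class_of`` is
    None all pathways form one group under key ``None``.
    """
    labels = [None] * len(pathways) if class_of is None else list(np.asarray(class_of))
    acc: dict = {}
    for p, c in zip(pathways, labels):
        key = c if c is None else int(c)
        edges = acc.setdefault(key, {})
        syms = _condensed_symbols(p, condense_level)
        for e in {(int(a), int(b)) for a, b in zip(syms[:-1], syms[1:])}:
            edges[e] = edges.get(e, 0.0) + p.weight
    return {
        key: sorted((a, b, w) for (a, b), w in edges.items())
        for key, edges in acc.items()
    }


def network_node_weights(
    pathways: Sequence[Pathway],
    class_of=None,
    condense_level: int | None = 2,
) -> dict[int | None, list[tuple[int, float]]]:
    """Summed pathway weight visiting each state, per class."""
    labels = [None] * len(pathways) if class_of is None else list(np.asarray(class_of))
    acc: dict = {}
    for p, c in zip(pathways, labels):
        key = c if c is None else int(c)
        nodes = acc.setdefault(key, {})
        for s in set(_condensed_symbols(p, condense_level)):
            nodes[int(s)] = nodes.get(int(s), 0.0) + p.weight
    return {key: sorted(nodes.items()) for key, nodes in acc.items()}


@dataclass
class ClassReport:
    """Full classification result for a pathway ensemble."""

    class_of: np.ndarray
    class_prob: dict[int, float]
    durations: dict[int, list[int]]
    edges: dict[int | None, list[tuple[int, int, float]]]
    cut_height: float
    n_classes: int
    warnings_emitted: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.class_prob.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")

    def to_dict(self) -> dict:
        return {
            "cut_height": self.cut_height,
            "n_classes": self.n_classes,
            "class_of": np.asarray(self.class_of).tolist(),
            "class_prob": {str(k): v for k, v in self.class_prob.items()},
            "durations": {str(k): v for k, v in self.durations.items()},
            "edges": {
                ("all" if k is None else str(k)): [list(e) for e in v]
                for k, v in self.edges.items()
            },
            "warnings": self.warnings_emitted,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def edges_to_csv(self, path) -> None:
        rows = [
            {"class": "all" if c is None else c, "from_state": a, "to_state": b, "weight": w}
            for c, edge_list in self.edges.items()
            for a, b, w in edge_list
        ]
        pd.DataFrame(rows, columns=["class", "from_state", "to_state", "weight"]).to_csv(
            path, index=False
        )


def classify_pathways(
    pathways: Sequence[Pathway],
    corrected: bool = True,
    condense_level: int | None = 2,
    metric_hook: Callable | None = None,
    method: str = "lcs",
    cut_height: float | None = None,
    n_classes: int | None = None,
) -> tuple[ClassReport, LinkageTree, DistanceMatrix]:
    """Distance matrix -> Ward tree -> cut -> full class report.

    ``cut_height`` or ``n_classes`` override the max-gap suggestion.
    Workflow guardrails (too few states / pathways / small classes) are
    emitted as warnings and recorded in the report.
    """
    emitted: list[str] = []

    def note(msg: str) -> None:
        emitted.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    n_states = len({s for p in pathways for s in p.symbols})
    if n_states < MIN_STATES:
        note(f"only {n_states} discrete states appear in the ensemble (< {MIN_STATES})")
    if len(pathways) < MIN_PATHWAYS:
        note(f"only {len(pathways)} pathways (< {MIN_PATHWAYS}); statistics may be weak")

    d = pairwise_distances(
        [p.symbols for p in pathways],
        corrected=corrected,
        condense_level=condense_level,
        metric_hook=metric_hook,
        method=method,
    )
    tree = ward_linkage(d)
    if cut_height is None:
        if n_classes is not None:
            cut_height = cut_for_n_classes(tree, n_classes)
        else:
            cut_height, _ = suggest_cut(tree)
    weights = [p.weight for p in pathways]
    class_of = assign_classes(tree, cut_height, weights=weights)
    k = int(class_of.max())
    sizes = {int(c): int((class_of == c).sum()) for c in np.unique(class_of)}
    for c, size in sizes.items():
        if size < MIN_CLASS_SIZE:
            note(f"class {c} contains only {size} pathways (< {MIN_CLASS_SIZE})")

    edges = network_edges(pathways, class_of, condense_level)
    edges[None] = network_edges(pathways, None, condense_level)[None]
    report = ClassReport(
        class_of=class_of,
        class_prob=class_probabilities(pathways, class_of),
        durations=duration_histograms(pathways, class_of),
        edges=edges,
        cut_height=float(cut_height),
        n_classes=k,
        warnings_emitted=emitted,
    )
    return report, tree, d


def plot_summary(report: ClassReport, tree: LinkageTree, out_dir) -> list[str]:
    """Minimal rendered summaries (dendrogram, class/duration histograms).

    Requires matplotlib; returns the written file paths.
    """
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    dendrogram(tree.Z, ax=ax, no_labels=True)
    ax.axhline(report.cut_height, ls="--", c="k")
    ax.set_ylabel("merge height (distance)")
    fig.savefig(out / "dendrogram.png", dpi=120)
    plt.close(fig)
    written.append(str(out / "dendrogram.png"))

    fig, ax = plt.subplots()
    classes = sorted(report.class_prob)
    ax.bar([str(c) for c in classes], [report.class_prob[c] for c in classes])
    ax.set_xlabel("pathway class")
    ax.set_ylabel("probability")
    fig.savefig(out / "class_histogram.png", dpi=120)
    plt.close(fig)
    written.append(str(out / "class_histogram.png"))

    fig, ax = plt.subplots()
    for c in classes:
        ax.hist(report.durations.get(c, []), alpha=0.6, label=f"class {c}")
    ax.set_xlabel("event duration (frames)")
    ax.set_ylabel("count")
    ax.legend()
    fig.savefig(out / "duration_histogram.png", dpi=120)
    plt.close(fig)
    written.append(str(out / "duration_histogram.png"))
    return written
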