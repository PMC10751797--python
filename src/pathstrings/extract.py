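"""Extract successful source->target pathways from labeled trajectories.

A successful pathway runs from the *last* exit of the source state to
the *first* entry of the target state (re-entering the source restarts
the clock; recrossings after first target entry are ignored). The
emitted symbol sequence excludes the source dwell and includes the
single arrival symbol in the target, so at stride 1 the event duration
in frames equals the string length.

Striding samples every ``stride``-th frame of the transition segment,
anchored at the arrival frame (sampling walks backward from the target
entry) so the final symbol is always the target; the strided string has
exactly ceil(L / stride) symbols for a segment of L frames.

Weighted-ensemble (WE) data arrives as a :class:`TrajectoryTree` of
per-iteration segments with parent links and weights; lineages are
flattened before the same scan is applied, and each arriving segment
contributes one pathway carrying its weight at the arrival iteration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discretize import UNASSIGNED, LabelArray
from .similarity import PathString, encode_symbols

__all__ = [
    "Pathway",
    "TrajectoryTree",
    "ShortPathwayWarning",
    "IncompleteDiscretizationError",
    "MalformedTreeError",
    "extract_cmd",
    "trace_lineage",
    "extract_we",
    "pathways_to_json",
    "pathways_from_json",
    "write_pathway_outputs",
]

logger = logging.getLogger(__name__)

#: Pathways shorter than this many frames trigger an alert.
SHORT_PATHWAY_FRAMES = 10
#: Fraction of short pathways that triggers the second, louder alert.
SHORT_PATHWAY_FRACTION = 0.25


class ShortPathwayWarning(UserWarning):
    """Raised (as a warning) when suspiciously short pathways exist."""


class IncompleteDiscretizationError(ValueError):
    """An unassigned (-1) label occurred inside a transition segment."""


class MalformedTreeError(ValueError):
    """A trajectory tree has a broken parent link."""


@dataclass(frozen=True)
class Pathway:
    """One successful source->target transition."""

    symbols: tuple[int, ...]
    weight: float
    start_frame: int
    end_frame: int
    event_duration_frames: int
    origin: tuple = ()

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("a pathway needs at least one symbol")
        if self.weight <= 0:
            raise ValueError("pathway weight must be positive")
        if self.event_duration_frames < 1:
            raise ValueError("event duration must be >= 1 frame")

    @property
    def string(self) -> PathString:
        return PathString(self.symbols)

    @property
    def text(self) -> str:
        return encode_symbols(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


def _coerce_labels(labels) -> np.ndarray:
    if isinstance(labels, LabelArray):
        return labels.labels
    return np.asarray(labels, dtype=np.int64).ravel()


def _scan_transitions(labels: np.ndarray, source_id: int, target_id: int):
    """Yield (first_frame, target_frame) index pairs, last-exit semantics."""
    last_source = None
    for i, lab in enumerate(labels.tolist()):
        if lab == source_id:
            last_source = i
        elif lab == target_id and last_source is not None:
            yield last_source + 1, i
            last_source = None  # first-passage: wait for a fresh source visit


def _stride_indices(n: int, stride: int) -> np.ndarray:
    """Backward-anchored sample indices: always include the last frame."""
    idx = np.arange(n - 1, -1, -stride)[::-1]
    return idx


def _warn_short(pathways: Sequence[Pathway]) -> None:
    if not pathways:
        return
    short = [p for p in pathways if p.event_duration_frames < SHORT_PATHWAY_FRAMES]
    if short:
        warnings.warn(
            f"{len(short)} of {len(pathways)} pathways have fewer than "
            f"{SHORT_PATHWAY_FRAMES} frames: "
            f"{[(p.origin, p.event_duration_frames) for p in short[:20]]}; "
            "consider raising --exclude-length",
            ShortPathwayWarning,
            stacklevel=3,
        )
        if len(short) / len(pathways) > SHORT_PATHWAY_FRACTION:
            warnings.warn(
                f"more than {SHORT_PATHWAY_FRACTION:.0%} of pathways fall below the "
                f"{SHORT_PATHWAY_FRAMES}-frame threshold; a higher exclusion "
                "threshold is recommended",
                ShortPathwayWarning,
                stacklevel=3,
            )


def _build_pathway(
    labels: np.ndarray,
    first: int,
    arrival: int,
    stride: int,
    weight: float,
    origin: tuple,
) -> Pathway:
    seg = labels[first : arrival + 1]
    if np.any(seg == UNASSIGNED):
        bad = first + int(np.argmax(seg == UNASSIGNED))
        raise IncompleteDiscretizationError(
            f"unassigned label at frame {bad} inside a transition; "
            "refine the state map before extraction"
        )
    symbols = tuple(int(x) for x in seg[_stride_indices(seg.size, stride)])
    return Pathway(
        symbols=symbols,
        weight=weight,
        start_frame=int(first),
        end_frame=int(arrival),
        event_duration_frames=int(seg.size),
        origin=origin,
    )


def extract_cmd(
    labels,
    source_id: int,
    target_id: int,
    stride: int = 1,
    exclude_length: int = 0,
    origin_id=0,
) -> list[Pathway]:
    """Extract pathways from one flat (cMD-style) label series.

    Each surviving pathway gets weight 1/n (uniform over the returned
    set). Pathways with fewer than ``exclude_length`` symbols are
    dropped; an alert lists pathways shorter than 10 frames.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if exclude_length < 0:
        raise ValueError(f"exclude_length must be >= 0, got {exclude_length}")
    arr = _coerce_labels(labels)
    raw: list[Pathway] = []
    for first, arrival in _scan_transitions(arr, source_id, target_id):
        raw.append(_build_pathway(arr, first, arrival, stride, 1.0, (origin_id, len(raw))))
    kept = [p for p in raw if len(p) >= exclude_length]
    n = len(kept)
    out = [
        Pathway(
            symbols=p.symbols,
            weight=1.0 / n,
            start_frame=p.start_frame,
            end_frame=p.end_frame,
            event_duration_frames=p.event_duration_frames,
            origin=p.origin,
        )
        for p in kept
    ]
    _warn_short(out)
    return out


@dataclass
class _Segment:
    parent_id: int
    weight: float
    labels: np.ndarray


@dataclass
class TrajectoryTree:
    """Weighted-ensemble segment table with parent links and labels.

    ``segments`` maps iteration (1-based) -> {seg_id -> _Segment}. Every
    segment carries exactly ``tau_frames`` labels; parents live in the
    previous iteration (parent_id -1 marks an initial segment).
    """

    tau_frames: int
    segments: dict[int, dict[int, _Segment]] = field(default_factory=dict)
    sim_id: int = 0

    def add_segment(self, iteration: int, seg_id: int, parent_id: int, weight: float, labels) -> None:
        labels = np.asarray(labels, dtype=np.int64).ravel()
        if labels.size != self.tau_frames:
            raise ValueError(
                f"segment ({iteration}, {seg_id}) has {labels.size} frames, expected {self.tau_frames}"
            )
        if weight <= 0:
            raise ValueError(f"segment ({iteration}, {seg_id}) has non-positive weight")
        self.segments.setdefault(iteration, {})[seg_id] = _Segment(int(parent_id), float(weight), labels)

    @property
    def iterations(self) -> list[int]:
        return sorted(self.segments)

    def validate(self, weight_tol: float = 1e-6) -> None:
        """Check parent links and per-iteration weight conservation."""
        for it in self.iterations:
            for sid, seg in self.segments[it].items():
                if seg.parent_id != -1:
                    prev = self.segments.get(it - 1, {})
                    if seg.parent_id not in prev:
                        raise MalformedTreeError(
                            f"segment ({it}, {sid}) references missing parent "
                            f"({it - 1}, {seg.parent_id})"
                        )
            total = sum(s.weight for s in self.segments[it].values())
            if abs(total - 1.0) > weight_tol:
                warnings.warn(
                    f"iteration {it} weights sum to {total:.8f}, not 1",
                    UserWarning,
                    stacklevel=2,
                )

    # --- I/O ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        cols = [f"frame_{i}" for i in range(self.tau_frames)]
        for it in self.iterations:
            for sid in sorted(self.segments[it]):
                seg = self.segments[it][sid]
                rows.append(
                    {"iteration": it, "seg_id": sid, "parent_id": seg.parent_id, "weight": seg.weight}
                    | dict(zip(cols, seg.labels.tolist()))
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryTree":
        df = pd.read_csv(path)
        frame_cols = sorted(
            (c for c in df.columns if c.startswith("frame_")), key=lambda c: int(c.split("_")[1])
        )
        tree = cls(tau_frames=len(frame_cols))
        for row in df.itertuples(index=False):
            d = row._asdict()
            tree.add_segment(
                int(d["iteration"]),
                int(d["seg_id"]),
                int(d["parent_id"]),
                float(d["weight"]),
                [int(d[c]) for c in frame_cols],
            )
        return tree

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["tau_frames"] = self.tau_frames
            for it in self.iterations:
                grp = fh.create_group(f"iter_{it:06d}")
                sids = sorted(self.segments[it])
                grp.create_dataset("seg_ids", data=np.array(sids, dtype=np.int64))
                grp.create_dataset(
                    "parent_ids", data=np.array([self.segments[it][s].parent_id for s in sids], dtype=np.int64)
                )
                grp.create_dataset(
                    "weights", data=np.array([self.segments[it][s].weight for s in sids], dtype=float)
                )
                grp.create_dataset(
                    "labels", data=np.vstack([self.segments[it][s].labels for s in sids])
                )

    @classmethod
    def from_hdf5(cls, path) -> "TrajectoryTree":
        import h5py

        with h5py.File(path, "r") as fh:
            tree = cls(tau_frames=int(fh.attrs["tau_frames"]))
            for name in sorted(fh):
                it = int(name.split("_")[1])
                grp = fh[name]
                sids = grp["seg_ids"][:]
                parents = grp["parent_ids"][:]
                weights = grp["weights"][:]
                labels = grp["labels"][:]
                for k, sid in enumerate(sids):
                    tree.add_segment(it, int(sid), int(parents[k]), float(weights[k]), labels[k])
        return tree


def trace_lineage(tree: TrajectoryTree, iteration: int, seg_id: int) -> np.ndarray:
    """Concatenated per-frame labels from the root ancestor to this segment."""
    chunks = []
    it, sid = iteration, seg_id
    while True:
        try:
            seg = tree.segments[it][sid]
        except KeyError:
            raise MalformedTreeError(f"segment ({it}, {sid}) not found in tree") from None
        chunks.append(seg.labels)
        if seg.parent_id == -1:
            break
        it, sid = it - 1, seg.parent_id
    return np.concatenate(chunks[::-1])


def extract_we(
    tree: TrajectoryTree,
    source_id: int,
    target_id: int,
    stride: int | None = None,
    exclude_length: int = 0,
) -> list[Pathway]:
    """Extract one pathway per segment whose lineage first reaches the target.

    ``stride`` must divide ``tau_frames``; ``stride=tau_frames`` (the
    default) reproduces per-tau sampling. Sub-tau truncation applies at
    both ends: only frames after the last source exit and up to the
    first target entry enter the string. Pathway weight is the arriving
    segment's weight at its arrival iteration. Segments whose lineage
    starts in the target without a preceding source visit are skipped
    with a logged notice.
    """
    if stride is None:
        stride = tree.tau_frames
    if stride < 1 or tree.tau_frames % stride != 0:
        raise ValueError(
            f"stride ({stride}) must be >= 1 and divide tau_frames ({tree.tau_frames})"
        )
    if exclude_length < 0:
        raise ValueError(f"exclude_length must be >= 0, got {exclude_length}")
    tree.validate()
    raw: list[Pathway] = []
    for it in tree.iterations:
        for sid in sorted(tree.segments[it]):
            lineage = trace_lineage(tree, it, sid)
            block_start = lineage.size - tree.tau_frames
            emitted = 0
            for first, arrival in _scan_transitions(lineage, source_id, target_id):
                if arrival < block_start:
                    continue  # arrival credited to the ancestor segment
                raw.append(
                    _build_pathway(
                        lineage,
                        first,
                        arrival,
                        stride,
                        tree.segments[it][sid].weight,
                        (tree.sim_id, it, sid),
                    )
                )
                emitted += 1
            if emitted == 0:
                hits = np.flatnonzero(lineage[block_start:] == target_id)
                if hits.size and not np.any(
                    lineage[: block_start + int(hits[0])] == source_id
                ):
                    logger.info(
                        "segment (%d, %d) reaches target with no preceding source visit; skipped",
                        it,
                        sid,
                    )
    out = [p for p in raw if len(p) >= exclude_length]
    _warn_short(out)
    return out


# --- pathway I/O ---------------------------------------------------------


def pathways_to_json(pathways: Iterable[Pathway], path) -> None:
    records = [
        {
            "id": i,
            "symbols": list(p.symbols),
            "weight": p.weight,
            "start_frame": p.start_frame,
            "end_frame": p.end_frame,
            "event_duration_frames": p.event_duration_frames,
            "origin": list(p.origin),
        }
        for i, p in enumerate(pathways)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def pathways_from_json(path) -> list[Pathway]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        Pathway(
            symbols=tuple(r["symbols"]),
            weight=r["weight"],
            start_frame=r["start_frame"],
            end_frame=r["end_frame"],
            event_duration_frames=r["event_duration_frames"],
            origin=tuple(r["origin"]),
        )
        for r in records
    ]


def write_pathway_outputs(pathways: Sequence[Pathway], out_dir) -> None:
    """Write pathways.json, strings.txt, and manifest.csv to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathways_to_json(pathways, out / "pathways.json")
    with open(out / "strings.txt", "w") as fh:
        for p in pathways:
            fh.write(p.text + "\n")
    pd.DataFrame(
        {
            "id": range(len(pathways)),
            "weight": [p.weight for p in pathways],
            "event_duration_frames": [p.event_duration_frames for p in pathways],
            "origin": [repr(p.origin) for p in pathways],
        }
    ).to_csv(out / "manifest.csv", index=False)
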