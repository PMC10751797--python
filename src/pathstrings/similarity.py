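"""Pathway strings, condensation, and length-corrected Gestalt similarity.

A pathway is an ordered sequence of small non-negative integer state ids.
For display and text I/O each id is rendered as a single character: ids
0..93 map to the printable ASCII range ``!`` (0x21) through ``~`` (0x7E);
ids >= 94 continue into the Latin-1 supplement and beyond (``chr(0xA1 +
id - 94)``), so per-symbol string operations remain correct for
arbitrarily many states.

The similarity between two pathways A and B is

    uncorrected:  2 * LCS / (L_A + L_B)
    corrected:    2 * LCS / (L_A + L_B - |L_A - L_B| / 2)

where LCS is the length of the longest (not necessarily contiguous)
common subsequence. The corrected form penalises large length
differences so that scores are driven by the shared state sequence
rather than by raw pathway length. A Ratcliff-Obershelp
"matching blocks" numerator is available as an alternative via
``method="matching_blocks"``.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "PathString",
    "SimilarityScore",
    "DistanceMatrix",
    "encode_symbols",
    "decode_text",
    "lcs_length",
    "matching_blocks_length",
    "gestalt_similarity",
    "condense",
    "pairwise_distances",
]

_ASCII_BASE = 0x21  # '!'
_N_ASCII = 94  # printable ASCII '!'..'~'
_EXT_BASE = 0xA1  # Latin-1 supplement onward for ids >= 94


def encode_symbols(symbols: Iterable[int]) -> str:
    """Render a sequence of state ids as a display string (bijective)."""
    chars = []
    for s in symbols:
        s = int(s)
        if s < 0:
            raise ValueError(f"state ids must be non-negative, got {s}")
        if s < _N_ASCII:
            chars.append(chr(_ASCII_BASE + s))
        else:
            chars.append(chr(_EXT_BASE + s - _N_ASCII))
    return "".join(chars)


def decode_text(text: str) -> tuple[int, ...]:
    """Inverse of :func:`encode_symbols`."""
    out = []
    for ch in text:
        cp = ord(ch)
        if _ASCII_BASE <= cp < _ASCII_BASE + _N_ASCII:
            out.append(cp - _ASCII_BASE)
        elif cp >= _EXT_BASE:
            out.append(cp - _EXT_BASE + _N_ASCII)
        else:
            raise ValueError(f"character {ch!r} is outside the display alphabet")
    return tuple(out)


@dataclass(frozen=True)
class PathString:
    """An ordered sequence of state ids representing one pathway."""

    symbols: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(int(s) for s in self.symbols))
        if any(s < 0 for s in self.symbols):
            raise ValueError("state ids must be non-negative")

    @classmethod
    def from_text(cls, text: str) -> "PathString":
        return cls(decode_text(text))

    @property
    def text(self) -> str:
        return encode_symbols(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def _as_symbols(s) -> tuple:
    """Coerce PathString / str / int sequence to a hashable symbol tuple.

    Raw ``str`` input is compared character-by-character, which is
    consistent with the display encoding (a bijection).
    """
    if isinstance(s, PathString):
        return s.symbols
    if isinstance(s, str):
        return tuple(s)
    return tuple(s)


def lcs_length(a, b) -> int:
    """Length of the longest (non-contiguous) common subsequence.

    Classical O(len(a) * len(b)) dynamic program. Total function: empty
    input yields 0.
    """
    sa, sb = _as_symbols(a), _as_symbols(b)
    if not sa or not sb:
        return 0
    prev = [0] * (len(sb) + 1)
    for x in sa:
        curr = [0]
        append = curr.append
        for j, y in enumerate(sb, 1):
            if x == y:
                append(prev[j - 1] + 1)
            else:
                pj = prev[j]
                cj = curr[j - 1]
                append(pj if pj >= cj else cj)
        prev = curr
    return prev[-1]


def matching_blocks_length(a, b) -> int:
    """Total size of Ratcliff-Obershelp matching blocks (difflib).

    Alternative numerator for the similarity score; always <= the true
    LCS length.
    """
    sa, sb = _as_symbols(a), _as_symbols(b)
    sm = difflib.SequenceMatcher(None, sa, sb, autojunk=False)
    return sum(block.size for block in sm.get_matching_blocks())


@dataclass(frozen=True)
class SimilarityScore:
    """Similarity of one pathway pair, with its numerator bookkeeping."""

    value: float
    lcs_length: int
    corrected: bool

    def __float__(self) -> float:
        return self.value


_NUMERATORS: dict[str, Callable] = {
    "lcs": lcs_length,
    "matching_blocks": matching_blocks_length,
}


def gestalt_similarity(a, b, corrected: bool = True, method: str = "lcs") -> SimilarityScore:
    """Score a pathway pair in [0, 1]; 1 exactly for identical strings.

    Parameters
    ----------
    a, b
        Pathways as :class:`PathString`, display text, or int sequences.
    corrected
        If True, subtract half the length difference from the combined
        length in the denominator (the length penalty).
    method
        ``"lcs"`` (default) or ``"matching_blocks"``.
    """
    sa, sb = _as_symbols(a), _as_symbols(b)
    if not sa and not sb:
        raise ValueError("cannot score a pair of empty pathways")
    try:
        numerator_fn = _NUMERATORS[method]
    except KeyError:
        raise ValueError(f"unknown similarity method {method!r}") from None
    common = numerator_fn(sa, sb)
    la, lb = len(sa), len(sb)
    denom = la + lb
    if corrected:
        denom -= abs(la - lb) / 2.0
    return SimilarityScore(value=2.0 * common / denom, lcs_length=common, corrected=corrected)


def _collapse_block_size(seq: list, k: int) -> bool:
    """One full left-to-right pass collapsing immediate k-block repeats.

    After each collapse the scan stays at the collapse position so newly
    adjacent repeats are caught. Returns True if anything changed.
    """
    changed = False
    i = 0
    while i + 2 * k <= len(seq):
        if seq[i : i + k] == seq[i + k : i + 2 * k]:
            del seq[i + k : i + 2 * k]
            changed = True
        else:
            i += 1
    return changed


def condense(s, max_block: int):
    """Collapse immediate repetitions of blocks of size 1..max_block.

    Block sizes are processed smallest-first, each to a fixed point; the
    sweep over block sizes repeats until the whole result is stable, so
    the output is a fixed point of the operation. The return type
    mirrors the input (str -> str, PathString -> PathString, otherwise a
    tuple of ints).
    """
    if max_block < 1:
        raise ValueError(f"max_block must be >= 1, got {max_block}")
    seq = list(_as_symbols(s))
    dirty = True
    while dirty:
        dirty = False
        for k in range(1, max_block + 1):
            while _collapse_block_size(seq, k):
                dirty = True
    if isinstance(s, str):
        return "".join(seq)
    if isinstance(s, PathString):
        return PathString(tuple(seq))
    return tuple(seq)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise pathway distances d = 1 - similarity."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Condensed (upper-triangle) form for scipy linkage."""
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)

    def to_npy(self, path) -> None:
        np.save(path, self.values)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.17g")

    @classmethod
    def from_npy(cls, path) -> "DistanceMatrix":
        return cls(np.load(path))

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2))


def pairwise_distances(
    pathways: Sequence,
    corrected: bool = True,
    condense_level: int | None = None,
    metric_hook: Callable | None = None,
    method: str = "lcs",
) -> DistanceMatrix:
    """Build the full pairwise distance matrix (1 - similarity).

    ``condense_level`` (if given) is applied to every string before
    scoring; it affects matching only. ``metric_hook`` replaces the
    built-in score: it receives two symbol tuples and must return a
    similarity in [0, 1]; a value outside that range is a contract
    violation.
    """
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways for a distance matrix")
    strings = [_as_symbols(p) for p in pathways]
    if condense_level is not None and condense_level >= 1:
        strings = [condense(s, condense_level) for s in strings]
    n = len(strings)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if metric_hook is not None:
                sim = float(metric_hook(strings[i], strings[j]))
                if not (0.0 <= sim <= 1.0):
                    raise ValueError(
                        f"metric hook returned {sim!r} for pair ({i}, {j}); "
                        "similarity must lie in [0, 1]"
                    )
            else:
                sim = gestalt_similarity(strings[i], strings[j], corrected=corrected, method=method).value
            d[i, j] = d[j, i] = 1.0 - sim
    # identical strings can leave tiny negative residue from float ops
    np.clip(d, 0.0, 1.0, out=d)
    return DistanceMatrix(d)
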