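"""Pairwise sequence distances over aligned sequences.

Two metrics are provided:

* ``p`` — the uncorrected p-distance: the fraction of differing sites among
  comparable columns.
* ``blastn`` — a score-based distance on the classic blastn scoring scheme
  (match +5, mismatch -4), ``1 - S / S_max`` with ``S_max = 5 * L`` the score
  of a perfect match over the comparable columns, clamped to [0, 1].  This is
  the metric used by the barcode neighbor skim.

Both metrics use pairwise deletion: a column is comparable only when *both*
sequences carry an unambiguous A/C/G/T there.  Gaps and IUPAC ambiguity codes
(N, R, Y, ...) are treated as missing data so that low-quality capture
sequence does not inflate distances.  Case is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DistanceMatrix, GeneAlignment

__all__ = [
    "UndefinedDistanceError",
    "PairwiseScoreScheme",
    "p_distance",
    "blastn_distance",
    "alignment_distance_matrix",
]


class UndefinedDistanceError(ValueError):
    """Raised when a sequence pair shares no comparable (A/C/G/T) column."""


@dataclass(frozen=True)
class PairwiseScoreScheme:
    """Blastn-style match/mismatch scores; gap/ambiguity columns are skipped."""

    match_score: float = 5.0
    mismatch_score: float = -4.0

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("require match_score > 0 > mismatch_score")


DEFAULT_SCHEME = PairwiseScoreScheme()

# ASCII -> base code; 0..3 for ACGT, 255 otherwise
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (0..3 = ACGT, 255 = missing)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    comparable = (a != 255) & (b != 255)
    n = int(comparable.sum())
    if n == 0:
        return 0, 0
    diffs = int((a[comparable] != b[comparable]).sum())
    return n, diffs


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance with pairwise deletion; in [0, 1]."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    n, diffs = _pair_counts(encode(a), encode(b))
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    return diffs / n


def blastn_distance(a: str, b: str, scheme: PairwiseScoreScheme = DEFAULT_SCHEME) -> float:
    """Score distance ``1 - S/S_max`` under blastn scores, clamped to [0, 1]."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    n, diffs = _pair_counts(encode(a), encode(b))
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    matches = n - diffs
    score = scheme.match_score * matches + scheme.mismatch_score * diffs
    dist = 1.0 - score / (scheme.match_score * n)
    return float(min(1.0, max(0.0, dist)))


def alignment_distance_matrix(
    aln: GeneAlignment,
    metric: str = "p",
    scheme: PairwiseScoreScheme = DEFAULT_SCHEME,
) -> DistanceMatrix:
    """Full pairwise distance matrix over the rows of an alignment.

    Raises :class:`UndefinedDistanceError` listing every offending pair if any
    pair has no comparable column.
    """
    if metric not in ("p", "blastn"):
        raise ValueError(f"unknown metric {metric!r}")
    if aln.n_rows < 2:
        raise ValueError("need >= 2 rows for a distance matrix")
    labels = aln.sample_ids
    codes = _CODE[aln.to_byte_matrix()]
    n = len(labels)
    values = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            comp, diffs = _pair_counts(codes[i], codes[j])
            if comp == 0:
                undefined.append((labels[i], labels[j]))
                continue
            if metric == "p":
                d = diffs / comp
            else:
                matches = comp - diffs
                score = scheme.match_score * matches + scheme.mismatch_score * diffs
                d = min(1.0, max(0.0, 1.0 - score / (scheme.match_score * comp)))
            values[i, j] = values[j, i] = d
    if undefined:
        raise UndefinedDistanceError(
            f"no comparable columns for pairs: {undefined[:10]}"
            + (" ..." if len(undefined) > 10 else "")
        )
    return DistanceMatrix(labels, values)
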