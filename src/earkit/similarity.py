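"""Pairwise global percent identity between peptide motifs.

Identity is computed from a Needleman-Wunsch global alignment with match
+1, mismatch -1, gap -1 and no free end gaps; percent identity is the
number of identical aligned columns divided by the alignment length
(gap columns included) times 100. Because co-optimal alignments can differ
in their identical-column count, the dynamic programme tracks, among all
optimal-score alignments, the maximum number of identities and, among
those, the minimum alignment length — making the reported identity a
deterministic, well-defined quantity rather than an artifact of traceback
order.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .datatypes import IdentityMatrix, ParameterError

MATCH = 1
MISMATCH = -1
GAP = -1


def _align_stats(a: str, b: str) -> tuple[int, int, int]:
    """(optimal score, max identities at that score, min alignment length
    among those)."""
    la, lb = len(a), len(b)
    # per cell: (score, identities, -length), maximised lexicographically
    prev = [(j * GAP, 0, -j) for j in range(lb + 1)]
    for i in range(1, la + 1):
        ai = a[i - 1]
        cur = [(i * GAP, 0, -i)]
        for j in range(1, lb + 1):
            ps, pi, pl = prev[j - 1]
            diag_match = ai == b[j - 1]
            diag = (ps + (MATCH if diag_match else MISMATCH),
                    pi + (1 if diag_match else 0), pl - 1)
            us, ui, ul = prev[j]
            up = (us + GAP, ui, ul - 1)
            ls_, li, ll = cur[j - 1]
            left = (ls_ + GAP, li, ll - 1)
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur.append(best)
        prev = cur
    score, ident, neg_len = prev[lb]
    return score, ident, -neg_len


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``."""
    if not a or not b:
        raise ParameterError("sequences must be non-empty")
    _, ident, length = _align_stats(a, b)
    return 100.0 * ident / length


def identity_matrix(sequences: Sequence[str], ids: Sequence[str] | None = None
                    ) -> IdentityMatrix:
    """Symmetric percent-identity matrix over a list of sequences."""
    n = len(sequences)
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(n)]
    if len(ids) != n:
        raise ParameterError("ids and sequences must have equal length")
    mat = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = global_identity(sequences[i], sequences[j])
    return IdentityMatrix(ids=list(ids), identity=mat)


def max_pairwise_identity(
    sequences: Sequence[str], ids: Sequence[str] | None = None
) -> tuple[float, tuple[str, str]]:
    """Maximum off-diagonal identity and the pair achieving it.

    Ties are broken toward the first pair in id order; duplicated
    sequences legitimately return 100.
    """
    if len(sequences) < 2:
        raise ParameterError("need at least 2 sequences")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(sequences))]
    best = -1.0
    best_pair = (ids[0], ids[1])
    for i, j in itertools.combinations(range(len(sequences)), 2):
        v = global_identity(sequences[i], sequences[j])
        if v > best:
            best = v
            best_pair = (ids[i], ids[j])
    return best, best_pair
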