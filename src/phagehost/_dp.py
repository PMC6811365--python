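"""Dynamic-programming alignment kernels (numba-compiled).

Two kernels live here:

* an affine-gap global (Needleman-Wunsch/Gotoh) aligner over BLOSUM62 used
  for protein identity, with a fixed, documented tie-break so results are
  bit-reproducible: on equal scores substitution beats a gap in the second
  sequence, which beats a gap in the first; a gap of length k costs
  open + k * extend (BLAST convention, default 11 + k);
* a semi-global profile-profile aligner over a precomputed column-score
  matrix (free end gaps on both profiles), used for subfamily comparison.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "AA_ORDER",
    "BLOSUM62",
    "encode_protein",
    "global_identity",
    "profile_align",
]

_B62 = substitution_matrices.load("BLOSUM62")
AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

BLOSUM62 = np.zeros((len(AA_ORDER), len(AA_ORDER)), dtype=np.int64)
for _i, _a in enumerate(AA_ORDER):
    for _j, _b in enumerate(AA_ORDER):
        BLOSUM62[_i, _j] = int(_B62[_a, _b])


def encode_protein(seq: str) -> np.ndarray:
    """Map residues to BLOSUM row indices (unknowns -> X)."""
    x = _AA_INDEX["X"]
    return np.array([_AA_INDEX.get(a, x) for a in seq.upper()], dtype=np.int64)


NEG = -(10 ** 9)


@njit(cache=True)
def _gotoh(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consumes b)
    open_cost = gap_open + gap_extend
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - i * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + s
            x1 = M[i - 1, j] - open_cost
            x2 = Ix[i - 1, j] - gap_extend
            Ix[i, j] = x1 if x1 >= x2 else x2
            y1 = M[i, j - 1] - open_cost
            y2 = Iy[i, j - 1] - gap_extend
            Iy[i, j] = y1 if y1 >= y2 else y2
    return M, Ix, Iy


@njit(cache=True)
def _traceback_identity(a, b, sub, M, Ix, Iy, gap_open, gap_extend
                        ):  # pragma: no cover - jitted
    i, j = len(a), len(b)
    open_cost = gap_open + gap_extend
    # state preference on ties: M > Ix > Iy
    state = 0
    best = M[i, j]
    if Ix[i, j] > best:
        state, best = 1, Ix[i, j]
    if Iy[i, j] > best:
        state, best = 2, Iy[i, j]
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                # only possible at origin
                break
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = M[i, j] - sub[a[i - 1], b[j - 1]]
            if M[i - 1, j - 1] == prev:
                state = 0
            elif Ix[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            columns += 1
            if M[i - 1, j] - open_cost == Ix[i, j]:
                state = 0
            i -= 1
        else:
            columns += 1
            if M[i, j - 1] - open_cost == Iy[i, j]:
                state = 0
            j -= 1
    return matches, columns, best


def global_identity(seq1: str, seq2: str, gap_open: int = 11,
                    gap_extend: int = 1) -> tuple[float, int]:
    """Global-alignment identity and optimal score.

    Identity = identical columns / alignment length; gap columns count in
    the denominator. Raises on empty input.
    """
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    if seq1 == seq2:
        return 1.0, int(BLOSUM62[encode_protein(seq1), encode_protein(seq1)].sum())
    a, b = encode_protein(seq1), encode_protein(seq2)
    M, Ix, Iy = _gotoh(a, b, BLOSUM62, gap_open, gap_extend)
    matches, columns, score = _traceback_identity(
        a, b, BLOSUM62, M, Ix, Iy, gap_open, gap_extend
    )
    return matches / columns, int(score)


@njit(cache=True)
def profile_align(S, gap):  # pragma: no cover - jitted
    """Semi-global DP over a column-score matrix S (free end gaps).

    Returns (score, i_start, i_end, j_start, j_end): the aligned spans on
    each profile (half-open, 0-based). Linear gap penalty ``gap`` > 0.
    """
    n, m = S.shape
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    # free leading gaps: first row/col stay 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            u = H[i - 1, j] - gap
            l = H[i, j - 1] - gap
            v = d
            if u > v:
                v = u
            if l > v:
                v = l
            H[i, j] = v
    # best end on last row or column (free trailing gaps)
    bi, bj, best = n, m, H[n, m]
    for i in range(n + 1):
        if H[i, m] > best:
            bi, bj, best = i, m, H[i, m]
    for j in range(m + 1):
        if H[n, j] > best:
            bi, bj, best = n, j, H[n, j]
    # traceback to recover spans
    i, j = bi, bj
    while i > 0 and j > 0:
        d = H[i - 1, j - 1] + S[i - 1, j - 1]
        u = H[i - 1, j] - gap
        if H[i, j] == d:
            i -= 1
            j -= 1
        elif H[i, j] == u:
            i -= 1
        else:
            j -= 1
        if H[i, j] == 0.0 and (i == 0 or j == 0):
            break
    return best, i, bi, j, bj
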