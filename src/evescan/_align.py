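"""Local alignment kernels.

Three dynamic programs back the whole package:

* :func:`sw_matrix` — affine-gap local (Smith–Waterman) alignment over a
  pre-scored column×column matrix; serves pairwise protein, pairwise
  nucleotide and profile-vs-sequence alignment.
* :func:`fs_align` — frameshift-aware translated alignment of a nucleotide
  sequence against a protein: codon matches advance 3 nt, a frame change
  advances 2 or 4 nt and costs a fixed per-event penalty, so a single local
  alignment can bridge single-base assembly artefacts.

Gap cost convention throughout: a gap of length k costs
``gap_open + k * gap_extend`` (BLAST-style).

E-values use Karlin–Altschul statistics with the standard gapped BLOSUM62
(11/1) constants; they are internally consistent (monotone in score) but not
numerically identical to any particular search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_AA_CODE = np.full(256, AA_INDEX["X"], dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _AA_CODE[ord(_aa)] = _i
    _AA_CODE[ord(_aa.lower())] = _i


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein string into BLOSUM62 row indices (unknown -> X)."""
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _load_blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    assert str(m.alphabet) == AA_ALPHABET
    return np.asarray(m, dtype=np.float32)


BLOSUM62 = _load_blosum62()

# Karlin-Altschul constants for gapped BLOSUM62 with 11/1 gap costs
KA_LAMBDA = 0.267
KA_K = 0.041

# default gap costs: protein (BLOSUM62 11/1) and nucleotide (+2/-3, 5/2)
PROT_GAP_OPEN, PROT_GAP_EXTEND = 11.0, 1.0
NT_MATCH, NT_MISMATCH = 2.0, -3.0
NT_GAP_OPEN, NT_GAP_EXTEND = 5.0, 2.0


def bit_score(raw: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def evalue(raw: float, query_len: int, db_len: int,
           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Expected number of chance alignments scoring >= raw."""
    return k * query_len * db_len * math.exp(-lam * raw)


@dataclass
class LocalAlignment:
    """Result of a local alignment in 0-based half-open coordinates.

    ``a_cols``/``b_cols`` hold, per alignment column, the index in the
    respective sequence or -1 for a gap.
    """

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_cols: np.ndarray
    b_cols: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.a_cols)

    def identity(self, a_codes: np.ndarray, b_codes: np.ndarray) -> float:
        """Fraction of matching residues over aligned (non-gap) columns."""
        mask = (self.a_cols >= 0) & (self.b_cols >= 0)
        if not mask.any():
            return 0.0
        return float(np.mean(a_codes[self.a_cols[mask]] ==
                             b_codes[self.b_cols[mask]]))


# ---------------------------------------------------------------------------
# Generic affine-gap Smith-Waterman over a prescored matrix
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_fill(S, gap_open, gap_extend, ptr):  # pragma: no cover - numba
    n, m = S.shape
    NEG = -1.0e30
    h_prev = np.zeros(m + 1, dtype=np.float64)
    h_cur = np.zeros(m + 1, dtype=np.float64)
    f_col = np.full(m + 1, NEG, dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0.0
        for j in range(1, m + 1):
            p = 0
            # E: gap in A (consume B), horizontal
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_open >= e_ext:
                e = e_open
                p |= 4
            else:
                e = e_ext
            # F: gap in B (consume A), vertical
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_col[j] - gap_extend
            if f_open >= f_ext:
                f_col[j] = f_open
                p |= 8
            else:
                f_col[j] = f_ext
            diag = h_prev[j - 1] + S[i - 1, j - 1]
            h = 0.0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f_col[j] > h:
                h = f_col[j]
                src = 3
            h_cur[j] = h
            ptr[i, j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj


@njit(cache=True)
def _sw_traceback(ptr, bi, bj):  # pragma: no cover - numba
    max_len = bi + bj
    a_cols = np.empty(max_len, dtype=np.int64)
    b_cols = np.empty(max_len, dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                a_cols[k] = i - 1
                b_cols[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E: gap in A, consumed B char
            a_cols[k] = -1
            b_cols[k] = j - 1
            k += 1
            opened = (p & 4) != 0
            j -= 1
            if opened:
                state = 0
        else:  # F: gap in B, consumed A char
            a_cols[k] = i - 1
            b_cols[k] = -1
            k += 1
            opened = (p & 8) != 0
            i -= 1
            if opened:
                state = 0
    return a_cols[:k][::-1].copy(), b_cols[:k][::-1].copy(), i, j


@njit(cache=True)
def _sw_nt_fill(a, b, match, mismatch, gap_open, gap_extend, ptr):  # pragma: no cover
    # int32 DP; scores computed inline: match/mismatch, any N (code 4)
    # scores 0, masking sentinels (codes > 4) always mismatch
    n = len(a)
    m = len(b)
    NEG = np.int32(-(2 ** 28))
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f_col = np.full(m + 1, NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            p = 0
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_open >= e_ext:
                e = e_open
                p |= 4
            else:
                e = e_ext
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_col[j] - gap_extend
            if f_open >= f_ext:
                f_col[j] = f_open
                p |= 8
            else:
                f_col[j] = f_ext
            bj_code = b[j - 1]
            if ai == 4 or bj_code == 4:
                s = 0
            elif ai == bj_code and ai < 4:
                s = match
            else:
                s = mismatch
            diag = h_prev[j - 1] + s
            h = 0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f_col[j] > h:
                h = f_col[j]
                src = 3
            h_cur[j] = h
            ptr[i, j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj


def sw_nt(a_codes: np.ndarray, b_codes: np.ndarray,
          match: float = NT_MATCH, mismatch: float = NT_MISMATCH,
          gap_open: float = NT_GAP_OPEN, gap_extend: float = NT_GAP_EXTEND
          ) -> LocalAlignment | None:
    """Nucleotide local alignment without materialising a score matrix."""
    n, m = len(a_codes), len(b_codes)
    if n == 0 or m == 0:
        return None
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    score, bi, bj = _sw_nt_fill(a_codes, b_codes, int(round(match)),
                                int(round(mismatch)), int(round(gap_open)),
                                int(round(gap_extend)), ptr)
    if score <= 0.0:
        return None
    a_cols, b_cols, i0, j0 = _sw_traceback(ptr, bi, bj)
    return LocalAlignment(float(score), int(i0), int(bi), int(j0), int(bj),
                          a_cols, b_cols)


def sw_matrix(S: np.ndarray, gap_open: float, gap_extend: float
              ) -> LocalAlignment | None:
    """Best local alignment over prescored matrix S (shape len(a) x len(b))."""
    n, m = S.shape
    if n == 0 or m == 0:
        return None
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    score, bi, bj = _sw_fill(np.ascontiguousarray(S, dtype=np.float64),
                             float(gap_open), float(gap_extend), ptr)
    if score <= 0.0:
        return None
    a_cols, b_cols, i0, j0 = _sw_traceback(ptr, bi, bj)
    return LocalAlignment(float(score), int(i0), int(bi), int(j0), int(bj),
                          a_cols, b_cols)


def score_matrix_protein(a_codes: np.ndarray, b_codes: np.ndarray,
                         submat: np.ndarray = BLOSUM62) -> np.ndarray:
    return submat[np.ix_(a_codes, b_codes)]


def score_matrix_nt(a_codes: np.ndarray, b_codes: np.ndarray,
                    match: float = NT_MATCH, mismatch: float = NT_MISMATCH
                    ) -> np.ndarray:
    """Nucleotide scores; any comparison involving N scores 0."""
    S = np.where(a_codes[:, None] == b_codes[None, :], match, mismatch)
    S[a_codes == 4, :] = 0.0
    S[:, b_codes == 4] = 0.0
    return S.astype(np.float64)


def align_protein(a: str | np.ndarray, b: str | np.ndarray,
                  gap_open: float = PROT_GAP_OPEN,
                  gap_extend: float = PROT_GAP_EXTEND) -> LocalAlignment | None:
    a_codes = encode_aa(a) if isinstance(a, str) else a
    b_codes = encode_aa(b) if isinstance(b, str) else b
    return sw_matrix(score_matrix_protein(a_codes, b_codes), gap_open, gap_extend)


def align_nt(a: str | np.ndarray, b: str | np.ndarray,
             match: float = NT_MATCH, mismatch: float = NT_MISMATCH,
             gap_open: float = NT_GAP_OPEN,
             gap_extend: float = NT_GAP_EXTEND) -> LocalAlignment | None:
    from .seqio import encode_nt
    a_codes = encode_nt(a) if isinstance(a, str) else a
    b_codes = encode_nt(b) if isinstance(b, str) else b
    return sw_nt(a_codes, b_codes, match, mismatch, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Frameshift-aware translated alignment
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fs_fill(P, gap_open, gap_extend, fs_penalty, ptr):  # pragma: no cover
    # P[i, j] = substitution score of the codon starting at nt i vs query aa j
    nc, m = P.shape       # nc = n_nt - 2 codon start positions
    n = nc + 2
    NEG = np.int32(-(2 ** 28))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full(m + 1, NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        E[:] = NEG
        for j in range(1, m + 1):
            p = 0
            # E: insertion in protein (consume aa only)
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[j - 1] - gap_extend
            if e_open >= e_ext:
                E[j] = e_open
                p |= 8
            else:
                E[j] = e_ext
            # F: deletion of a codon (consume 3 nt)
            if i >= 3:
                f_open = H[i - 3, j] - gap_open - gap_extend
                f_ext = F[i - 3, j] - gap_extend
                if f_open >= f_ext:
                    F[i, j] = f_open
                    p |= 16
                else:
                    F[i, j] = f_ext
            h = np.int32(0)
            src = 0
            if i >= 3:
                sub = P[i - 3, j - 1]
                diag = H[i - 3, j - 1] + sub
                if diag > h:
                    h = diag
                    src = 1
                f2 = H[i - 2, j - 1] + sub - fs_penalty
                if f2 > h:
                    h = f2
                    src = 2
                if i >= 4:
                    f4 = H[i - 4, j - 1] + sub - fs_penalty
                    if f4 > h:
                        h = f4
                        src = 3
            if E[j] > h:
                h = E[j]
                src = 4
            if F[i, j] > h:
                h = F[i, j]
                src = 5
            H[i, j] = h
            ptr[i, j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _fs_traceback(ptr, bi, bj):  # pragma: no cover - numba
    # returns per-column codon start (or -1) and query index (or -1),
    # plus number of frameshift events and alignment start coordinates
    max_len = bi + bj
    nt_cols = np.empty(max_len, dtype=np.int64)
    q_cols = np.empty(max_len, dtype=np.int64)
    k = 0
    n_fs = 0
    i, j = bi, bj
    state = 0  # 0 H, 1 E, 2 F
    while i > 0 or j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 7
            if src == 0:
                break
            if src == 1 or src == 2 or src == 3:
                nt_cols[k] = i - 3
                q_cols[k] = j - 1
                k += 1
                j -= 1
                if src == 1:
                    i -= 3
                elif src == 2:
                    i -= 2
                    n_fs += 1
                else:
                    i -= 4
                    n_fs += 1
            elif src == 4:
                state = 1
            else:
                state = 2
        elif state == 1:
            nt_cols[k] = -1
            q_cols[k] = j - 1
            k += 1
            opened = (p & 8) != 0
            j -= 1
            if opened:
                state = 0
        else:
            nt_cols[k] = i - 3
            q_cols[k] = -1
            k += 1
            opened = (p & 16) != 0
            i -= 3
            if opened:
                state = 0
    return nt_cols[:k][::-1].copy(), q_cols[:k][::-1].copy(), i, j, n_fs


@dataclass
class FrameshiftAlignment:
    """A translated local alignment that may cross frame boundaries.

    ``nt_start``/``nt_end`` delimit the consumed nucleotide span (0-based
    half-open); ``codon_starts`` holds the codon start of every alignment
    column (-1 where a protein residue aligns to a gap).
    """

    score: float
    nt_start: int
    nt_end: int
    q_start: int
    q_end: int
    n_frameshifts: int
    codon_starts: np.ndarray
    q_cols: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.q_cols)

    def identity(self, aa_at: np.ndarray, q_codes: np.ndarray) -> float:
        mask = (self.codon_starts >= 0) & (self.q_cols >= 0)
        if not mask.any():
            return 0.0
        return float(np.mean(aa_at[self.codon_starts[mask]] ==
                             q_codes[self.q_cols[mask]]))


def translate_codons(nt_codes: np.ndarray, table_lut: np.ndarray) -> np.ndarray:
    """AA code of the codon starting at every nt position (len n-2)."""
    n = len(nt_codes)
    if n < 3:
        return np.empty(0, dtype=np.uint8)
    c = nt_codes.astype(np.int32)
    idx = c[:-2] * 25 + c[1:-1] * 5 + c[2:]
    return _AA_CODE[table_lut[idx]]


def fs_align(nt_codes: np.ndarray, q_codes: np.ndarray, table_lut: np.ndarray,
             gap_open: float = PROT_GAP_OPEN, gap_extend: float = PROT_GAP_EXTEND,
             fs_penalty: float = 15.0, submat: np.ndarray = BLOSUM62
             ) -> FrameshiftAlignment | None:
    """Best frameshift-aware local alignment of a nt sequence vs a protein."""
    aa_at = translate_codons(nt_codes, table_lut)
    if len(aa_at) == 0 or len(q_codes) == 0:
        return None
    P = np.rint(submat[np.ix_(aa_at, q_codes)]).astype(np.int32)
    n = len(nt_codes)
    m = len(q_codes)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    score, bi, bj = _fs_fill(np.ascontiguousarray(P), int(round(gap_open)),
                             int(round(gap_extend)), int(round(fs_penalty)), ptr)
    if score <= 0.0:
        return None
    nt_cols, q_cols, i0, j0, n_fs = _fs_traceback(ptr, bi, bj)
    return FrameshiftAlignment(float(score), int(i0), int(bi), int(j0), int(bj),
                               int(n_fs), nt_cols, q_cols)


def mask_region(codes: np.ndarray, start: int, end: int,
                sentinel: int) -> np.ndarray:
    out = codes.copy()
    out[start:end] = sentinel
    return out
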