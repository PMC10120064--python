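"""Terminal inverted repeat (TIR) detection.

A TIR pair is a region near one end of a sequence whose reverse complement
recurs near the other end — the hallmark of an integrated mobile element.
Detection aligns the sequence against its own reverse complement and keeps
self-symmetric, non-overlapping, near-end local matches; the trivial
self-palindromic diagonal (a region matching its own reverse complement in
place) is excluded by requiring the two copies to be disjoint and ordered.

Small search windows are aligned exhaustively; genome- or locus-scale
searches (``end_window=None``) go through an exact-k-mer seeding stage and
run the same exact alignment on candidate windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._align import (NT_GAP_EXTEND, NT_GAP_OPEN, NT_MATCH, NT_MISMATCH,
                     LocalAlignment, align_nt, sw_nt)
from .seqio import encode_nt

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 20
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_END_WINDOW = 5000
DEFAULT_MAX_PAIRS = 3
DEFAULT_MAX_EVALUE = 0.01
# ungapped Karlin-Altschul constants for +2/-3 at equal base frequencies
_NT_LAMBDA = 0.63
_NT_K = 0.1
_SEED_K = 12
_SEED_PAD = 500
_FULL_SW_MAX_CELLS = 30_000_000


@dataclass(frozen=True)
class TirPair:
    """An inverted repeat pair in 0-based half-open sequence coordinates."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    repeat_length: int
    pct_identity: float
    score: float

    def __post_init__(self):
        assert self.left_end <= self.right_start, "TIR copies must be ordered"

    @property
    def left(self) -> tuple[int, int]:
        return (self.left_start, self.left_end)

    @property
    def right(self) -> tuple[int, int]:
        return (self.right_start, self.right_end)

    def shifted(self, offset: int) -> "TirPair":
        return TirPair(self.left_start + offset, self.left_end + offset,
                       self.right_start + offset, self.right_end + offset,
                       self.repeat_length, self.pct_identity, self.score)


def _pair_from_alignment(aln: LocalAlignment, n: int, a_codes: np.ndarray,
                         b_codes: np.ndarray, b_offset: int,
                         a_offset: int = 0) -> TirPair | None:
    """Map an A-vs-revcomp alignment back to a candidate sequence pair.

    ``b_codes`` indexes into revcomp(seq); revcomp position t corresponds to
    sequence position n-1-t.
    """
    left = (aln.a_start + a_offset, aln.a_end + a_offset)
    b0, b1 = aln.b_start + b_offset, aln.b_end + b_offset
    right = (n - b1, n - b0)
    if left[1] > right[0]:
        return None
    ident = aln.identity(a_codes, b_codes)
    rep_len = min(left[1] - left[0], right[1] - right[0])
    return TirPair(left[0], left[1], right[0], right[1], rep_len,
                   100.0 * ident, aln.score)


def _mask(codes: np.ndarray, start: int, end: int, value: int) -> np.ndarray:
    out = codes.copy()
    out[start:end] = value
    return out


def _full_sw_pairs(a: np.ndarray, b: np.ndarray, n: int, b_offset: int,
                   min_len: int, min_identity: float, max_pairs: int,
                   score_min: float, a_offset: int = 0) -> list[TirPair]:
    """Exhaustive alignment with masking; distinct codes mask A and B."""
    pairs = []
    a_work, b_work = a, b
    # weakest admissible pair: min_len columns at exactly min_identity,
    # or the significance floor, whichever is higher
    floor = max(score_min,
                min_len * (NT_MATCH * min_identity
                           + NT_MISMATCH * (1.0 - min_identity)))
    for _ in range(max_pairs + 3):
        if len(pairs) >= max_pairs:
            break
        aln = sw_nt(a_work, b_work)
        if aln is None or aln.score < floor:
            break
        pair = _pair_from_alignment(aln, n, a_work, b_work, b_offset, a_offset)
        a_work = _mask(a_work, aln.a_start, aln.a_end, 5)
        b_work = _mask(b_work, aln.b_start, aln.b_end, 6)
        if pair is None:
            continue
        if (pair.repeat_length >= min_len
                and pair.pct_identity >= 100.0 * min_identity):
            pairs.append(pair)
    return pairs


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for off in range(k):
        out = out * 5 + codes[off:off + n]
    return out


def _seeded_pairs(codes: np.ndarray, rc: np.ndarray, n: int, min_len: int,
                  min_identity: float, max_pairs: int,
                  score_min: float) -> list[TirPair]:
    ka = _kmer_codes(codes, _SEED_K)
    kb = _kmer_codes(rc, _SEED_K)
    order = np.argsort(kb, kind="stable")
    kb_sorted = kb[order]
    lo = np.searchsorted(kb_sorted, ka, side="left")
    hi = np.searchsorted(kb_sorted, ka, side="right")
    seeds = []
    for i in np.nonzero(hi > lo)[0]:
        for t in order[lo[i]:hi[i]]:
            j_start = n - int(t) - _SEED_K  # seq coordinate of the partner
            if abs(int(i) - j_start) <= _SEED_K:
                continue  # self-palindromic diagonal
            if int(i) > j_start:
                continue  # keep the left-copy representative only
            seeds.append((int(i) - int(t), int(i), int(t)))
    if not seeds:
        return []
    # cluster seeds on the (i - t) diagonal
    seeds.sort()
    clusters: list[list[tuple[int, int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        d_prev, i_prev, _ = clusters[-1][-1]
        if s[0] - d_prev <= 30 and abs(s[1] - i_prev) <= 400:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    candidates: list[TirPair] = []
    for cl in clusters:
        i_min = min(s[1] for s in cl)
        i_max = max(s[1] for s in cl) + _SEED_K
        t_min = min(s[2] for s in cl)
        t_max = max(s[2] for s in cl) + _SEED_K
        a0 = max(0, i_min - _SEED_PAD)
        a1 = min(n, i_max + _SEED_PAD)
        b0 = max(0, t_min - _SEED_PAD)
        b1 = min(n, t_max + _SEED_PAD)
        candidates.extend(_full_sw_pairs(
            codes[a0:a1], rc[b0:b1], n, b0, min_len, min_identity,
            max_pairs=2, score_min=score_min, a_offset=a0))
    return candidates


def find_tirs(seq: str, min_len: int = DEFAULT_MIN_LEN,
              min_identity: float = DEFAULT_MIN_IDENTITY,
              end_window: int | None = DEFAULT_END_WINDOW,
              max_pairs: int = DEFAULT_MAX_PAIRS,
              max_evalue: float = DEFAULT_MAX_EVALUE) -> list[TirPair]:
    """Detect inverted repeat pairs in a sequence.

    With an ``end_window``, both copies must start within that distance of
    their respective sequence ends (the "terminal" in TIR); ``None`` searches
    the whole sequence (used when scanning a locus whose element boundaries
    are unknown). Besides the length and identity thresholds, a pair must be
    statistically surprising for the searched space: its alignment score must
    reach an E-value of at most ``max_evalue`` under ungapped Karlin-Altschul
    statistics for the +2/-3 scoring (chance short high-identity matches are
    otherwise common in any few-kbp window). Pairs are ranked by alignment
    score; overlapping candidates are resolved best-first; at most
    ``max_pairs`` pairs are returned, outermost first on ties.
    """
    n = len(seq)
    if n < 2 * min_len:
        logger.info("sequence of %d nt shorter than 2 x min_len; no TIR search", n)
        return []
    codes = encode_nt(seq.upper())
    rc = codes[::-1].copy()
    rc = np.where(rc < 4, 3 - rc, rc).astype(np.uint8)
    W = n if end_window is None else min(end_window, n)
    score_min = np.log(_NT_K * float(W) * float(W) / max_evalue) / _NT_LAMBDA
    if W * W <= _FULL_SW_MAX_CELLS:
        raw = _full_sw_pairs(codes[:W], rc[:W], n, 0, min_len, min_identity,
                             max_pairs * 3, score_min)
    else:
        raw = _seeded_pairs(codes, rc, n, min_len, min_identity, max_pairs,
                            score_min)
        if end_window is not None:
            raw = [p for p in raw if p.left_start < end_window
                   and p.right_end > n - end_window]
    # best-first conflict resolution; ties broken outermost-first
    raw.sort(key=lambda p: (-p.score, p.left_start, -(p.right_end)))
    kept: list[TirPair] = []
    for p in raw:
        clash = any(_overlaps(p.left, q.left) or _overlaps(p.right, q.right)
                    for q in kept)
        if not clash:
            kept.append(p)
        if len(kept) >= max_pairs:
            break
    return kept


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) > max(a[0], b[0])


def recompute_identity(seq: str, pair: TirPair) -> float:
    """Realign the two copies directly: identity(left, revcomp(right))."""
    from .seqio import revcomp
    left = seq[pair.left_start:pair.left_end]
    right_rc = revcomp(seq[pair.right_start:pair.right_end])
    aln = align_nt(left, right_rc)
    if aln is None:
        return 0.0
    return 100.0 * aln.identity(encode_nt(left.upper()),
                                encode_nt(right_rc.upper()))


def tir_fraction(loci) -> tuple[float, int, int]:
    """Fraction of loci with at least one TIR pair inside their boundary.

    Accepts any objects exposing ``tirs`` and ``boundary_estimate`` (as
    :class:`evescan.locus.EveLocus` does). Returns (fraction, numerator,
    denominator).
    """
    loci = list(loci)
    if not loci:
        raise ValueError("tir_fraction of an empty locus set is undefined")
    num = 0
    for locus in loci:
        be = getattr(locus, "boundary_estimate", None)
        tirs = getattr(locus, "tirs", [])
        if not tirs:
            continue
        if be is None:
            continue
        bs, be_end = be[0], be[1]
        if any(p.left_start >= bs and p.right_end <= be_end for p in tirs):
            num += 1
    return num / len(loci), num, len(loci)
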