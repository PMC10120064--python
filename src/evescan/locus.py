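"""Candidate EVE loci: flank extraction, hallmark annotation, boundaries.

A locus is the capsid-gene hit plus up to 30 kbp of flanking sequence on
each side. The locus is annotated against a hallmark protein database
(polymerase, primase–helicase, integrase/recombinase, protease, ATPase,
minor capsid, ...), profiled for GC deviation from the genomic mean, and
scanned for terminal inverted repeats. Insertion boundaries are estimated
from a TIR pair flanking the capsid gene when one exists, otherwise from a
sustained GC-deviation segment containing it.

All coordinates on :class:`EveLocus` and :class:`GeneAnnotation` are
absolute contig coordinates (0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .search import TranslatedHit, range_cull, translated_search
from .seqio import Contig, Feature, GenomeAssembly, gc_track
from .tir import TirPair, find_tirs

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 30000
DEFAULT_ANNOT_EVALUE = 1e-4
DEFAULT_ANNOT_COVERAGE = 0.7
DEFAULT_GC_WINDOW = 500
DEFAULT_GC_STEP = 100
DEFAULT_GC_THRESHOLD = 0.05
DEFAULT_GC_MIN_RUN = 5000


@dataclass(frozen=True)
class GeneAnnotation:
    """A hallmark-protein match inside a locus (absolute contig coords)."""

    gene_name: str
    start: int
    end: int
    strand: str
    evalue: float
    pct_identity: float
    source_query: str


@dataclass
class EveLocus:
    """A capsid hit with its genomic context."""

    contig_id: str
    start: int
    end: int
    seq: str
    mcp_hit: TranslatedHit
    contig_length: int
    gc_genomic_mean: float
    left_truncated: bool = False
    right_truncated: bool = False
    annotations: list[GeneAnnotation] = field(default_factory=list)
    gc_deltas: list[tuple[int, float]] = field(default_factory=list)
    tirs: list[TirPair] = field(default_factory=list)
    boundary_estimate: tuple[int, int] | None = None
    boundary_method: str | None = None
    quality_flags: list[str] = field(default_factory=list)

    @property
    def locus_id(self) -> str:
        return f"{self.contig_id}:{self.mcp_hit.nt_start}-{self.mcp_hit.nt_end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_locus(assembly: GenomeAssembly, hit: TranslatedHit,
                  flank: int = DEFAULT_FLANK) -> EveLocus:
    """Extract the hit plus up to ``flank`` bp up- and downstream.

    Truncation at a contig end is recorded in ``left_truncated`` /
    ``right_truncated``.
    """
    contig = assembly[hit.contig_id]
    n = len(contig)
    start = max(0, hit.nt_start - flank)
    end = min(n, hit.nt_end + flank)
    return EveLocus(
        contig_id=hit.contig_id, start=start, end=end,
        seq=contig.seq[start:end], mcp_hit=hit, contig_length=n,
        gc_genomic_mean=assembly.mean_gc,
        left_truncated=(hit.nt_start - flank < 0),
        right_truncated=(hit.nt_end + flank > n))


def annotate_hallmarks(locus: EveLocus, hallmark_db: dict[str, str],
                       evalue: float = DEFAULT_ANNOT_EVALUE,
                       coverage: float = DEFAULT_ANNOT_COVERAGE,
                       function_classes: dict[str, str] | None = None
                       ) -> list[GeneAnnotation]:
    """Annotate a locus against hallmark proteins (greedy best-hit per region).

    A hallmark match must satisfy the E-value cutoff and cover at least
    ``coverage`` of its query; among overlapping matches only the
    best-scoring is kept. ``function_classes`` optionally maps query ids to
    function-class labels (defaults to the query id itself).
    """
    if not hallmark_db:
        raise ValueError("hallmark database is empty")
    mini = GenomeAssembly([Contig(locus.contig_id, locus.seq)])
    hits = translated_search(mini, hallmark_db, min_identity=0.0,
                             min_aa_len=30, evalue_max=evalue)
    hits = [h for h in hits
            if h.aligned_aa_len >= coverage * len(hallmark_db[h.query_id])]
    hits = range_cull(hits)
    annots = []
    for h in hits:
        cls = (function_classes or {}).get(h.query_id, h.query_id)
        annots.append(GeneAnnotation(cls, locus.start + h.nt_start,
                                     locus.start + h.nt_end, h.strand,
                                     h.evalue, h.pct_identity, h.query_id))
    locus.annotations = annots
    return annots


def gc_deviation(locus: EveLocus, window: int = DEFAULT_GC_WINDOW,
                 step: int = DEFAULT_GC_STEP) -> list[tuple[int, float]]:
    """Per-window GC delta (locus window GC minus genomic mean GC)."""
    track = gc_track(locus.seq, window, step)
    deltas = [(locus.start + s, gc - locus.gc_genomic_mean) for s, gc in track]
    locus.gc_deltas = deltas
    return deltas


def scan_tirs(locus: EveLocus, min_len: int = 20, min_identity: float = 0.85,
              max_pairs: int = 3) -> list[TirPair]:
    """Whole-locus inverted-repeat scan (element ends are unknown a priori)."""
    pairs = find_tirs(locus.seq, min_len=min_len, min_identity=min_identity,
                      end_window=None, max_pairs=max_pairs)
    locus.tirs = [p.shifted(locus.start) for p in pairs]
    return locus.tirs


def estimate_boundaries(locus: EveLocus,
                        gc_threshold: float = DEFAULT_GC_THRESHOLD,
                        gc_min_run: int = DEFAULT_GC_MIN_RUN,
                        gc_window: int = DEFAULT_GC_WINDOW
                        ) -> tuple[int, int] | None:
    """Estimate the insertion interval.

    TIR method (takes precedence): the best-scoring TIR pair that flanks the
    capsid gene; boundaries are the outer TIR coordinates. GC method: the
    longest sign-consistent run of GC deltas with |delta| >= threshold
    spanning at least ``gc_min_run`` bp that contains the capsid gene.
    Returns None (and sets no boundary) when neither fires.
    """
    mcp_s, mcp_e = locus.mcp_hit.nt_start, locus.mcp_hit.nt_end
    flanking = [p for p in locus.tirs
                if p.left_end <= mcp_s and p.right_start >= mcp_e]
    if flanking:
        best = max(flanking, key=lambda p: p.score)
        locus.boundary_estimate = (best.left_start, best.right_end)
        locus.boundary_method = "TIR"
        return locus.boundary_estimate
    if locus.gc_deltas:
        runs = _deviation_runs(locus.gc_deltas, gc_threshold, gc_window)
        runs = [r for r in runs
                if r[1] - r[0] >= gc_min_run and r[0] <= mcp_s and r[1] >= mcp_e]
        if runs:
            run = max(runs, key=lambda r: r[1] - r[0])
            locus.boundary_estimate = (max(run[0], locus.start),
                                       min(run[1], locus.end))
            locus.boundary_method = "GC"
            return locus.boundary_estimate
    locus.boundary_estimate = None
    locus.boundary_method = None
    return None


def _deviation_runs(deltas: list[tuple[int, float]], threshold: float,
                    window: int) -> list[tuple[int, int]]:
    """Maximal same-direction runs of windows with |delta| >= threshold.

    Runs of the same sign separated by no more than one window length of
    sub-threshold windows are merged (sampling noise briefly dips below the
    threshold even inside a genuinely shifted segment).
    """
    raw = []
    cur_start = None
    cur_sign = 0
    last_pos = None
    for pos, d in deltas:
        sign = 1 if d >= threshold else (-1 if d <= -threshold else 0)
        if sign != 0 and sign == cur_sign:
            last_pos = pos
        else:
            if cur_sign != 0:
                raw.append((cur_start, last_pos + window, cur_sign))
            cur_start, cur_sign, last_pos = (pos, sign, pos) if sign else (None, 0, None)
    if cur_sign != 0:
        raw.append((cur_start, last_pos + window, cur_sign))
    merged: list[list] = []
    for s, e, sign in raw:
        if merged and sign == merged[-1][2] and s - merged[-1][1] <= window:
            merged[-1][1] = e
        else:
            merged.append([s, e, sign])
    return [(s, e) for s, e, _ in merged]


def annotate_locus(locus: EveLocus, hallmark_db: dict[str, str],
                   annot_evalue: float = DEFAULT_ANNOT_EVALUE,
                   annot_coverage: float = DEFAULT_ANNOT_COVERAGE,
                   function_classes: dict[str, str] | None = None,
                   gc_window: int = DEFAULT_GC_WINDOW,
                   gc_step: int = DEFAULT_GC_STEP,
                   gc_threshold: float = DEFAULT_GC_THRESHOLD,
                   gc_min_run: int = DEFAULT_GC_MIN_RUN,
                   tir_min_len: int = 20, tir_min_identity: float = 0.85
                   ) -> EveLocus:
    """Run the full per-locus annotation stack in the canonical order."""
    annotate_hallmarks(locus, hallmark_db, annot_evalue, annot_coverage,
                       function_classes)
    gc_deviation(locus, gc_window, gc_step)
    scan_tirs(locus, tir_min_len, tir_min_identity)
    estimate_boundaries(locus, gc_threshold, gc_min_run, gc_window)
    return locus


def loci_to_features(loci: list[EveLocus]) -> list[Feature]:
    """Locus, capsid, hallmark, TIR and boundary features for GFF3 export."""
    feats = []
    for locus in loci:
        lid = locus.locus_id
        feats.append(Feature(locus.contig_id, locus.start, locus.end,
                             type="eve_locus", strand=".",
                             attributes={"ID": lid,
                                         "eve_quality": ",".join(
                                             locus.quality_flags) or "NA"}))
        h = locus.mcp_hit
        feats.append(Feature(h.contig_id, h.nt_start, h.nt_end,
                             type="mcp_gene", strand=h.strand, score=h.score,
                             attributes={"Parent": lid, "Name": h.query_id}))
        for a in locus.annotations:
            feats.append(Feature(locus.contig_id, a.start, a.end,
                                 type="hallmark_gene", strand=a.strand,
                                 score=-a.evalue,
                                 attributes={"Parent": lid, "Name": a.gene_name}))
        for i, p in enumerate(locus.tirs):
            for side, (s, e) in (("L", p.left), ("R", p.right)):
                feats.append(Feature(locus.contig_id, s, e,
                                     type="terminal_inverted_repeat",
                                     strand=".", score=p.score,
                                     attributes={"Parent": lid,
                                                 "Name": f"TIR{i+1}{side}"}))
        if locus.boundary_estimate is not None:
            bs, be = locus.boundary_estimate
            feats.append(Feature(locus.contig_id, bs, be,
                                 type="insertion_boundary", strand=".",
                                 attributes={"Parent": lid,
                                             "method": locus.boundary_method}))
    return feats


def loci_summary(loci: list[EveLocus]) -> pd.DataFrame:
    rows = []
    for lc in loci:
        rows.append({
            "locus_id": lc.locus_id, "contig_id": lc.contig_id,
            "locus_start": lc.start, "locus_end": lc.end,
            "mcp_start": lc.mcp_hit.nt_start, "mcp_end": lc.mcp_hit.nt_end,
            "mcp_query": lc.mcp_hit.query_id,
            "mcp_identity": lc.mcp_hit.pct_identity,
            "n_hallmarks": len(lc.annotations),
            "n_tir_pairs": len(lc.tirs),
            "boundary_start": lc.boundary_estimate[0] if lc.boundary_estimate else -1,
            "boundary_end": lc.boundary_estimate[1] if lc.boundary_estimate else -1,
            "boundary_method": lc.boundary_method or "none",
            "quality": ",".join(lc.quality_flags) or "NA",
        })
    return pd.DataFrame(rows)
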