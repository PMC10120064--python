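"""Per-assembly census of capsid-gene hits and candidate EVE loci.

Implements the literal quality and fragmentation rules used to summarise
hits: a high-quality locus sits on a contig longer than 60 kb with the
capsid gene more than 20 kb from either contig end and at least three
viral-like genes; a hit on a contig shorter than 1,600 bp is a lone capsid
fragment, shorter than 25,000 bp a sub-element fragment. Genome-fraction
bounds assume each capsid gene marks one 15–20 kbp element.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from .locus import EveLocus
from .search import TranslatedHit

HQ_MIN_CONTIG = 60000          # bp, strictly greater
HQ_MIN_END_DISTANCE = 20000    # bp, strictly greater, both ends
HQ_MIN_VIRAL_GENES = 3
LONE_MCP_MAX = 1600            # bp, strictly less
SUBVIRAL_MAX = 25000           # bp, strictly less
ELEMENT_LEN_LOW = 15000
ELEMENT_LEN_HIGH = 20000


def _count_nonoverlapping(intervals: list[tuple[int, int]]) -> int:
    """Maximum number of pairwise non-overlapping intervals (greedy by end)."""
    count = 0
    last_end = -1
    for s, e in sorted(intervals, key=lambda iv: iv[1]):
        if s >= last_end:
            count += 1
            last_end = e
    return count


def classify_high_quality(locus: EveLocus, contig_length: int | None = None,
                          min_contig: int = HQ_MIN_CONTIG,
                          min_end_distance: int = HQ_MIN_END_DISTANCE,
                          min_viral_genes: int = HQ_MIN_VIRAL_GENES,
                          count_mcp: bool = True) -> tuple[bool, list[str]]:
    """High-quality test with reason codes for every failed criterion.

    Viral-like genes are counted as non-overlapping annotations; the capsid
    hit itself counts as one of them by default (``count_mcp``).
    """
    if contig_length is None:
        contig_length = locus.contig_length
    reasons = []
    if contig_length <= min_contig:
        reasons.append("contig_too_short")
    mcp = locus.mcp_hit
    if not (mcp.nt_start > min_end_distance
            and contig_length - mcp.nt_end > min_end_distance):
        reasons.append("mcp_near_end")
    intervals = [(a.start, a.end) for a in locus.annotations]
    if count_mcp:
        intervals.append((mcp.nt_start, mcp.nt_end))
    n_genes = _count_nonoverlapping(intervals)
    if n_genes < min_viral_genes:
        reasons.append("too_few_viral_genes")
    ok = not reasons
    locus.quality_flags = ["high_quality"] if ok else reasons
    return ok, reasons


def fragment_category(hit: TranslatedHit | None, contig_length: int) -> str:
    """Categorise a hit by its contig length: lone capsid fragment
    (< 1,600 bp), sub-element fragment (< 25,000 bp), or resolved."""
    if contig_length < LONE_MCP_MAX:
        return "lone_mcp"
    if contig_length < SUBVIRAL_MAX:
        return "subviral_fragment"
    return "resolved"


def genome_fraction(n_mcp: int, genome_len: int,
                    element_len_low: int = ELEMENT_LEN_LOW,
                    element_len_high: int = ELEMENT_LEN_HIGH
                    ) -> tuple[float, float]:
    """Percent of the genome in EVEs, assuming one element per capsid gene.

    Returns ``(low, high)`` percentages for the element-length bounds.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    if n_mcp < 0:
        raise ValueError("n_mcp must be non-negative")
    low = 100.0 * n_mcp * element_len_low / genome_len
    high = 100.0 * n_mcp * element_len_high / genome_len
    return low, high


def mcp_density(n_mcp: int, genome_len: int) -> float:
    """Capsid-gene hits per Mbp of assembly."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    return n_mcp / (genome_len / 1e6)


@dataclass
class CensusReport:
    """Per-assembly summary of the scan."""

    assembly_id: str
    n_mcp_hits: int
    hits_per_cluster: dict[str, int]
    n_high_quality: int
    tir_fraction_high_quality: float
    fragment_counts: dict[str, int]
    genome_fraction_low: float
    genome_fraction_high: float
    mcp_density_per_mbp: float
    genome_length: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CensusReport":
        return cls(**json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["hits_per_cluster"] = json.dumps(d["hits_per_cluster"], sort_keys=True)
        d["fragment_counts"] = json.dumps(d["fragment_counts"], sort_keys=True)
        d["extra"] = json.dumps(d["extra"], sort_keys=True)
        return pd.DataFrame([d])


def build_census(assembly, loci: list[EveLocus], clusters=None,
                 assembly_id: str | None = None) -> CensusReport:
    """Assemble a census report from annotated loci (one assembly).

    ``clusters`` is an optional list of :class:`evescan.network.SequenceCluster`
    over locus ids; every member must name a known locus.
    """
    genome_len = assembly.total_length
    aid = assembly_id or "assembly"
    locus_ids = {lc.locus_id for lc in loci}
    hits_per_cluster: dict[str, int] = {}
    if clusters:
        for cl in clusters:
            unknown = [m for m in cl.members if m not in locus_ids]
            if unknown:
                raise ValueError(f"cluster {cl.representative!r} references "
                                 f"unknown loci: {unknown[:3]}")
            hits_per_cluster[cl.representative] = len(cl.members)
    n_hits = len(loci)
    frag_counts = {"lone_mcp": 0, "subviral_fragment": 0, "resolved": 0}
    hq_loci = []
    for lc in loci:
        frag_counts[fragment_category(lc.mcp_hit, lc.contig_length)] += 1
        ok, _ = classify_high_quality(lc)
        if ok:
            hq_loci.append(lc)
    if hq_loci:
        from .tir import tir_fraction
        tf, _, _ = tir_fraction(hq_loci)
    else:
        tf = 0.0
    gf_low, gf_high = genome_fraction(n_hits, genome_len) if genome_len else (0.0, 0.0)
    return CensusReport(
        assembly_id=aid, n_mcp_hits=n_hits, hits_per_cluster=hits_per_cluster,
        n_high_quality=len(hq_loci), tir_fraction_high_quality=tf,
        fragment_counts=frag_counts, genome_fraction_low=gf_low,
        genome_fraction_high=gf_high,
        mcp_density_per_mbp=mcp_density(n_hits, genome_len),
        genome_length=genome_len)
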