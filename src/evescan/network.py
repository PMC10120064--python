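"""EVE diversity: greedy identity/coverage clustering and similarity networks.

Clustering follows incremental greedy semantics: sequences are taken
longest-first (ties broken by id); each sequence joins the first existing
cluster whose representative it matches at the identity/coverage thresholds,
otherwise it founds a new cluster. Identity is matches over aligned
(non-gap) columns of a local alignment; coverage is alignment columns over
the length of the shorter sequence.

The similarity network aligns all unordered protein pairs, keeps edges
passing an E-value cutoff and a minimum (bit-scale) alignment score, and
labels connected components deterministically by smallest member id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._align import (LocalAlignment, align_nt, align_protein, bit_score,
                     encode_aa, evalue)
from .seqio import encode_nt

logger = logging.getLogger(__name__)


@dataclass
class SequenceCluster:
    """A representative with its members under an identity/coverage threshold."""

    representative: str
    members: list[str]
    min_identity: float
    min_coverage: float
    alphabet: str = "nt"

    def __post_init__(self):
        assert self.representative in self.members


def _pair_stats(a: str, b: str, alphabet: str
                ) -> tuple[LocalAlignment | None, float, float]:
    if alphabet == "aa":
        aln = align_protein(a, b)
        enc = encode_aa
    else:
        aln = align_nt(a, b)
        enc = lambda s: encode_nt(s.upper())  # noqa: E731
    if aln is None:
        return None, 0.0, 0.0
    ident = aln.identity(enc(a), enc(b))
    cov = aln.n_columns / min(len(a), len(b))
    return aln, ident, cov


def greedy_cluster(seqs: dict[str, str], min_identity: float,
                   min_coverage: float, alphabet: str = "nt"
                   ) -> list[SequenceCluster]:
    """Incremental greedy clustering at an identity/coverage threshold."""
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("identity and coverage must be in (0, 1]")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[SequenceCluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            _, ident, cov = _pair_stats(seqs[sid], seqs[cl.representative],
                                        alphabet)
            if ident >= min_identity and cov >= min_coverage:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(sid, [sid], min_identity,
                                            min_coverage, alphabet))
    return clusters


def clusters_to_frame(clusters: list[SequenceCluster]) -> pd.DataFrame:
    rows = [{"member": m, "representative": cl.representative,
             "min_identity": cl.min_identity, "min_coverage": cl.min_coverage}
            for cl in clusters for m in cl.members]
    return pd.DataFrame(rows, columns=["member", "representative",
                                       "min_identity", "min_coverage"])


DIVERSITY_THRESHOLDS = (1.00, 0.98, 0.50)


def within_genome_diversity(mcp_seqs: dict[str, str],
                            thresholds: tuple[float, ...] = DIVERSITY_THRESHOLDS,
                            min_coverage: float = 0.3, alphabet: str = "nt"
                            ) -> pd.DataFrame:
    """Cluster counts at decreasing identity thresholds (coverage 30%)."""
    if not mcp_seqs:
        raise ValueError("no sequences")
    rows = []
    for t in thresholds:
        n = len(greedy_cluster(mcp_seqs, t, min_coverage, alphabet))
        rows.append({"threshold": t, "n_clusters": n})
    return pd.DataFrame(rows)


def dereplicate_per_genome(seqs_by_genome: dict[str, dict[str, str]],
                           min_identity: float = 0.90,
                           min_coverage: float = 0.8, alphabet: str = "nt"
                           ) -> dict[str, str]:
    """Cluster within each genome independently; pool the representatives.

    The same variant present in two genomes yields two representatives —
    dereplication never merges across genomes.
    """
    reps: dict[str, str] = {}
    for genome, seqs in seqs_by_genome.items():
        if not seqs:
            logger.info("genome %s has no sequences; skipped", genome)
            continue
        for cl in greedy_cluster(seqs, min_identity, min_coverage, alphabet):
            # keys are genome-qualified: identical ids in two genomes stay
            # distinct representatives
            reps[f"{genome}:{cl.representative}"] = seqs[cl.representative]
    return reps


# ---------------------------------------------------------------------------
# Similarity network
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNetwork:
    """All-vs-all protein similarity graph with connected components."""

    graph: nx.Graph
    components: dict[str, int] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(set(self.components.values())) if self.components else 0

    def component_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.components.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(m) for c, m in out.items()}


def _label_components(graph: nx.Graph) -> dict[str, int]:
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    return {node: i for i, comp in enumerate(comps) for node in comp}


def build_network(proteins: dict[str, str], evalue_cutoff: float = 1e-4,
                  min_score: float = 6.0,
                  node_attributes: dict[str, dict] | None = None
                  ) -> SimilarityNetwork:
    """All-vs-all local alignment network.

    An edge joins two proteins when their best local alignment has E-value
    at most ``evalue_cutoff`` and bit-scale score at least ``min_score``.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    g = nx.Graph()
    for pid in proteins:
        g.add_node(pid, **(node_attributes or {}).get(pid, {}))
    ids = sorted(proteins)
    codes = {i: encode_aa(proteins[i]) for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            aln = align_protein(codes[a], codes[b])
            if aln is None:
                continue
            ev = evalue(aln.score, len(proteins[a]), len(proteins[b]))
            bits = bit_score(aln.score)
            if ev <= evalue_cutoff and bits >= min_score:
                g.add_edge(a, b, score=bits, evalue=ev, raw_score=aln.score)
    return SimilarityNetwork(g, _label_components(g))


def export_network(net: SimilarityNetwork
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge table (source, target, score, evalue) + node attribute table."""
    edges = pd.DataFrame(
        [{"source": min(u, v), "target": max(u, v),
          "score": d["score"], "evalue": d["evalue"]}
         for u, v, d in net.graph.edges(data=True)],
        columns=["source", "target", "score", "evalue"])
    edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    nodes = pd.DataFrame(
        [{"node": n, "component": net.components.get(n, -1),
          **{k: v for k, v in d.items()}}
         for n, d in sorted(net.graph.nodes(data=True))])
    return edges, nodes


def import_network(edges: pd.DataFrame, nodes: pd.DataFrame
                   ) -> SimilarityNetwork:
    """Rebuild a network from exported tables (round-trip inverse)."""
    g = nx.Graph()
    for row in nodes.itertuples():
        attrs = {k: v for k, v in row._asdict().items()
                 if k not in ("Index", "node", "component")}
        g.add_node(row.node, **attrs)
    for row in edges.itertuples():
        g.add_edge(row.source, row.target, score=row.score, evalue=row.evalue)
    return SimilarityNetwork(g, _label_components(g))
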