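"""Synthetic host assemblies with planted endogenous viral elements.

The generator emulates the statistical structure the detection pipeline
assumes in real draft assemblies:

* elements 14–40 kbp long, carrying one major capsid protein (MCP) gene plus
  a complement of viral hallmark genes (pPolB, primase–helicase, integrase,
  protease, ATPase, minor capsid), with terminal inverted repeats (TIRs) and
  a depressed GC content relative to the host background;
* families of closely related microvariants radiating from one ancestor
  (star phylogeny) at a configurable per-site divergence;
* assembly artefacts — single-base frameshifts and premature stop codons —
  injected inside planted intervals only;
* optional fragmentation: a copy emitted as a short detached contig instead
  of an embedded insertion (a lone-MCP contig < 1,600 bp, or a sub-element
  fragment < 25,000 bp).

Every run is fully determined by the seed; placement, mutation and artefact
randomness draw from separate child streams so that changing one rate does
not reshuffle the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Contig, Feature, GenomeAssembly, revcomp

BASES = np.array(list("ACGT"))

#: default amino-acid lengths for the viral gene complement
GENE_AA_LENGTHS = {
    "MCP": 450,
    "mCP": 250,
    "ATPase": 260,
    "protease": 210,
    "pPolB": 700,
    "Pri-Hel": 560,
    "YR": 360,
    "rve-integrase": 320,
    "hypothetical": 150,
}

#: hallmark genes other than the capsid marker itself
HALLMARK_GENES = ["mCP", "ATPase", "protease", "pPolB", "Pri-Hel", "YR",
                  "rve-integrase", "hypothetical"]

# amino-acid background used to draw synthetic proteins (Robinson & Robinson)
_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQ = np.array([0.07805, 0.05129, 0.04487, 0.05364, 0.01925, 0.04264,
                     0.06295, 0.07377, 0.02199, 0.05142, 0.09019, 0.05744,
                     0.02243, 0.03856, 0.05203, 0.07120, 0.05841, 0.01330,
                     0.03216, 0.06441])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

# standard-code codons per amino acid (used for GC-biased reverse translation)
_CODONS: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT  # noqa: E402
for _codon, _aa in _CT.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class GeneCopy:
    """A gene within one element copy, coordinates relative to the element."""

    name: str
    start: int
    end: int
    strand: str


@dataclass
class EveTemplate:
    """Blueprint of one element family: length, TIRs, GC offset, gene layout."""

    template_id: str
    element_length: int
    tir_length: int = 100
    gc_offset: float = -0.10
    gene_layout: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        mcp = [g for g, _, _ in self.gene_layout if g == "MCP"]
        if len(mcp) != 1:
            raise ValueError("template must contain exactly one MCP gene")
        coding = sum(3 * (aa + 1) for _, _, aa in self.gene_layout)
        if coding + 2 * self.tir_length > self.element_length:
            raise ValueError("genes + TIRs exceed element_length")

    @classmethod
    def random(cls, template_id: str, rng: np.random.Generator,
               length_range: tuple[int, int] = (14000, 40000),
               tir_length: int = 100, gc_offset: float = -0.10,
               n_hallmarks: int | None = None) -> "EveTemplate":
        """Draw a template: MCP centrally placed among sampled hallmark genes."""
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if n_hallmarks is None:
            n_hallmarks = int(rng.integers(4, len(HALLMARK_GENES) + 1))
        names = list(rng.choice(HALLMARK_GENES, size=n_hallmarks, replace=False))
        # the capsid gene sits mid-element so a +/-30 kbp flank reaches both ends
        names.insert(len(names) // 2, "MCP")
        layout = [(g, "+" if rng.random() < 0.5 else "-", GENE_AA_LENGTHS[g])
                  for g in names]
        return cls(template_id, length, tir_length, gc_offset, layout)


@dataclass
class EveVariant:
    seq: str
    variant_id: str
    genes: list[GeneCopy]
    has_tir: bool
    n_substitutions: int
    n_indels: int
    mcp_identity_warning: bool = False


@dataclass
class EveFamily:
    """An ancestral element plus its microvariants."""

    template: EveTemplate
    ancestral_seq: str
    proteins: dict[str, str]          # gene name -> ancestral protein
    genes: list[GeneCopy]             # ancestral coordinates
    variants: list[EveVariant] = field(default_factory=list)

    @property
    def mcp_protein(self) -> str:
        return self.proteins["MCP"]


@dataclass
class SimulationConfig:
    """All simulator knobs; the seed fully determines the output."""

    seed: int = 0
    n_contigs: int = 5
    contig_length: int = 2_000_000
    host_gc: float = 0.5
    n_templates: int = 3
    copies_per_template: int = 20
    element_length_range: tuple[int, int] = (14000, 40000)
    tir_length: int = 100
    tir_probability: float = 1.0
    gc_offset: float = -0.10
    divergence: float = 0.02          # substitutions/site, ancestor -> variant
    indel_rate: float = 0.0           # single-base indels/site within variants
    frameshift_rate: float = 0.0      # artefact single-base indels/site
    premature_stop_rate: float = 0.0  # artefact stop-creating subs/site
    fragmented_probability: float = 0.0
    lone_mcp_fraction: float = 0.5    # of fragmented copies
    retroelement_insertion_probability: float = 0.0
    mcp_identity_floor: float = 0.50

    def __post_init__(self):
        for name in ("tir_probability", "divergence", "indel_rate",
                     "frameshift_rate", "premature_stop_rate",
                     "fragmented_probability", "lone_mcp_fraction",
                     "retroelement_insertion_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.host_gc < 1.0:
            raise ValueError("host_gc must be in (0,1)")


TRUTH_COLUMNS = ["contig_id", "start", "end", "template_id", "variant_id",
                 "strand", "has_tir", "fragmented", "category",
                 "n_substitutions", "n_indels", "mcp_start", "mcp_end",
                 "mcp_identity_warning"]


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def random_nt(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def generate_host_contig(length: int, host_gc: float,
                         rng: np.random.Generator, contig_id: str = "contig"
                         ) -> Contig:
    """An i.i.d. host contig with expected GC = host_gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < host_gc <= 1.0:
        if host_gc == 0.0:
            raise ValueError("host_gc must be in (0,1]")
        raise ValueError("host_gc must be in (0,1]")
    return Contig(contig_id, random_nt(length, host_gc, rng))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_AA))[rng.choice(20, size=length, p=_AA_FREQ)])


def _codon_weights(codons: list[str], g: float) -> np.ndarray:
    w = np.array([np.prod([g / 2 if b in "GC" else (1 - g) / 2 for b in c])
                  for c in codons])
    return w / w.sum()


def _expected_coding_gc(protein: str, g: float) -> float:
    num = den = 0.0
    for aa in set(protein):
        codons = _CODONS[aa]
        w = _codon_weights(codons, g)
        gc_counts = np.array([sum(b in "GC" for b in c) for c in codons])
        n_aa = protein.count(aa)
        num += n_aa * float(w @ gc_counts)
        den += n_aa * 3.0
    return num / den


def reverse_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Encode a protein with synonymous-codon choice hitting a target GC.

    Coding constraints cap how far synonymous choice can push composition,
    so the bias parameter is calibrated by bisection to make the expected
    coding GC match ``gc`` as closely as the code allows.
    """
    lo, hi = 0.01, 0.99
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _expected_coding_gc(protein, mid) < gc:
            lo = mid
        else:
            hi = mid
    g = 0.5 * (lo + hi)
    out = []
    for aa in protein:
        codons = _CODONS[aa]
        out.append(codons[rng.choice(len(codons), p=_codon_weights(codons, g))])
    out.append("TGA")
    return "".join(out)


def build_family_ancestor(template: EveTemplate, host_gc: float,
                          rng: np.random.Generator) -> EveFamily:
    """Realize a template as an ancestral element sequence."""
    gc = min(max(host_gc + template.gc_offset, 0.05), 0.95)
    proteins = {g: random_protein(aa, rng) for g, _, aa in template.gene_layout}
    cds = {}
    for g, strand, _aa in template.gene_layout:
        s = reverse_translate(proteins[g], gc, rng)
        cds[g] = s if strand == "+" else revcomp(s)
    coding = sum(len(s) for s in cds.values())
    interior = template.element_length - 2 * template.tir_length
    n_spacers = len(template.gene_layout) + 1
    spare = interior - coding
    spacer_lens = [spare // n_spacers] * n_spacers
    spacer_lens[-1] += spare - sum(spacer_lens)
    tir = random_nt(template.tir_length, gc, rng)
    parts = [tir]
    genes = []
    pos = template.tir_length
    for i, (g, strand, _aa) in enumerate(template.gene_layout):
        sp = random_nt(spacer_lens[i], gc, rng)
        parts.append(sp)
        pos += len(sp)
        parts.append(cds[g])
        genes.append(GeneCopy(g, pos, pos + len(cds[g]), strand))
        pos += len(cds[g])
    parts.append(random_nt(spacer_lens[-1], gc, rng))
    parts.append(revcomp(tir))
    seq = "".join(parts)
    assert len(seq) == template.element_length
    return EveFamily(template, seq, proteins, genes)


def _mutate(seq: str, genes: list[GeneCopy], n_sub: int, n_indel: int,
            rng: np.random.Generator) -> tuple[str, list[GeneCopy], int, int]:
    arr = np.array(list(seq))
    n = len(arr)
    if n_sub:
        pos = rng.choice(n, size=min(n_sub, n), replace=False)
        for p in pos:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(3)]
    seq_list = list(arr)
    genes = [dataclasses.replace(g) for g in genes]
    applied_indels = 0
    if n_indel:
        for p in sorted(rng.choice(n, size=min(n_indel, n), replace=False),
                        reverse=True):
            if rng.random() < 0.5:
                del seq_list[p]
                delta = -1
            else:
                seq_list.insert(p, "ACGT"[rng.integers(4)])
                delta = 1
            applied_indels += 1
            for g in genes:
                if g.start > p:
                    g.start += delta
                if g.end > p:
                    g.end += delta
    return "".join(seq_list), genes, int(min(n_sub, n)), applied_indels


def generate_eve_family(family: EveFamily, n_variants: int, divergence: float,
                        rng: np.random.Generator, indel_rate: float = 0.0,
                        tir_probability: float = 1.0,
                        mcp_identity_floor: float = 0.5) -> EveFamily:
    """Populate a family with microvariants (star phylogeny from the ancestor).

    Variant 0 is the unmutated ancestor; every other variant carries
    Poisson(divergence × length) substitutions (and optionally single-base
    indels). TIR positions mutate like any other site. A variant whose
    expected MCP identity falls below ``mcp_identity_floor`` is flagged.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    n = len(family.ancestral_seq)
    tmpl = family.template
    family.variants = []
    for v in range(n_variants):
        if v == 0:
            seq, genes, ns, ni = family.ancestral_seq, family.genes, 0, 0
        else:
            n_sub = int(rng.poisson(divergence * n))
            n_ind = int(rng.poisson(indel_rate * n))
            seq, genes, ns, ni = _mutate(family.ancestral_seq, family.genes,
                                         n_sub, n_ind, rng)
        has_tir = bool(rng.random() < tir_probability) if tmpl.tir_length else False
        if tmpl.tir_length and not has_tir:
            # replace both terminal repeats with unrelated sequence
            gc = min(max(0.5 + tmpl.gc_offset, 0.05), 0.95)
            t = tmpl.tir_length
            seq = (random_nt(t, gc, rng) + seq[t:len(seq) - t]
                   + random_nt(t, gc, rng))
        warn = (1.0 - divergence) if v else 1.0
        family.variants.append(EveVariant(
            seq, f"{tmpl.template_id}.v{v}", genes, has_tir, ns, ni,
            mcp_identity_warning=warn < mcp_identity_floor))
    return family


def insert_retroelement(var: EveVariant, retro_seq: str,
                        rng: np.random.Generator) -> EveVariant:
    """Embed a Ty3/Gypsy-like decoy cassette in an intergenic gap."""
    gaps = []
    prev_end = 0
    for g in sorted(var.genes, key=lambda g: g.start):
        if g.start - prev_end > 50:
            gaps.append((prev_end, g.start))
        prev_end = g.end
    if len(var.seq) - prev_end > 50:
        gaps.append((prev_end, len(var.seq)))
    if not gaps:
        return var
    gs, ge = gaps[int(rng.integers(len(gaps)))]
    pos = (gs + ge) // 2
    genes = [dataclasses.replace(g) for g in var.genes]
    for g in genes:
        if g.start >= pos:
            g.start += len(retro_seq)
        if g.end > pos:
            g.end += len(retro_seq)
    genes.append(GeneCopy("retroelement", pos, pos + len(retro_seq), "+"))
    return dataclasses.replace(
        var, seq=var.seq[:pos] + retro_seq + var.seq[pos:], genes=genes)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _variant_on_strand(var: EveVariant, strand: str) -> tuple[str, list[GeneCopy]]:
    if strand == "+":
        return var.seq, var.genes
    n = len(var.seq)
    genes = [GeneCopy(g.name, n - g.end, n - g.start,
                      "-" if g.strand == "+" else "+") for g in var.genes]
    return revcomp(var.seq), genes


def _mcp_interval(genes: list[GeneCopy]) -> tuple[int, int]:
    g = next(g for g in genes if g.name == "MCP")
    return g.start, g.end


def plant_eves(assembly: GenomeAssembly, families: list[EveFamily],
               config: SimulationConfig, rng: np.random.Generator
               ) -> tuple[GenomeAssembly, pd.DataFrame]:
    """Insert every family variant into the assembly (or emit fragments).

    Embedded copies extend their host contig at a uniformly chosen position
    (host bases are never deleted); a configurable fraction of copies is
    instead emitted as a detached short contig: a lone-MCP contig
    (< 1,600 bp) or a sub-element fragment (< 25,000 bp).
    """
    inserts: dict[str, list[tuple[int, str, dict]]] = {c.id: [] for c in assembly}
    contig_ids = [c.id for c in assembly]
    lengths = np.array([len(c) for c in assembly], dtype=float)
    weights = lengths / lengths.sum()
    fragment_contigs: list[Contig] = []
    frag_rows: list[dict] = []
    n_frag = 0
    for fam in families:
        for var in fam.variants:
            strand = "+" if rng.random() < 0.5 else "-"
            seq, genes = _variant_on_strand(var, strand)
            row = {
                "template_id": fam.template.template_id,
                "variant_id": var.variant_id, "strand": strand,
                "has_tir": var.has_tir, "n_substitutions": var.n_substitutions,
                "n_indels": var.n_indels,
                "mcp_identity_warning": var.mcp_identity_warning,
            }
            if rng.random() < config.fragmented_probability:
                n_frag += 1
                ms, me = _mcp_interval(genes)
                if rng.random() < config.lone_mcp_fraction:
                    flank = int(rng.integers(20, max(21, (1599 - (me - ms)) // 2)))
                    s = max(0, ms - flank)
                    e = min(len(seq), me + flank)
                    e = min(e, s + 1599)
                    category = "lone_mcp"
                else:
                    target = int(rng.integers(max(2000, me - ms + 200), 24999))
                    s = max(0, ms - int(rng.integers(0, max(1, target - (me - ms)))))
                    e = min(len(seq), s + target)
                    category = "subviral_fragment"
                cid = f"frag_{var.variant_id}"
                fragment_contigs.append(Contig(cid, seq[s:e]))
                frag_rows.append({**row, "contig_id": cid, "start": 0,
                                  "end": e - s, "fragmented": True,
                                  "category": category,
                                  "mcp_start": ms - s, "mcp_end": me - s,
                                  "has_tir": False})
            else:
                ci = int(rng.choice(len(contig_ids), p=weights))
                pos = int(rng.integers(0, lengths[ci] + 1))
                inserts[contig_ids[ci]].append((pos, seq, {**row, "genes": genes}))
    new_contigs = []
    rows: list[dict] = []
    for contig in assembly:
        ins = sorted(inserts[contig.id], key=lambda t: t[0])
        parts = []
        cursor = 0
        offset = 0
        for pos, seq, meta in ins:
            parts.append(contig.seq[cursor:pos])
            start = pos + offset
            parts.append(seq)
            genes = meta.pop("genes")
            ms, me = _mcp_interval(genes)
            rows.append({**meta, "contig_id": contig.id, "start": start,
                         "end": start + len(seq), "fragmented": False,
                         "category": "embedded",
                         "mcp_start": start + ms, "mcp_end": start + me})
            offset += len(seq)
            cursor = pos
        parts.append(contig.seq[cursor:])
        new_contigs.append(Contig(contig.id, "".join(parts), contig.description))
    new_contigs.extend(fragment_contigs)
    truth = pd.DataFrame(rows + frag_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["contig_id", "start"]).reset_index(drop=True)
    return GenomeAssembly(new_contigs), truth


# ---------------------------------------------------------------------------
# Assembly artefacts
# ---------------------------------------------------------------------------

ARTIFACT_COLUMNS = ["contig_id", "position", "kind", "ref", "alt"]


def simulate_assembly_artifacts(assembly: GenomeAssembly, truth: pd.DataFrame,
                                config: SimulationConfig,
                                rng: np.random.Generator
                                ) -> tuple[GenomeAssembly, pd.DataFrame, pd.DataFrame]:
    """Inject frameshifts and premature stops inside planted intervals.

    Single-base insertions/deletions (frameshift artefacts) and stop-creating
    substitutions are sampled at the configured per-site rates inside each
    truth interval. Returns the edited assembly, the coordinate-adjusted
    truth table and an edit log sufficient to invert every edit.
    """
    truth = truth.copy()
    log: list[dict] = []
    new_contigs = []
    for contig in assembly:
        idx = truth.index[truth["contig_id"] == contig.id]
        idx = sorted(idx, key=lambda i: truth.at[i, "start"])
        pieces = []
        cursor = 0
        shift = 0
        for i in idx:
            s, e = int(truth.at[i, "start"]), int(truth.at[i, "end"])
            pieces.append(contig.seq[cursor:s])
            elem = list(contig.seq[s:e])
            n_fs = rng.poisson(config.frameshift_rate * (e - s))
            n_stop = rng.poisson(config.premature_stop_rate * (e - s))
            edits = []
            for p in rng.choice(e - s, size=min(n_fs, e - s), replace=False):
                kind = "del" if rng.random() < 0.5 else "ins"
                edits.append((int(p), kind))
            for p in rng.choice(max(e - s - 3, 1),
                                size=min(n_stop, max(e - s - 3, 1)),
                                replace=False):
                edits.append((int(p), "stop"))
            delta = 0
            mcp_s = int(truth.at[i, "mcp_start"])
            mcp_e = int(truth.at[i, "mcp_end"])
            elem_log: list[tuple[int, dict]] = []
            for p, kind in sorted(edits, reverse=True):
                if kind == "del":
                    elem_log.append((p, {"contig_id": contig.id, "kind": "del",
                                         "ref": elem[p], "alt": ""}))
                    del elem[p]
                    delta -= 1
                    if s + p < mcp_s:
                        mcp_s -= 1
                    if s + p < mcp_e:
                        mcp_e -= 1
                elif kind == "ins":
                    b = "ACGT"[rng.integers(4)]
                    elem_log.append((p, {"contig_id": contig.id, "kind": "ins",
                                         "ref": "", "alt": b}))
                    elem.insert(p, b)
                    delta += 1
                    if s + p < mcp_s:
                        mcp_s += 1
                    if s + p < mcp_e:
                        mcp_e += 1
                else:
                    ref = "".join(elem[p:p + 3])
                    elem_log.append((p, {"contig_id": contig.id, "kind": "stop",
                                         "ref": ref, "alt": "TAA"}))
                    elem[p:p + 3] = list("TAA")
            # record positions in final (post-edit) coordinates so the log
            # can be undone by a simple descending sweep
            cum_below = 0
            for p, entry in sorted(elem_log, key=lambda t: t[0]):
                entry["position"] = s + shift + p + cum_below
                log.append(entry)
                if entry["kind"] == "del":
                    cum_below -= 1
                elif entry["kind"] == "ins":
                    cum_below += 1
            pieces.append("".join(elem))
            truth.at[i, "start"] = s + shift
            truth.at[i, "end"] = e + shift + delta
            truth.at[i, "mcp_start"] = mcp_s + shift
            truth.at[i, "mcp_end"] = mcp_e + shift
            shift += delta
            cursor = e
        pieces.append(contig.seq[cursor:])
        new_contigs.append(Contig(contig.id, "".join(pieces),
                                  contig.description))
    artifact_log = pd.DataFrame(log, columns=ARTIFACT_COLUMNS)
    return GenomeAssembly(new_contigs), truth, artifact_log


def revert_artifacts(assembly: GenomeAssembly, artifact_log: pd.DataFrame
                     ) -> GenomeAssembly:
    """Invert an artefact log exactly (bookkeeping check)."""
    seqs = {c.id: c.seq for c in assembly}
    descr = {c.id: c.description for c in assembly}
    # positions are logged in final coordinates: undoing from the top down
    # never disturbs the coordinates of edits still to be undone
    for row in artifact_log.sort_values("position", ascending=False).itertuples():
        s = seqs[row.contig_id]
        p = int(row.position)
        if row.kind == "ins":
            seqs[row.contig_id] = s[:p] + s[p + 1:]
        elif row.kind == "del":
            seqs[row.contig_id] = s[:p] + str(row.ref) + s[p:]
        else:
            seqs[row.contig_id] = s[:p] + str(row.ref) + s[p + 3:]
    return GenomeAssembly([Contig(i, seqs[i], descr[i]) for i in seqs])


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    assembly: GenomeAssembly
    truth: pd.DataFrame
    families: list[EveFamily]
    mcp_refs: dict[str, str]
    hallmark_refs: dict[str, str]
    artifact_log: pd.DataFrame


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: host, families, planting, artefacts."""
    root = np.random.SeedSequence(config.seed)
    rng_host, rng_family, rng_place, rng_artifact = (
        np.random.default_rng(s) for s in root.spawn(4))
    host = GenomeAssembly([
        generate_host_contig(config.contig_length, config.host_gc, rng_host,
                             f"contig_{i+1}")
        for i in range(config.n_contigs)])
    families = []
    for t in range(config.n_templates):
        tmpl = EveTemplate.random(
            f"T{t+1}", rng_family, config.element_length_range,
            config.tir_length, config.gc_offset)
        fam = build_family_ancestor(tmpl, config.host_gc, rng_family)
        generate_eve_family(fam, config.copies_per_template, config.divergence,
                            rng_family, config.indel_rate,
                            config.tir_probability, config.mcp_identity_floor)
        if config.retroelement_insertion_probability > 0:
            retro = reverse_translate(random_protein(800, rng_family),
                                      config.host_gc, rng_family)
            fam.variants = [
                insert_retroelement(v, retro, rng_family)
                if rng_family.random() < config.retroelement_insertion_probability
                else v
                for v in fam.variants]
        families.append(fam)
    assembly, truth = plant_eves(host, families, config, rng_place)
    assembly, truth, artifact_log = simulate_assembly_artifacts(
        assembly, truth, config, rng_artifact)
    mcp_refs = {f"{fam.template.template_id}_MCP": fam.mcp_protein
                for fam in families}
    hallmark_refs = {}
    for fam in families:
        for g, seq in fam.proteins.items():
            hallmark_refs[f"{fam.template.template_id}_{g}"] = seq
    return SimulationResult(config, assembly, truth, families, mcp_refs,
                            hallmark_refs, artifact_log)


def truth_to_features(truth: pd.DataFrame) -> list[Feature]:
    return [Feature(r.contig_id, int(r.start), int(r.end), type="planted_eve",
                    strand=r.strand,
                    attributes={"Name": r.variant_id,
                                "template": r.template_id,
                                "has_tir": r.has_tir})
            for r in truth.itertuples()]
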