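"""Sequence and annotation I/O plus genetic-code-aware primitives.

All internal coordinates are 0-based, half-open. Conversion to the 1-based
inclusive GFF3 convention (and back) happens only at format boundaries, in
:func:`write_gff3` / :func:`write_bed`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)
_IUPAC = set("ACGTNRYSWKMBDHV")


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the accepted alphabet."""


@dataclass
class Contig:
    """A single assembly contig: nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over non-N bases (0.0 for all-N contigs)."""
        gc = sum(self.seq.count(b) for b in "GC")
        denom = len(self.seq) - self.seq.count("N")
        return gc / denom if denom else 0.0


@dataclass
class GenomeAssembly:
    """An ordered collection of contigs with cached global GC statistics."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.contigs:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r}")
            seen.add(c.id)
        self._index = {c.id: c for c in self.contigs}

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def __getitem__(self, contig_id: str) -> Contig:
        return self._index[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._index

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def mean_gc(self) -> float:
        """Genome-wide GC fraction over non-N bases."""
        gc = 0
        denom = 0
        for c in self.contigs:
            gc += c.seq.count("G") + c.seq.count("C")
            denom += len(c.seq) - c.seq.count("N")
        if denom == 0:
            warnings.warn("assembly contains no unambiguous bases; mean_gc set to 0")
            return 0.0
        return gc / denom


def _clean_seq(seq: str, record_id: str, on_invalid: str) -> str:
    seq = seq.upper()
    extra = set(seq) - NUCLEOTIDES
    if not extra:
        return seq
    if on_invalid == "map":
        keep = str.maketrans({c: "N" for c in extra})
        return seq.translate(keep)
    bad = next(i for i, c in enumerate(seq) if c not in NUCLEOTIDES)
    raise SequenceAlphabetError(
        f"record {record_id!r}: non-ACGTN character {seq[bad]!r} at position {bad} "
        "(pass on_invalid='map' to convert to N)"
    )


def read_fasta(path: str | Path, on_invalid: str = "error") -> GenomeAssembly:
    """Read a (multi-)FASTA file into a :class:`GenomeAssembly`.

    Parameters
    ----------
    path
        FASTA file, wrapped or unwrapped.
    on_invalid
        ``"error"`` (default) rejects characters outside {A,C,G,T,N};
        ``"map"`` silently converts them to N.
    """
    if on_invalid not in ("error", "map"):
        raise ValueError("on_invalid must be 'error' or 'map'")
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        contigs.append(Contig(rec.id, _clean_seq(str(rec.seq), rec.id, on_invalid), desc))
    if not contigs:
        raise ValueError(f"no records in FASTA file {path}")
    return GenomeAssembly(contigs)


def read_fasta_proteins(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no records in FASTA file {path}")
    return out


def write_fasta(assembly: GenomeAssembly | Iterable[Contig] | dict, path: str | Path,
                width: int = 70) -> None:
    """Write contigs (or an {id: seq} mapping) as wrapped FASTA."""
    if isinstance(assembly, dict):
        records = [SeqRecord(Seq(s), id=i, description="") for i, s in assembly.items()]
    else:
        records = [SeqRecord(Seq(c.seq), id=c.id, description=c.description)
                   for c in assembly]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, IUPAC ambiguity codes are honoured."""
    extra = set(seq.upper()) - _IUPAC
    if extra:
        up = seq.upper()
        bad = next(i for i, c in enumerate(up) if c not in _IUPAC)
        raise SequenceAlphabetError(
            f"invalid nucleotide {seq[bad]!r} at position {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------

class TranslationTable:
    """A 64-codon genetic code.

    Table 1 is the standard code; table 6 (ciliate/dasycladacean, used by
    *Streblomastix strix*-like hosts) reads TAA and TAG as glutamine; table 11
    is the bacterial/plastid code (same codon meanings as table 1 but kept
    distinct because gene callers treat its start codons differently).
    """

    SUPPORTED = (1, 6, 11)

    def __init__(self, table_id: int):
        if table_id not in self.SUPPORTED:
            raise ValueError(f"unsupported translation table {table_id}; "
                             f"supported: {self.SUPPORTED}")
        self.table_id = table_id
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        self.codon_map: dict[str, str] = dict(bio.forward_table)
        for stop in bio.stop_codons:
            self.codon_map[stop] = "*"
        assert len(self.codon_map) == 64
        # integer lookup over 5-letter alphabet A,C,G,T,N -> aa ('X' if any N)
        lut = np.full(125, ord("X"), dtype=np.uint8)
        base = {b: i for i, b in enumerate("ACGTN")}
        for codon, aa in self.codon_map.items():
            idx = base[codon[0]] * 25 + base[codon[1]] * 5 + base[codon[2]]
            lut[idx] = ord(aa)
        self._lut = lut

    _cache: dict[int, "TranslationTable"] = {}

    @classmethod
    def get(cls, table_id: int) -> "TranslationTable":
        if table_id not in cls._cache:
            cls._cache[table_id] = cls(table_id)
        return cls._cache[table_id]


_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_nt(seq: str) -> np.ndarray:
    """Encode nucleotides as uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate(seq: str, table: TranslationTable | int = 1, frame: int = 0,
              strand: str = "+") -> str:
    """Translate a nucleotide sequence in one frame.

    Codons are read from offset ``frame`` on the given strand (the minus
    strand is the reverse complement); a trailing partial codon is dropped.
    Codons containing N translate to ``X``; stops are ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if isinstance(table, int):
        table = TranslationTable.get(table)
    if strand == "-":
        seq = revcomp(seq)
    codes = encode_nt(seq)[frame:]
    n_codons = len(codes) // 3
    if n_codons == 0:
        return ""
    codes = codes[: n_codons * 3].reshape(n_codons, 3).astype(np.int32)
    idx = codes[:, 0] * 25 + codes[:, 1] * 5 + codes[:, 2]
    return table._lut[idx].tobytes().decode("ascii")


def six_frame_translate(seq: str, table: TranslationTable | int = 1
                        ) -> dict[str, str]:
    """All six translation frames, keyed '+0','+1','+2','-0','-1','-2'.

    Minus-strand frames are computed on the reverse complement, so frame
    '-0' starts at the 3' end of the forward strand.
    """
    out = {}
    rc = revcomp(seq)
    for f in (0, 1, 2):
        out[f"+{f}"] = translate(seq, table, f, "+")
    for f in (0, 1, 2):
        out[f"-{f}"] = translate(rc, table, f, "+")
    return out


# ---------------------------------------------------------------------------
# GC windows
# ---------------------------------------------------------------------------

def gc_track(contig: Contig | str, window: int = 500, step: int = 100
             ) -> list[tuple[int, float]]:
    """Sliding-window GC content along a sequence.

    Returns ``(window_start, gc_fraction)`` pairs. N bases are excluded from
    the denominator (an all-N window reports 0.0). A trailing partial window
    is included when it covers at least half a window. A window longer than
    the sequence degenerates to a single whole-sequence window.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    if step < 1 or window < step:
        raise ValueError("require window >= step >= 1")
    n = len(seq)
    codes = encode_nt(seq)
    is_gc = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
    non_n = np.concatenate(([0], np.cumsum(codes != 4)))
    if window >= n:
        denom = int(non_n[n])
        return [(0, float(is_gc[n] / denom) if denom else 0.0)]
    out = []
    for start in range(0, n, step):
        end = min(start + window, n)
        if end - start < window and end - start < window / 2:
            break
        denom = int(non_n[end] - non_n[start])
        gc = float((is_gc[end] - is_gc[start]) / denom) if denom else 0.0
        out.append((start, gc))
        if end == n:
            break
    return out


# ---------------------------------------------------------------------------
# Annotation output (GFF3 / BED / TSV)
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """A genomic feature in internal (0-based half-open) coordinates."""

    contig_id: str
    start: int
    end: int
    type: str = "region"
    strand: str = "."
    score: float | None = None
    source: str = "evescan"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}")


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


def _check_bounds(f: Feature, contig_lengths: dict[str, int] | None) -> None:
    if contig_lengths is not None:
        length = contig_lengths.get(f.contig_id)
        if length is not None and f.end > length:
            raise ValueError(
                f"feature [{f.start},{f.end}) exceeds contig {f.contig_id} "
                f"length {length}")


def write_gff3(features: Sequence[Feature], path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3 (1-based inclusive; attributes joined with ';')."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            _check_bounds(f, contig_lengths)
            g_start, g_end = to_gff3_coords(f.start, f.end)
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write("\t".join([f.contig_id, f.source, f.type, str(g_start),
                                str(g_end), score, f.strand, ".", attrs]) + "\n")


def write_bed(features: Sequence[Feature], path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write features as BED6 (0-based half-open, as stored internally)."""
    with open(path, "w") as fh:
        for f in features:
            _check_bounds(f, contig_lengths)
            name = str(f.attributes.get("Name", f.attributes.get("ID", f.type)))
            score = "0" if f.score is None else f"{f.score:g}"
            strand = f.strand if f.strand in "+-" else "."
            fh.write("\t".join([f.contig_id, str(f.start), str(f.end),
                                name, score, strand]) + "\n")


def read_bed(path: str | Path) -> list[Feature]:
    """Read a BED6 (or BED3+) file back into features."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "region"
            score = float(parts[4]) if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(Feature(contig, start, end, type="region", strand=strand,
                                 score=score, attributes={"Name": name}))
    return feats


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
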