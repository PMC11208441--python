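"""Shared domain types and standard-format I/O for linear ECE genomes.

Coordinates are 0-based half-open everywhere inside the package. GFF3 is
written 1-based inclusive and BED 0-based half-open, following the format
standards. The ambiguity code ``N`` contributes to genome length but never
matches in repeat, ITR or motif scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A CDS on a linear genome; ``ordinal`` is its rank in gene order."""

    id: str
    start: int
    end: int
    strand: str
    ordinal: int = -1
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ITRAnnotation:
    """Inverted terminal repeat: left arm starts at 0, right arm ends at L."""

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    arm_length: int
    identity: float


@dataclass
class LinearGenome:
    id: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    itr: Optional[ITRAnnotation] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("empty genome")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in {self.id}: {sorted(bad)}")
        self._sort_and_rank_genes()

    def _sort_and_rank_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end))
        for i, g in enumerate(self.genes):
            if g.end > len(self.sequence):
                raise ValueError(f"gene {g.id} extends past genome end")
            g.ordinal = i

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        """GC fraction over unambiguous bases."""
        s = self.sequence
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        return gc / acgt if acgt else 0.0


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED / TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta-2line" if width == 0 else "fasta")


def read_gff3(path: str | Path) -> dict[str, list[GeneModel]]:
    """Read CDS features from a GFF3 file, grouped by seqid.

    Only the fields this package writes are interpreted (CDS rows with an
    ``ID=`` attribute); other feature types and comment lines are skipped.
    """
    genes: dict[str, list[GeneModel]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            seqid, _, _, start, end, _, strand, _, attrs = parts[:9]
            gid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
            g = GeneModel(id=gid or f"{seqid}_{start}", start=int(start) - 1,
                          end=int(end), strand=strand)
            genes.setdefault(seqid, []).append(g)
    for glist in genes.values():
        glist.sort(key=lambda g: (g.start, g.end))
        for i, g in enumerate(glist):
            g.ordinal = i
    return genes


def write_gff3(genomes: Iterable[LinearGenome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome in genomes:
            fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
            for g in genome.genes:
                fh.write(
                    f"{genome.id}\tborgtools\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.id}\n"
                )


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end, name, score, strand = (tuple(row) + (".", 0, "+"))[:6]
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Fallback ORF caller
# ---------------------------------------------------------------------------

def _orfs_one_strand(seq: str, min_aa: int, strand: str, L: int) -> list[tuple[int, int, str]]:
    """Longest ORF per stop on one strand; returns genome-frame intervals."""
    out = []
    for frame in range(3):
        start_codon = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start_codon = None  # ambiguity breaks the reading run
                continue
            if codon in STOP_CODONS:
                if start_codon is not None and (i + 3 - start_codon) // 3 >= min_aa:
                    out.append((start_codon, i + 3))
                start_codon = None
            elif start_codon is None and codon in START_CODONS:
                start_codon = i
    if strand == "+":
        return [(s, e, "+") for s, e in out]
    # mirror coordinates back to the forward strand
    return [(L - e, L - s, "-") for s, e in out]


def call_orfs(genome: LinearGenome, min_aa: int = 33) -> list[GeneModel]:
    """Six-frame ORF scan (fallback when no external gene calls exist).

    Uses a longest-ORF-per-stop heuristic with ATG/GTG/TTG starts, suited to
    archaeal start-codon usage but explicitly approximate. ORFs run from the
    first start codon after the previous stop to the next stop (inclusive)
    and must span at least ``min_aa`` codons.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    seq = genome.sequence
    if not seq:
        raise ValueError("empty genome")
    hits = _orfs_one_strand(seq, min_aa, "+", len(seq))
    hits += _orfs_one_strand(revcomp(seq), min_aa, "-", len(seq))
    hits.sort()
    genes = []
    for i, (s, e, strand) in enumerate(hits):
        sub = seq[s:e] if strand == "+" else revcomp(seq[s:e])
        prot = str(Seq(sub[:-3]).translate(table=11))
        genes.append(GeneModel(id=f"{genome.id}_orf{i:05d}", start=s, end=e,
                               strand=strand, ordinal=i, protein=prot))
    return genes


__all__ = [
    "DNA_ALPHABET", "GeneModel", "ITRAnnotation", "LinearGenome", "revcomp",
    "read_fasta", "write_fasta", "read_gff3", "write_gff3", "write_bed",
    "call_orfs", "START_CODONS", "STOP_CODONS",
]
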