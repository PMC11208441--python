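"""Protein pangenome: all-vs-all similarity, subfamily clustering, marker
classes, shared-content matrices, and multiheme-cytochrome motif scanning.

The similarity search is a k-mer prefilter followed by Smith-Waterman local
alignment (BLOSUM62, affine gaps) with a Karlin-Altschul-style expectation
value; retained edges need significance <= 0.001 and coverage >= 0.5 of the
shorter sequence. Subfamilies come from a deterministic greedy set-cover
over the similarity graph. A subfamily is a *marker* when it occurs exactly
once in every genome of the cohort, a *near marker* when it occurs once in
all but one genome, and *multicopy core* when present in every genome with
at least one genome carrying two or more copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

# gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge (a <-> b)."""

    a: str
    b: str
    score: float          # bit-score-like value
    significance: float   # expectation value
    coverage: float       # aligned fraction of the shorter sequence


@dataclass
class Subfamily:
    id: str
    representative: str
    members: list[str]
    copy_counts: dict[str, int] = field(default_factory=dict)
    cls: Optional[str] = None   # marker | near_marker | multicopy_core | accessory


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def bit_score(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / _LN2


def expect_value(raw_score: float, m: int, n: int) -> float:
    return m * n * math.pow(2.0, -bit_score(raw_score))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_pair(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
               ) -> tuple[float, float, float]:
    """Local alignment of two proteins -> (bit score, e-value, coverage)."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)
    best = aln[0]
    raw = best.score
    spans = best.aligned
    short = min(len(a), len(b))
    idx = 0 if len(a) <= len(b) else 1
    covered = sum(e - s for s, e in spans[idx])
    return bit_score(raw), expect_value(raw, len(a), len(b)), covered / short


def pairwise_similarity(proteins: dict[str, str], max_significance: float = 0.001,
                        min_cover: float = 0.5, k: int = 5,
                        min_shared_kmers: int = 2) -> list[SimilarityEdge]:
    """All-vs-all protein similarity edges passing the e-value/cover filter.

    Candidate pairs must share at least ``min_shared_kmers`` distinct k-mers
    before alignment is attempted; one undirected edge is emitted per
    retained pair.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    for pid, seq in proteins.items():
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in record {pid}")

    kmer_sets = {pid: _kmers(seq.upper(), k) for pid, seq in proteins.items()}
    bucket: dict[str, list[str]] = {}
    for pid, kms in kmer_sets.items():
        for km in kms:
            bucket.setdefault(km, []).append(pid)
    shared: dict[tuple[str, str], int] = {}
    for pids in bucket.values():
        if len(pids) < 2:
            continue
        for x, y in combinations(sorted(pids), 2):
            shared[(x, y)] = shared.get((x, y), 0) + 1

    aligner = _make_aligner()
    edges = []
    for (x, y), n_shared in sorted(shared.items()):
        if n_shared < min_shared_kmers:
            continue
        bits, ev, cov = align_pair(proteins[x].upper(), proteins[y].upper(), aligner)
        if ev <= max_significance and cov >= min_cover:
            edges.append(SimilarityEdge(a=x, b=y, score=bits, significance=ev,
                                        coverage=cov))
    return edges


# ---------------------------------------------------------------------------
# Greedy set-cover clustering
# ---------------------------------------------------------------------------

def cluster_subfamilies(proteins: Iterable[str],
                        edges: Iterable[SimilarityEdge]) -> list[Subfamily]:
    """Partition proteins into subfamilies by greedy set cover.

    Repeatedly pick the uncovered protein with the most uncovered neighbours
    as representative (ties: higher total degree, then lexicographically
    smaller id); it and its uncovered neighbours form a new subfamily.
    Singletons become singleton subfamilies. Deterministic and independent of
    input order.
    """
    ids = sorted(set(proteins))
    adj: dict[str, set[str]] = {pid: set() for pid in ids}
    for e in edges:
        if e.a == e.b:
            continue
        adj[e.a].add(e.b)
        adj[e.b].add(e.a)

    covered: set[str] = set()
    subfams: list[Subfamily] = []
    remaining = set(ids)
    while remaining:
        rep = max(remaining,
                  key=lambda p: (len(adj[p] - covered), len(adj[p]),
                                 _NegStr(p)))
        members = sorted({rep} | (adj[rep] - covered))
        covered.update(members)
        remaining.difference_update(members)
        subfams.append(Subfamily(id="", representative=rep, members=members))
    subfams.sort(key=lambda s: (-len(s.members), s.representative))
    for i, sf in enumerate(subfams):
        sf.id = f"subfam{i:04d}"
    return subfams


class _NegStr(str):
    """Inverts string comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Marker classification and shared-content matrix
# ---------------------------------------------------------------------------

def classify_subfamilies(subfams: list[Subfamily], protein_genome: dict[str, str],
                         genomes: list[str]) -> tuple[list[Subfamily], dict]:
    """Assign marker classes from per-genome copy counts and build a census.

    The census reports class totals and the fraction of proteins with at
    least one homolog in another genome (i.e. membership in a subfamily that
    spans >=2 genomes).
    """
    if not genomes:
        raise ValueError("empty genome set")
    n_genomes = len(genomes)
    n_proteins = 0
    n_with_homolog = 0
    for sf in subfams:
        counts = {g: 0 for g in genomes}
        for pid in sf.members:
            counts[protein_genome[pid]] += 1
        sf.copy_counts = counts
        present = sum(c > 0 for c in counts.values())
        singles = sum(c == 1 for c in counts.values())
        if present == n_genomes and singles == n_genomes:
            sf.cls = "marker"
        elif present == n_genomes - 1 and singles == n_genomes - 1:
            sf.cls = "near_marker"
        elif present == n_genomes and any(c >= 2 for c in counts.values()):
            sf.cls = "multicopy_core"
        else:
            sf.cls = "accessory"
        n_proteins += len(sf.members)
        if len({protein_genome[p] for p in sf.members}) >= 2:
            n_with_homolog += len(sf.members)
    census = {
        "n_subfamilies": len(subfams),
        "n_proteins": n_proteins,
        "marker": sum(sf.cls == "marker" for sf in subfams),
        "near_marker": sum(sf.cls == "near_marker" for sf in subfams),
        "multicopy_core": sum(sf.cls == "multicopy_core" for sf in subfams),
        "accessory": sum(sf.cls == "accessory" for sf in subfams),
        "fraction_with_homolog": (n_with_homolog / n_proteins) if n_proteins else 0.0,
    }
    census["core"] = census["marker"] + census["near_marker"] + census["multicopy_core"]
    return subfams, census


def shared_subfamily_matrix(subfams: list[Subfamily],
                            genomes: list[str]) -> pd.DataFrame:
    """Symmetric genome x genome matrix of shared subfamily counts; the
    diagonal counts subfamilies present in that genome."""
    mat = pd.DataFrame(0, index=genomes, columns=genomes, dtype=int)
    for sf in subfams:
        present = [g for g in genomes if sf.copy_counts.get(g, 0) > 0]
        for ga in present:
            for gb in present:
                mat.loc[ga, gb] += 1
    return mat


# ---------------------------------------------------------------------------
# Heme-binding motifs (multiheme cytochromes)
# ---------------------------------------------------------------------------

def scan_heme_motifs(protein: str, max_spacing: int = 30) -> dict:
    """Count heme-binding motifs: canonical CxxCH and non-canonical CXnCH.

    Each cysteine anchor contributes at most one motif, at the smallest
    spacing n (residues between the two cysteines) with 2 <= n <= 30;
    n = 2 is canonical, n > 2 non-canonical. A protein with >=3 canonical
    motifs counts as a multiheme cytochrome (MHC).
    """
    s = protein.upper()
    canonical = 0
    noncanonical: list[tuple[int, int]] = []
    for i, ch in enumerate(s):
        if ch != "C":
            continue
        for n in range(2, max_spacing + 1):
            j = i + 1 + n
            if j + 1 >= len(s):
                break
            if s[j] == "C" and s[j + 1] == "H":
                if n == 2:
                    canonical += 1
                else:
                    noncanonical.append((n, i))
                break
    return {"canonical_count": canonical, "noncanonical": noncanonical,
            "is_mhc": canonical >= 3}


__all__ = [
    "SimilarityEdge", "Subfamily", "pairwise_similarity", "align_pair",
    "cluster_subfamilies", "classify_subfamilies", "shared_subfamily_matrix",
    "scan_heme_motifs", "bit_score", "expect_value",
]
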