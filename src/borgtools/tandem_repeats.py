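"""Exact tandem-repeat detection in nucleotide and amino-acid space.

A tandem-repeat (TR) region is a maximal run of consecutive exact copies of
a unit, reported at its smallest (fundamental) period, with no mismatches
allowed. Nucleotide arrays must span >=50 nt with >=3 units; amino-acid
arrays >=16 residues with >=3 units. Partial trailing units extend the
region but do not count as units. ``N`` (nt) and ``X`` (aa) never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome_io import GeneModel, LinearGenome

MAX_PERIOD_NT = 1000
MAX_PERIOD_AA = 200


@dataclass
class TandemRepeatRegion:
    genome_id: str
    interval: tuple[int, int]
    unit: str
    unit_length: int
    unit_count: int
    total_length: int
    space: str                       # nt | aa
    context: Optional[str] = None    # intergenic | in_orf | overlapping
    gene_id: Optional[str] = None

    @property
    def canonical_unit(self) -> str:
        """Lexicographically least rotation of the unit (array identity)."""
        u = self.unit
        return min(u[i:] + u[:i] for i in range(len(u)))


@dataclass
class TRSummary:
    genome_id: str
    genome_length: int
    n_regions: int
    regions_per_100kbp: float
    total_tr_length: int
    tr_percent: float
    total_unit_count: int
    n_intergenic: int
    n_in_orf: int
    n_overlapping: int


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _find_trs(s: str, min_region: int, min_units: int, max_period: int,
              wildcard: str, space: str, genome_id: str) -> list[TandemRepeatRegion]:
    n = len(s)
    if n < min_region:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    wc = ord(wildcard)
    regions: list[TandemRepeatRegion] = []
    accepted: list[tuple[int, int]] = []   # intervals of smaller-period regions
    max_p = min(max_period, n - 1)
    for p in range(1, max_p + 1):
        left, right = arr[:-p], arr[p:]
        match = (left == right) & (left != wc)
        if not match.any():
            continue
        # maximal runs of True
        padded = np.concatenate([[False], match, [False]]).astype(np.int8)
        diff = np.diff(padded)
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]
        for i, j in zip(run_starts, run_ends):
            start, end = int(i), int(j) + p   # region [start, end)
            total = end - start
            units = total // p
            if total < min_region or units < min_units:
                continue
            # suppress harmonics: a smaller-period region already covers this
            if any(a <= start and end <= b for a, b in accepted):
                continue
            accepted.append((start, end))
            regions.append(TandemRepeatRegion(
                genome_id=genome_id, interval=(start, end),
                unit=s[start : start + p], unit_length=p, unit_count=units,
                total_length=total, space=space))
    regions.sort(key=lambda r: r.interval)
    return regions


def find_nt_trs(seq: str | LinearGenome, min_region: int = 50, min_units: int = 3,
                max_period: int = MAX_PERIOD_NT) -> list[TandemRepeatRegion]:
    """Exact nucleotide tandem arrays (>=50 nt span, >=3 units by default)."""
    if isinstance(seq, LinearGenome):
        gid, s = seq.id, seq.sequence
    else:
        gid, s = "", seq.upper()
    return _find_trs(s, min_region, min_units, max_period, "N", "nt", gid)


def find_aa_trs(protein: str, min_region: int = 16, min_units: int = 3,
                max_period: int = MAX_PERIOD_AA,
                protein_id: str = "") -> list[TandemRepeatRegion]:
    """Exact amino-acid tandem arrays (>=16 aa span, >=3 units by default)."""
    return _find_trs(protein.upper(), min_region, min_units, max_period, "X",
                     "aa", protein_id)


# ---------------------------------------------------------------------------
# Genic context and per-genome summary
# ---------------------------------------------------------------------------

def classify_tr_context(regions: list[TandemRepeatRegion],
                        genes: list[GeneModel]) -> list[TandemRepeatRegion]:
    """Label each nt region in_orf / intergenic / overlapping against CDS."""
    for r in regions:
        s, e = r.interval
        r.context = "intergenic"
        r.gene_id = None
        for g in genes:
            if g.start <= s and e <= g.end:
                r.context = "in_orf"
                r.gene_id = g.id
                break
            if s < g.end and g.start < e:
                r.context = "overlapping"
                r.gene_id = g.id
                # keep scanning: a later gene may fully contain the region
    return regions


def summarize_tr(genome: LinearGenome, regions: list[TandemRepeatRegion],
                 fold_overlapping: bool = False) -> TRSummary:
    """Per-genome TR statistics (counts, density per 100 kbp, percent of
    genome in TR). Regions straddling a CDS edge are counted separately by
    default; ``fold_overlapping`` folds them into the in-ORF count.
    """
    L = genome.length
    n = len(regions)
    total_len = sum(r.total_length for r in regions)
    n_inter = sum(r.context == "intergenic" for r in regions)
    n_orf = sum(r.context == "in_orf" for r in regions)
    n_over = sum(r.context == "overlapping" for r in regions)
    if fold_overlapping:
        n_orf += n_over
        n_over = 0
    return TRSummary(
        genome_id=genome.id, genome_length=L, n_regions=n,
        regions_per_100kbp=round(n / (L / 100_000), 2),
        total_tr_length=total_len,
        tr_percent=round(100.0 * total_len / L, 2),
        total_unit_count=sum(r.unit_count for r in regions),
        n_intergenic=n_inter, n_in_orf=n_orf, n_overlapping=n_over)


__all__ = [
    "TandemRepeatRegion", "TRSummary", "find_nt_trs", "find_aa_trs",
    "classify_tr_context", "summarize_tr", "MAX_PERIOD_NT", "MAX_PERIOD_AA",
]
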