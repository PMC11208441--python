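"""Methylation-motif statistics and naive motif enrichment.

Borg genomes carry pervasive YC (Y = C/T) cytosine-modification motifs at
~184-192 occurrences per kbp (both strands) that fall predominantly (71%)
on the non-coding (template) strand of genes. This module counts IUPAC
motif occurrences on both strands, partitions genic occurrences by strand
relative to the overlapping gene, and recovers minimal motifs from called
modified-base positions by per-position composition tests against the
genome background (emulating the removal of extraneous flanking bases).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .genome_io import GeneModel, LinearGenome, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES = "ACGT"
_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}


@dataclass
class MotifStats:
    motif: str
    count_fwd: int
    count_rev: int
    genome_length: int

    @property
    def density_per_kbp(self) -> float:
        return (self.count_fwd + self.count_rev) / (self.genome_length / 1000.0)


@dataclass
class ModifiedSiteSet:
    genome_id: str
    sites: list[tuple[int, str, float]]    # (position, strand, score)


def _motif_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(f"[{IUPAC[c]}]" for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"not an IUPAC code: {exc.args[0]}") from exc
    return re.compile(f"(?=({body}))")     # lookahead: overlapping matches


def find_motif_occurrences(seq: str, motif: str) -> list[tuple[int, int, str]]:
    """All (start, end, strand) occurrences of an IUPAC motif, both strands,
    in forward-strand coordinates. Ambiguous genome bases (N) never match."""
    if not motif:
        raise ValueError("empty motif")
    pat = _motif_regex(motif)
    L, w = len(seq), len(motif)
    occ = [(m.start(), m.start() + w, "+") for m in pat.finditer(seq)]
    occ += [(L - m.start() - w, L - m.start(), "-")
            for m in pat.finditer(revcomp(seq))]
    occ.sort()
    return occ


def count_motif_occurrences(genome: LinearGenome | str, motif: str) -> MotifStats:
    """Both-strand occurrence counts and density per kbp of genome."""
    seq = genome.sequence if isinstance(genome, LinearGenome) else genome.upper()
    occ = find_motif_occurrences(seq, motif)
    fwd = sum(o[2] == "+" for o in occ)
    return MotifStats(motif=motif.upper(), count_fwd=fwd, count_rev=len(occ) - fwd,
                      genome_length=len(seq))


def strand_partition(genome: LinearGenome, motif: str,
                     genes: Optional[list[GeneModel]] = None) -> float:
    """Fraction of genic motif occurrences on the non-coding (template)
    strand: an occurrence inside a gene is *coding-strand* when its strand
    equals the gene's strand. Intergenic occurrences are excluded.
    """
    genes = genes if genes is not None else genome.genes
    if not genes:
        raise ValueError("no genes")
    occ = find_motif_occurrences(genome.sequence, motif)
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    strands = np.array([g.strand for g in genes])
    coding = noncoding = 0
    pos = np.array([o[0] for o in occ])
    end = np.array([o[1] for o in occ])
    ostr = np.array([o[2] for o in occ])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (end <= ends[np.clip(idx, 0, None)])
    same = ostr[ok] == strands[idx[ok]]
    coding = int(same.sum())
    noncoding = int((~same).sum())
    if coding + noncoding == 0:
        raise ValueError("no genic motif occurrences")
    return noncoding / (coding + noncoding)


# ---------------------------------------------------------------------------
# Motif enrichment from modified-base calls
# ---------------------------------------------------------------------------

def _depleted(obs: int, n: int, p0: float, alpha: float) -> bool:
    """One-sided two-proportion-style z-test: observed share below background."""
    if n == 0:
        return False
    phat = obs / n
    se = np.sqrt(p0 * (1 - p0) / n)
    if se == 0:
        return phat < p0
    return norm.cdf((phat - p0) / se) < alpha


def enrich_motifs(sites: ModifiedSiteSet, genome: LinearGenome | str,
                  k_max: int = 6, alpha: float = 0.01,
                  min_sites: int = 100, min_group_fraction: float = 0.1,
                  max_sites: int = 1500) -> list[dict]:
    """Recover minimal methylation motifs from modified-base positions.

    Site contexts (windows of +-(k_max-1) bases on the called strand) are
    grouped by the base at the modified position; within each group, every
    flanking position is tested base-by-base against an empirical background
    (one-sided depletion test, Bonferroni-corrected at ``alpha``). The
    background is estimated from the two outermost window positions on each
    side, which conditions it on the strand/region composition the sites
    actually come from (a genome-wide background would mis-call flanks on
    strand-asymmetric genomes). Positions with no significantly depleted
    base are extraneous and dropped; the contiguous constrained positions
    around the modified base, with their surviving base sets collapsed to
    IUPAC codes, form the reported motif. Uniform random sites therefore
    yield no motif at all.

    Returns motifs ranked by observed/expected enrichment, each a dict with
    keys motif, modified_offset, n_sites, enrichment.
    """
    seq = genome.sequence if isinstance(genome, LinearGenome) else genome.upper()
    if len(sites.sites) < min_sites:
        raise ValueError(f"need at least {min_sites} modified sites")
    radius = k_max - 1
    contexts = []
    for pos, strand, _score in sites.sites:
        if pos - radius < 0 or pos + radius + 1 > len(seq):
            continue
        win = seq[pos - radius : pos + radius + 1]
        if "N" in win:
            continue
        contexts.append(win if strand == "+" else revcomp(win))
    if len(contexts) < min_sites:
        raise ValueError("too few usable site contexts")
    if len(contexts) > max_sites:
        # even subsample: keeps the composition tests calibrated against the
        # mononucleotide background (local dinucleotide structure would reach
        # spurious significance at very large n)
        step = len(contexts) / max_sites
        contexts = [contexts[int(i * step)] for i in range(max_sites)]

    width = 2 * radius + 1
    # empirical background from the outermost flank positions of the windows
    flank_positions = [0, 1, width - 2, width - 1]
    pool = [c[q] for c in contexts for q in flank_positions]
    bg = {b: max(pool.count(b) / len(pool), 1e-6) for b in _BASES}
    n_tests = 4 * width          # Bonferroni over all (position, base) tests
    a_corr = alpha / n_tests

    # is the modified position itself constrained at all?
    center_counts = {b: sum(c[radius] == b for c in contexts) for b in _BASES}
    if not any(_depleted(center_counts[b], len(contexts), bg[b], a_corr)
               for b in _BASES):
        return []

    results = []
    for center_base in _BASES:
        group = [c for c in contexts if c[radius] == center_base]
        if len(group) < max(20, min_group_fraction * len(contexts)):
            continue
        n = len(group)
        allowed: list[Optional[frozenset]] = []
        for q in range(width):
            counts = {b: sum(c[q] == b for c in group) for b in _BASES}
            depleted = {b for b in _BASES if _depleted(counts[b], n, bg[b], a_corr)}
            allowed.append(frozenset(_BASES) - depleted if depleted else None)
        # contiguous constrained run through the modified position
        lo = hi = radius
        while lo > 0 and allowed[lo - 1] is not None:
            lo -= 1
        while hi < width - 1 and allowed[hi + 1] is not None:
            hi += 1
        if allowed[radius] is None:
            continue
        motif = "".join(_TO_IUPAC[allowed[q]] for q in range(lo, hi + 1))
        expected = float(np.prod([sum(bg[b] for b in allowed[q])
                                  for q in range(lo, hi + 1)]))
        matched = sum(all(c[q] in allowed[q] for q in range(lo, hi + 1))
                      for c in group)
        results.append({
            "motif": motif,
            "modified_offset": radius - lo,
            "n_sites": n,
            "enrichment": (matched / n) / expected if expected > 0 else np.inf,
        })
    results.sort(key=lambda r: -r["enrichment"])
    return results


__all__ = ["IUPAC", "MotifStats", "ModifiedSiteSet", "find_motif_occurrences",
           "count_motif_occurrences", "strand_partition", "enrich_motifs"]
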