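"""Genome architecture: GC skew, replichore partition, ITR detection, QC flags.

Borg-type elements are linear, replicate from their termini, and show a GC
skew (G-C)/(G+C) whose cumulative sum reaches its extremum where the two
replication forks meet — the boundary between the two unequal replichores.
Each replichore carries nearly all its genes on a single strand. Genomes are
terminated by kilobase-scale inverted terminal repeats (ITR). Assembly
artifacts show up as abrupt GC jumps (chimeric joins) or mirror-image blocks
(off-diagonal self-matches from whole-genome amplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np

from .genome_io import ITRAnnotation, LinearGenome, revcomp

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 1000

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SkewProfile:
    window: int
    step: int
    positions: np.ndarray          # window start coordinates (bp)
    gc: np.ndarray                 # GC fraction per window
    skew: np.ndarray               # (G-C)/(G+C), 0 where G+C = 0
    cumulative: np.ndarray         # running sum of skew

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ReplichorePartition:
    switch_point: int
    replichores: tuple[tuple[int, int], tuple[int, int]]
    origins: tuple[int, int]
    coding_fraction: tuple[float, float]
    majority_strand: tuple[str, str]


@dataclass
class QCFlag:
    kind: str                      # gc_jump | mirror_block
    interval: tuple[int, int]
    score: float
    partner: Optional[tuple[int, int]] = None


# ---------------------------------------------------------------------------
# GC and skew profiles
# ---------------------------------------------------------------------------

def _base_counts(seq: str, window: int, step: int) -> tuple[np.ndarray, ...]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    starts = np.arange(0, L - window + 1, step)
    g_cum = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    c_cum = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    at_cum = np.concatenate([[0], np.cumsum((arr == ord("A")) | (arr == ord("T")))])
    ends = starts + window
    g = g_cum[ends] - g_cum[starts]
    c = c_cum[ends] - c_cum[starts]
    at = at_cum[ends] - at_cum[starts]
    return starts, g, c, at


def gc_skew_profile(genome: LinearGenome | str, window: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP) -> SkewProfile:
    """Windowed GC fraction, GC skew and cumulative skew.

    Windows are placed every ``step`` bp while they fit entirely within the
    genome. Skew of a window with no G or C is defined as 0 so the cumulative
    sum stays continuous.
    """
    seq = genome.sequence if isinstance(genome, LinearGenome) else genome
    if not 0 < step <= window:
        raise ValueError("require 0 < step <= window")
    if window > len(seq):
        raise ValueError("window exceeds genome")
    starts, g, c, at = _base_counts(seq, window, step)
    gc_tot = g + c
    denom = np.maximum(gc_tot + at, 1)
    gc = gc_tot / denom
    skew = np.where(gc_tot > 0, (g - c) / np.maximum(gc_tot, 1), 0.0)
    return SkewProfile(window=window, step=step, positions=starts, gc=gc,
                       skew=skew, cumulative=np.cumsum(skew))


def partition_replichores(genome: LinearGenome, profile: SkewProfile) -> ReplichorePartition:
    """Split the genome at the cumulative-skew extremum into two replichores.

    The switch point is the interior global extremum of |cumulative skew|
    (first and last windows excluded); ties are broken toward the genome
    midpoint. Per-replichore coding fractions are computed from gene strands,
    assigning genes by midpoint.
    """
    if not genome.genes:
        raise ValueError("no genes")
    if len(profile) < 3:
        raise ValueError("profile too short to have an interior extremum")
    cum = np.abs(profile.cumulative[1:-1])
    best = cum.max()
    candidates = np.nonzero(cum == best)[0] + 1
    mid = genome.length / 2
    centres = profile.positions[candidates] + profile.window / 2
    idx = candidates[np.argmin(np.abs(centres - mid))]
    switch = int(profile.positions[idx] + profile.window)
    switch = min(max(switch, 1), genome.length - 1)

    halves = ((0, switch), (switch, genome.length))
    fracs, strands = [], []
    for lo, hi in halves:
        plus = minus = 0
        for g in genome.genes:
            gm = (g.start + g.end) // 2
            if lo <= gm < hi:
                plus += g.strand == "+"
                minus += g.strand == "-"
        tot = plus + minus
        if tot == 0:
            fracs.append(float("nan"))
            strands.append("+")
        else:
            strands.append("+" if plus >= minus else "-")
            fracs.append(max(plus, minus) / tot)
    return ReplichorePartition(switch_point=switch, replichores=halves,
                               origins=(0, genome.length),
                               coding_fraction=(fracs[0], fracs[1]),
                               majority_strand=(strands[0], strands[1]))


# ---------------------------------------------------------------------------
# Inverted terminal repeats
# ---------------------------------------------------------------------------

_EDIT_PENALTY = 4  # score = matches - penalty*edits; random extension loses


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def detect_itr(genome: LinearGenome | str, min_arm: int = 500,
               max_mismatch_frac: float = 0.05) -> Optional[ITRAnnotation]:
    """Detect an inverted terminal repeat by prefix-vs-suffix extension.

    Compares the genome prefix with the reverse complement of its suffix and
    extends the arm to the length maximising an alignment score
    (match +1, edit -4, banded edit distance via edlib), i.e. the arm stops
    where sequence similarity ends rather than where the error budget is
    exhausted. Returns None unless the best arm is at least ``min_arm`` long
    with identity >= 1 - max_mismatch_frac.
    """
    seq = genome.sequence if isinstance(genome, LinearGenome) else genome
    if min_arm < 100:
        raise ValueError("min_arm must be >= 100")
    L = len(seq)
    span = L // 2
    if span < min_arm:
        return None
    prefix = seq[:span]
    suffix_rc = revcomp(seq[L - span:])

    grid = max(8, min_arm // 20)

    def score(n: int) -> tuple[float, int]:
        d = _edit_distance(prefix[:n], suffix_rc[:n])
        return n - _EDIT_PENALTY * d, d

    best_n, best_s = 0, -1.0
    stale = 0
    for n in range(grid, span + 1, grid):
        s, _ = score(n)
        if s > best_s:
            best_s, best_n, stale = s, n, 0
        else:
            stale += 1
            if stale * grid > max(4 * min_arm, 8000):
                break
    if best_n == 0:
        return None
    # refine around the best grid point one base at a time
    lo = max(1, best_n - grid)
    hi = min(span, best_n + grid)
    for n in range(lo, hi + 1):
        s, _ = score(n)
        if s > best_s:
            best_s, best_n = s, n
    _, d = score(best_n)
    identity = 1 - d / best_n
    if best_n < min_arm or identity < 1 - max_mismatch_frac:
        return None
    return ITRAnnotation(left_arm=(0, best_n), right_arm=(L - best_n, L),
                         arm_length=best_n, identity=identity)


# ---------------------------------------------------------------------------
# Curation QC: GC jumps and mirror-image blocks
# ---------------------------------------------------------------------------

def detect_gc_jumps(profile: SkewProfile, delta_threshold: float = 8.0) -> list[QCFlag]:
    """Flag window boundaries where GC content jumps by more than
    ``delta_threshold`` percentage points; adjacent flagged boundaries merge.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    deltas = np.abs(np.diff(profile.gc)) * 100.0
    hot = np.nonzero(deltas > delta_threshold)[0]
    flags: list[QCFlag] = []
    for i in hot:
        start = int(profile.positions[i] + profile.window)
        end = int(profile.positions[i + 1] + profile.window)
        score = float(deltas[i])
        if flags and flags[-1].interval[1] >= start:
            prev = flags[-1]
            flags[-1] = QCFlag("gc_jump", (prev.interval[0], end),
                               max(prev.score, score))
        else:
            flags.append(QCFlag("gc_jump", (start, end), score))
    return flags


def _match_rc(x: str, y: str) -> bool:
    return x != "N" and _COMP[x] == y


def detect_mirror_blocks(seq: str, min_block: int = 200,
                         itr: Optional[ITRAnnotation] = None,
                         k: int = 32) -> list[QCFlag]:
    """Find exact off-diagonal self-matches: intervals whose reverse
    complement occurs elsewhere in the same sequence (length >= min_block).

    Seeds on shared k-mers between the sequence and its reverse complement,
    extends each seed to a maximal exact block, and reports one flag per
    (block, mirrored partner) pair. Arms of an annotated ITR are excluded —
    they are genuine architecture, not an amplification artifact.
    """
    if min_block < 50:
        raise ValueError("min_block must be >= 50")
    L = len(seq)
    if L < 2 * k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(0, L - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)

    seen: set[tuple[int, int, int, int]] = set()
    flags: list[QCFlag] = []
    for j in range(0, L - k + 1, max(1, k // 2)):
        window = seq[j : j + k]
        if "N" in window:
            continue
        rc = revcomp(window)
        for i in index.get(rc, ()):  # seq[i:i+k] == revcomp(seq[j:j+k])
            a1, a2, b1, b2 = i, i + k, j, j + k
            # extend right of A while it mirrors left of B
            while a2 < L and b1 > 0 and _match_rc(seq[a2], seq[b1 - 1]):
                a2 += 1
                b1 -= 1
            # extend left of A while it mirrors right of B
            while a1 > 0 and b2 < L and _match_rc(seq[a1 - 1], seq[b2]):
                a1 -= 1
                b2 += 1
            if a1 > b1 or (a1 == b1 and a2 > b2):
                a1, a2, b1, b2 = b1, b2, a1, a2
            if b1 < a2:
                # the two blocks overlap: the combined span is one palindrome;
                # report its two halves as the mirror pair
                lo, hi = min(a1, b1), max(a2, b2)
                mid = (lo + hi) // 2
                a1, a2, b1, b2 = lo, mid, mid, hi
            if a2 - a1 < min_block:
                continue
            key = (a1, a2, b1, b2)
            if key in seen:
                continue
            seen.add(key)
            if itr is not None:
                slop = 50
                arm = itr.arm_length
                if a2 <= arm + slop and b1 >= L - arm - slop:
                    continue
            flags.append(QCFlag("mirror_block", (a1, a2), float(a2 - a1),
                                partner=(b1, b2)))
    flags.sort(key=lambda f: (f.interval, f.partner))
    return flags


__all__ = [
    "SkewProfile", "ReplichorePartition", "QCFlag", "gc_skew_profile",
    "partition_replichores", "detect_itr", "detect_gc_jumps",
    "detect_mirror_blocks", "DEFAULT_WINDOW", "DEFAULT_STEP",
]
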