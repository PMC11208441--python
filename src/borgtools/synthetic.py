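"""Synthetic linear-ECE cohorts with known ground truth.

Generates Borg-like genomes whose every planted feature — inverted terminal
repeats, replichore structure with single-strand coding, exact tandem
repeats, high-GC host-derived islands, marker-family backbone, YC-type
methylation composition and host-correlated coverage — is recorded in a
truth object so each detector in the pipeline can be verified round-trip.

The nucleotide background is a first-order Markov chain calibrated so that
(i) GC content matches the target (~33%), (ii) the both-strand YC
dinucleotide density matches the study-scale ~188 occurrences per kbp, and
(iii) the genic strand split of YC is ~71% on the template strand. The
coding-strand asymmetry that produces (iii) is also what yields the GC skew
that the replichore partition detects: the two halves of the genome are
generated as mirror-image chains meeting at the replication terminus.
Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

from .genome_io import GeneModel, ITRAnnotation, LinearGenome, revcomp
from .motifs import ModifiedSiteSet, find_motif_occurrences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class TRPlan:
    n_regions: int = 23
    unit_len_range: tuple[int, int] = (4, 24)
    extra_units_max: int = 5
    in_orf_fraction: float = 0.5


@dataclass
class IslandPlan:
    count: int = 2
    gc: float = 0.50
    length: int = 8000


@dataclass
class MethylPlan:
    motif: str = "YC"
    density_per_kbp: float = 188.0       # both-strand occurrences
    noncoding_bias: float = 0.71         # template-strand share in genes
    modified_offset: int = 1             # the C of YC


@dataclass
class CoveragePlan:
    n_samples: int = 83
    n_hosts: int = 6
    n_borgs: int = 8
    ratio: float = 8.8                   # Borg : host copy ratio
    noise_sigma: float = 0.1             # lognormal sd around the ratio


@dataclass
class SyntheticSpec:
    n_genomes: int = 17
    length_range: tuple[int, int] = (600_000, 1_100_000)
    gc_target: float = 0.33
    itr_length: int = 2000
    replichore_split: float = 0.7
    strand_purity: float = 0.98
    n_marker_families: int = 40
    n_near: int = 22
    n_multicopy: int = 45
    n_accessory: int = 30
    coloc_block: int = 7
    tr_plan: TRPlan = field(default_factory=TRPlan)
    high_gc_islands: IslandPlan = field(default_factory=IslandPlan)
    methylation: MethylPlan = field(default_factory=MethylPlan)
    coverage: CoveragePlan = field(default_factory=CoveragePlan)
    gene_length: int = 900
    intergenic_gap: int = 150
    family_sub_rate: float = 0.10
    protein_len_range: tuple[int, int] = (60, 140)
    sequence_model: str = "markov"       # markov | iid


@dataclass
class GenomeTruth:
    itr_arm_length: int
    switch_point: int
    majority_strands: tuple[str, str]
    tr_regions: list[dict]
    islands: list[tuple[int, int]]
    methylation: MethylPlan


@dataclass
class CohortTruth:
    family_class: dict[str, str]                 # fam id -> class
    family_members: dict[str, list[str]]         # fam id -> protein ids
    proteins: dict[str, str]                     # protein id -> sequence
    protein_genome: dict[str, str]               # protein id -> genome id
    protein_positions: dict[str, tuple[str, int]]
    block_families: list[str]
    absent_genome: dict[str, str]                # near fam -> missing genome


@dataclass
class CoverageTruth:
    raw: pd.DataFrame
    totals: dict[str, float]
    normalized: pd.DataFrame
    pairs: list[tuple[str, str]]                 # (borg, host)
    ratio: float


# ---------------------------------------------------------------------------
# Calibrated background chain
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _calibrate_chain(gc: float, density_per_kbp: float, noncoding_bias: float
                     ) -> tuple[tuple, tuple]:
    """First-order chain (A,C,G,T) whose stationary GC, both-strand YC
    density and YC:GR ratio hit the requested targets. Returns (P, pi)."""
    yc_t = noncoding_bias * density_per_kbp / 1000.0
    gr_t = (1.0 - noncoding_bias) * density_per_kbp / 1000.0
    w = np.array([(1 - gc) / 2, gc * 0.6, gc * 0.4, (1 - gc) / 2])
    gamma = 1.2
    pi = w.copy()
    for _ in range(400):
        boost = np.ones((4, 4))
        boost[1, 1] = boost[3, 1] = gamma      # C after C or T (after Y)
        P = w[None, :] * boost
        P /= P.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        q = pi[:, None] * P
        yc = q[3, 1] + q[1, 1]
        gr = q[2, 0] + q[2, 2]
        gc_cur = pi[1] + pi[2]
        if (abs(yc - yc_t) < 1e-6 and abs(gr - gr_t) < 1e-6
                and abs(gc_cur - gc) < 1e-6):
            break
        gamma *= (yc_t / yc) ** 0.5
        w[2] *= (gr_t / gr) ** 0.5
        w[1] *= (max(gc - pi[2], 1e-6) / max(pi[1], 1e-6)) ** 0.5
        w[0] = w[3] = max(1.0 - w[1] - w[2], 1e-6) / 2
        w /= w.sum()
    if abs(yc - yc_t) > 5e-4 or abs(gr - gr_t) > 5e-4 or abs(gc_cur - gc) > 5e-3:
        raise ValueError("background chain calibration failed for "
                         f"gc={gc}, density={density_per_kbp}, bias={noncoding_bias}")
    return tuple(map(tuple, P)), tuple(pi)


def _sample_chain(P: np.ndarray, pi: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    state = int(rng.choice(4, p=pi))
    c0, c1, c2 = cum[:, 0], cum[:, 1], cum[:, 2]
    for i in range(n):
        ui = u[i]
        if ui < c0[state]:
            state = 0
        elif ui < c1[state]:
            state = 1
        elif ui < c2[state]:
            state = 2
        else:
            state = 3
        out[i] = state
    return out


def _chain_targets(spec: SyntheticSpec, L: int) -> tuple[float, float, float]:
    """Background-chain (density, bias) targets compensated so the
    genome-level observables — both-strand motif density per kbp and genic
    non-coding-strand fraction — match the planted values despite dilution
    by the symmetric high-GC islands and by minority-strand genes."""
    meth = spec.methylation
    isl = spec.high_gc_islands
    frac = min(0.5, isl.count * isl.length / L)
    d_island = 1000.0 * isl.gc / 2          # iid island YC+GR density
    density = (meth.density_per_kbp - frac * d_island) / (1 - frac)
    bias = (meth.noncoding_bias - frac * 0.5) / (1 - frac)
    p = spec.strand_purity
    if p > 0.5:
        bias = (bias - (1 - p)) / (2 * p - 1)
    gc = (spec.gc_target - frac * isl.gc) / (1 - frac)
    return gc, density, min(0.95, max(0.05, bias))


def _background(spec: SyntheticSpec, n: int, rng: np.random.Generator,
                gc: float, density: float, bias: float) -> str:
    P, pi = _calibrate_chain(gc, density, bias)
    P, pi = np.array(P), np.array(pi)
    if spec.sequence_model == "iid":
        states = rng.choice(4, size=n, p=pi)
    elif spec.sequence_model == "markov":
        states = _sample_chain(P, pi, n, rng)
    else:
        raise ValueError(f"unknown sequence model {spec.sequence_model!r}")
    return _BASES[states].tobytes().decode()


def _iid_gc_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


# ---------------------------------------------------------------------------
# Single-genome generation
# ---------------------------------------------------------------------------

def _tile_genes(spec: SyntheticSpec, L: int, split: int, genome_id: str,
                rng: np.random.Generator) -> list[GeneModel]:
    pitch = spec.gene_length + spec.intergenic_gap
    genes = []
    pos = spec.intergenic_gap
    i = 0
    while pos + spec.gene_length <= L - spec.intergenic_gap:
        majority = "-" if pos < split else "+"
        minority = "+" if majority == "-" else "-"
        strand = majority if rng.random() < spec.strand_purity else minority
        genes.append(GeneModel(id=f"{genome_id}.g{i:05d}", start=pos,
                               end=pos + spec.gene_length, strand=strand,
                               ordinal=i))
        pos += pitch
        i += 1
    return genes


def _random_unit(length: int, rng: np.random.Generator) -> str:
    """A repeat unit that is its own fundamental period."""
    while True:
        unit = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if all(unit != unit[p:] + unit[:p] for p in range(1, length)):
            if len(set(unit)) > 1:
                return unit


def _break_periodicity(seq: list[str], idx: int, avoid: set[str],
                       rng: np.random.Generator) -> None:
    """Replace seq[idx] with a base not in ``avoid`` (keeps TR maximal)."""
    if not 0 <= idx < len(seq):
        return
    choices = [b for b in "ACGT" if b not in avoid]
    if seq[idx] in avoid:
        seq[idx] = choices[int(rng.integers(0, len(choices)))]


def generate_genome(spec: SyntheticSpec, seed: int,
                    genome_id: str = "synth") -> tuple[LinearGenome, GenomeTruth]:
    """One linear genome with planted ITR, replichores, TRs and islands."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    itr = spec.itr_length
    if 2 * itr + 2 * spec.high_gc_islands.count * spec.high_gc_islands.length \
            + 20_000 > L:
        raise ValueError("infeasible packing: features exceed genome length")
    split = int(spec.replichore_split * L)

    # two mirror-image replichores: fwd strand C-rich left of the terminus,
    # G-rich right of it (genes -, + respectively)
    gc, density, bias = _chain_targets(spec, L)
    left = _background(spec, split, rng, gc, density, bias)
    right = revcomp(_background(spec, L - split, rng, gc, density, bias))
    seq = list(left + right)

    # impose the ITR and pin its flanks so extension stops exactly at the arm
    arm = seq[:itr]
    seq[L - itr:] = list(revcomp("".join(arm)))
    for off in range(3):
        partner = seq[L - 1 - (itr + off)]
        comp_partner = revcomp(partner)
        _break_periodicity(seq, itr + off, {comp_partner, "N"}, rng)

    genes = _tile_genes(spec, L, split, genome_id, rng)

    # plant exact tandem repeats
    plan = spec.tr_plan
    margin = itr + 500
    taken: list[tuple[int, int]] = [(0, margin), (L - margin, L)]

    def free(a: int, b: int) -> bool:
        return all(b + 100 <= s or e + 100 <= a for s, e in taken)

    # high-GC host-derived islands
    islands = []
    isl = spec.high_gc_islands
    for _k in range(isl.count):
        for _try in range(100):
            start = int(rng.integers(margin, L - margin - isl.length))
            if free(start, start + isl.length) and not (
                    start < split < start + isl.length):
                break
        else:
            raise ValueError(
                f"infeasible packing: cannot place GC island {_k} "
                f"(L={L}, margin={margin}, island={isl.length}, "
                f"taken={sorted(taken)[:8]}...)")
        seq[start : start + isl.length] = list(
            _iid_gc_seq(isl.length, isl.gc, rng))
        taken.append((start, start + isl.length))
        islands.append((start, start + isl.length))

    # plant exact tandem repeats
    tr_truth = []
    genic = [g for g in genes if margin < g.start and g.end < L - margin]
    attempts = 0
    while len(tr_truth) < plan.n_regions and attempts < 50 * plan.n_regions:
        attempts += 1
        ulen = int(rng.integers(plan.unit_len_range[0], plan.unit_len_range[1] + 1))
        count = max(3, -(-50 // ulen)) + int(rng.integers(0, plan.extra_units_max + 1))
        span = ulen * count
        in_orf = rng.random() < plan.in_orf_fraction
        if in_orf:
            g = genic[int(rng.integers(0, len(genic)))]
            if g.length < span + 60:
                continue
            start = g.start + 30 + int(rng.integers(0, g.length - span - 60))
            context = "in_orf"
        else:
            g = genic[int(rng.integers(0, len(genic) - 1))]
            gap_lo, gap_hi = g.end + 5, g.end + spec.intergenic_gap - 5
            if gap_hi - gap_lo < span:
                continue
            start = gap_lo + int(rng.integers(0, gap_hi - gap_lo - span + 1))
            context = "intergenic"
        end = start + span
        if not free(start, end):
            continue
        unit = _random_unit(ulen, rng)
        seq[start:end] = list(unit * count)
        _break_periodicity(seq, start - 1, {seq[start - 1 + ulen], "N"}, rng)
        _break_periodicity(seq, end, {seq[end - ulen], "N"}, rng)
        taken.append((start, end))
        tr_truth.append({"interval": (start, end), "unit": unit,
                         "unit_count": count, "context": context,
                         "gene_id": g.id if context == "in_orf" else None})

    genome = LinearGenome(
        id=genome_id, sequence="".join(seq), genes=genes,
        itr=ITRAnnotation(left_arm=(0, itr), right_arm=(L - itr, L),
                          arm_length=itr, identity=1.0),
        meta={"sample": "synthetic", "status": "complete"})
    truth = GenomeTruth(itr_arm_length=itr, switch_point=split,
                        majority_strands=("-", "+"),
                        tr_regions=sorted(tr_truth, key=lambda d: d["interval"]),
                        islands=islands, methylation=spec.methylation)
    return genome, truth


def generate_modified_sites(genome: LinearGenome, motif: str = "YC",
                            modified_offset: int = 1) -> ModifiedSiteSet:
    """Modified-base calls at every occurrence of ``motif`` (both strands),
    at the given offset within the motif on the motif's strand."""
    sites = []
    w = len(motif)
    for start, end, strand in find_motif_occurrences(genome.sequence, motif):
        pos = start + modified_offset if strand == "+" else end - 1 - modified_offset
        sites.append((pos, strand, 1.0))
    return ModifiedSiteSet(genome_id=genome.id, sites=sites)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _mutate_protein(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    out = list(ancestor)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AA[int(rng.integers(0, len(_AA)))]
    return "".join(out)


class _FamilySeparator:
    """Enforces the cohort's between-family dissimilarity condition.

    Families are meant to be unrelated (between-family identity well below
    any clustering threshold); because sequences are random, rare chance
    similarities can arise. Any candidate protein sharing >=2 five-mers with
    another family is re-drawn, which caps between-family local similarity
    far below the significance thresholds of the similarity search.
    """

    K = 5

    def __init__(self) -> None:
        self._kmer_fams: dict[str, set[str]] = {}

    def _kmers(self, prot: str) -> set[str]:
        return {prot[i : i + self.K] for i in range(len(prot) - self.K + 1)}

    def conflicts(self, prot: str, fam: str) -> bool:
        counts: dict[str, int] = {}
        for km in self._kmers(prot):
            for f in self._kmer_fams.get(km, ()):
                if f != fam:
                    counts[f] = counts.get(f, 0) + 1
                    if counts[f] >= 2:
                        return True
        return False

    def register(self, prot: str, fam: str) -> None:
        for km in self._kmers(prot):
            self._kmer_fams.setdefault(km, set()).add(fam)


def generate_cohort(spec: SyntheticSpec, seed: int
                    ) -> tuple[list[LinearGenome], CohortTruth]:
    """A cohort sharing a planted marker-family backbone.

    Marker families occur once per genome at conserved gene-order slots
    (with +-1 jitter); a block of ``coloc_block`` markers sits at strictly
    consecutive slots, well separated from its neighbours, so the
    colocalization stage has an exactly recoverable cluster. Near-marker
    families are absent from exactly one genome each; multicopy families
    have at least one genome with >=2 adjacent copies; accessory families
    occur in a strict subset of genomes. The nucleotide filler is the
    order-0 background (family structure does not depend on dinucleotide
    statistics), so cohorts of many genomes stay cheap to generate.
    """
    if spec.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if spec.coloc_block > spec.n_marker_families:
        raise ValueError("colocalization block larger than marker set")
    rng = np.random.default_rng(seed)
    genome_ids = [f"B{i:02d}" for i in range(spec.n_genomes)]

    fam_ids, fam_class = [], {}
    for i in range(spec.n_marker_families):
        fid = f"M{i:03d}"
        fam_ids.append(fid)
        fam_class[fid] = "marker"
    for i in range(spec.n_near):
        fid = f"N{i:03d}"
        fam_ids.append(fid)
        fam_class[fid] = "near_marker"
    for i in range(spec.n_multicopy):
        fid = f"C{i:03d}"
        fam_ids.append(fid)
        fam_class[fid] = "multicopy_core"
    for i in range(spec.n_accessory):
        fid = f"A{i:03d}"
        fam_ids.append(fid)
        fam_class[fid] = "accessory"

    # backbone slots: block first, a wide gap, then the rest densely spaced
    block = [f"M{i:03d}" for i in range(spec.coloc_block)]
    rest = [f for f in fam_ids if f not in block]
    slots: dict[str, int] = {}
    s = 5
    for f in block:
        slots[f] = s
        s += 1
    s += 15                                  # isolation gap around the block
    for f in rest:
        slots[f] = s
        s += 3
    n_slots_needed = s + 10

    separator = _FamilySeparator()
    ancestors: dict[str, str] = {}
    for f in fam_ids:
        size = int(rng.integers(*spec.protein_len_range))
        for _try in range(50):
            anc = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=size))
            if not separator.conflicts(anc, f):
                break
        ancestors[f] = anc
        separator.register(anc, f)

    near_absent = {f: genome_ids[i % spec.n_genomes]
                   for i, f in enumerate(f for f in fam_ids
                                         if fam_class[f] == "near_marker")}
    multicopy_counts: dict[str, dict[str, int]] = {}
    for f in (f for f in fam_ids if fam_class[f] == "multicopy_core"):
        counts = {g: int(rng.choice([1, 2, 3], p=[0.5, 0.35, 0.15]))
                  for g in genome_ids}
        if max(counts.values()) < 2:
            counts[genome_ids[int(rng.integers(0, spec.n_genomes))]] = 2
        multicopy_counts[f] = counts
    accessory_presence: dict[str, set[str]] = {}
    for f in (f for f in fam_ids if fam_class[f] == "accessory"):
        while True:
            present = {g for g in genome_ids if rng.random() < 0.4}
            if 1 <= len(present) <= spec.n_genomes - 2:
                break
        accessory_presence[f] = present

    genomes: list[LinearGenome] = []
    members: dict[str, list[str]] = {f: [] for f in fam_ids}
    proteins: dict[str, str] = {}
    prot_genome: dict[str, str] = {}
    prot_pos: dict[str, tuple[str, int]] = {}

    pitch = spec.gene_length + spec.intergenic_gap
    L = int(rng.integers(max(spec.length_range[0], n_slots_needed * pitch + 20_000),
                         max(spec.length_range[1],
                             n_slots_needed * pitch + 20_001) + 1))
    for gid in genome_ids:
        sub = SyntheticSpec(**{**asdict(spec),
                               "length_range": (L, L),
                               "sequence_model": "iid",
                               "tr_plan": asdict(spec.tr_plan),
                               "high_gc_islands": asdict(spec.high_gc_islands),
                               "methylation": asdict(spec.methylation),
                               "coverage": asdict(spec.coverage)})
        sub.tr_plan = TRPlan(**sub.tr_plan)
        sub.high_gc_islands = IslandPlan(**sub.high_gc_islands)
        sub.methylation = MethylPlan(**sub.methylation)
        sub.coverage = CoveragePlan(**sub.coverage)
        gseed = int(rng.integers(0, 2**31 - 1))
        genome, _ = generate_genome(sub, gseed, genome_id=gid)
        n_genes = len(genome.genes)
        if n_genes < n_slots_needed:
            raise ValueError("infeasible packing: too few genes for backbone")

        occupied: set[int] = set()

        def place(fid: str, slot: int, jitter: int) -> None:
            o = slot + jitter
            while o in occupied or not 0 <= o < n_genes:
                o += 1
            occupied.add(o)
            pid = f"{gid}.{fid}.{len(members[fid])}"
            for _try in range(20):
                prot = _mutate_protein(ancestors[fid], spec.family_sub_rate, rng)
                if not separator.conflicts(prot, fid):
                    break
            separator.register(prot, fid)
            gene = genome.genes[o]
            gene.protein = prot
            members[fid].append(pid)
            proteins[pid] = prot
            prot_genome[pid] = gid
            prot_pos[pid] = (gid, o)

        for f in fam_ids:
            cls = fam_class[f]
            if cls == "near_marker" and near_absent[f] == gid:
                continue
            if cls == "accessory" and gid not in accessory_presence[f]:
                continue
            jit = 0 if f in block else int(rng.integers(-1, 2))
            place(f, slots[f], jit)
            if cls == "multicopy_core":
                for extra in range(multicopy_counts[f][gid] - 1):
                    place(f, slots[f], extra + 1)
        genomes.append(genome)

    truth = CohortTruth(family_class=fam_class, family_members=members,
                        proteins=proteins, protein_genome=prot_genome,
                        protein_positions=prot_pos, block_families=block,
                        absent_genome=near_absent)
    return genomes, truth


# ---------------------------------------------------------------------------
# Coverage and artifacts
# ---------------------------------------------------------------------------

def generate_coverage(spec: SyntheticSpec, seed: int) -> CoverageTruth:
    """Entities x samples coverage with planted Borg-host correlation.

    Host abundance profiles are log-normal across samples; each Borg tracks
    its assigned host times the copy ratio times multiplicative log-normal
    noise. Raw coverages are de-normalized with per-sample sequencing totals
    so the normalization step is exercised round-trip.
    """
    cov = spec.coverage
    if cov.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    samples = [f"s{i:03d}" for i in range(cov.n_samples)]
    hosts = [f"host{i:02d}" for i in range(cov.n_hosts)]
    borgs = [f"borg{i:02d}" for i in range(cov.n_borgs)]

    host_mat = np.exp(rng.normal(2.0, 1.2, size=(cov.n_hosts, cov.n_samples)))
    assigned = [hosts[i % cov.n_hosts] for i in range(cov.n_borgs)]
    borg_mat = np.empty((cov.n_borgs, cov.n_samples))
    for i, h in enumerate(assigned):
        noise = np.exp(rng.normal(0.0, cov.noise_sigma, size=cov.n_samples)) \
            if cov.noise_sigma > 0 else 1.0
        borg_mat[i] = host_mat[hosts.index(h)] * cov.ratio * noise

    normalized = pd.DataFrame(np.vstack([borg_mat, host_mat]),
                              index=borgs + hosts, columns=samples)
    totals = {s: float(rng.uniform(5e9, 2e10)) for s in samples}
    raw = normalized * pd.Series(totals) / 1e11
    pairs = list(zip(borgs, assigned))
    return CoverageTruth(raw=raw, totals=totals, normalized=normalized,
                         pairs=pairs, ratio=cov.ratio)


def generate_artifacts(genome: LinearGenome, kind: str, seed: int,
                       block_length: int = 6000) -> tuple[str, dict]:
    """Corrupt a genome the way amplification/assembly artifacts do.

    ``mirror`` appends the reverse complement of a random internal block;
    ``chimera`` splices in a foreign 50%-GC block. Returns the corrupted
    sequence and a truth dict with the junction coordinates.
    """
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    L = len(seq)
    if kind == "mirror":
        start = int(rng.integers(L // 4, 3 * L // 4 - block_length))
        block = seq[start : start + block_length]
        corrupted = seq + revcomp(block)
        truth = {"kind": "mirror", "source_block": (start, start + block_length),
                 "mirror_block": (L, L + block_length), "junction": L}
    elif kind == "chimera":
        pos = int(rng.integers(L // 4, 3 * L // 4))
        foreign = _iid_gc_seq(block_length, 0.50, rng)
        corrupted = seq[:pos] + foreign + seq[pos:]
        truth = {"kind": "chimera", "foreign_block": (pos, pos + block_length),
                 "junctions": (pos, pos + block_length)}
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return corrupted, truth


__all__ = [
    "TRPlan", "IslandPlan", "MethylPlan", "CoveragePlan", "SyntheticSpec",
    "GenomeTruth", "CohortTruth", "CoverageTruth", "generate_genome",
    "generate_cohort", "generate_coverage", "generate_artifacts",
    "generate_modified_sites",
]
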