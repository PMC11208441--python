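"""GC skew, replichore partition, ITR detection and curation QC flags."""

import edlib
import numpy as np
import pytest

from borgtools.architecture import (detect_gc_jumps, detect_itr,
                                    detect_mirror_blocks, gc_skew_profile,
                                    partition_replichores)
from borgtools.genome_io import GeneModel, ITRAnnotation, LinearGenome, revcomp
from borgtools.synthetic import generate_artifacts

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(n, seed):
    return BASES[np.random.default_rng(seed).integers(0, 4, n)].tobytes().decode()


class TestSkewProfile:
    def test_pure_g_window_has_skew_one(self):
        assert gc_skew_profile("GGGG", window=4, step=4).skew[0] == 1.0

    def test_balanced_window_has_skew_zero(self):
        assert gc_skew_profile("GCGC", window=4, step=4).skew[0] == 0.0

    def test_no_gc_window_defined_as_zero(self):
        assert gc_skew_profile("ATAT", window=4, step=4).skew[0] == 0.0

    def test_window_larger_than_genome_errors(self):
        with pytest.raises(ValueError, match="window exceeds"):
            gc_skew_profile("ACGT", window=10, step=10)

    def test_revcomp_profile_is_reversed_negated(self):
        seq = random_dna(50_000, 4)
        fwd = gc_skew_profile(seq, window=1000, step=1000)
        rev = gc_skew_profile(revcomp(seq), window=1000, step=1000)
        np.testing.assert_allclose(rev.skew, -fwd.skew[::-1], atol=1e-12)
        np.testing.assert_allclose(rev.gc, fwd.gc[::-1], atol=1e-12)

    def test_cumulative_is_running_sum_over_concatenation(self):
        a, b = random_dna(20_000, 1), random_dna(30_000, 2)
        whole = gc_skew_profile(a + b, window=1000, step=1000)
        pa = gc_skew_profile(a, window=1000, step=1000)
        pb = gc_skew_profile(b, window=1000, step=1000)
        np.testing.assert_allclose(whole.skew, np.concatenate([pa.skew, pb.skew]))
        np.testing.assert_allclose(
            whole.cumulative,
            np.concatenate([pa.cumulative, pa.cumulative[-1] + pb.cumulative]))


class TestReplichorePartition:
    def test_planted_switch_point_recovered(self, genome_and_truth):
        genome, truth = genome_and_truth
        prof = gc_skew_profile(genome)
        part = partition_replichores(genome, prof)
        assert abs(part.switch_point - truth.switch_point) <= 2 * prof.window
        assert part.majority_strand == truth.majority_strands

    def test_all_plus_genes_give_coding_fraction_one(self):
        seq = ("G" * 30 + "C" * 10 + "A" * 10) * 200   # skewed, arbitrary
        genes = [GeneModel(f"g{i}", i * 100, i * 100 + 80, "+")
                 for i in range(len(seq) // 100)]
        g = LinearGenome(id="x", sequence=seq, genes=genes)
        part = partition_replichores(g, gc_skew_profile(g, 500, 500))
        assert part.coding_fraction[0] == 1.0

    def test_majority_counting_rule(self):
        seq = random_dna(110_000, 8)
        strands = ["+"] * 95 + ["-"] * 5
        rng = np.random.default_rng(0)
        rng.shuffle(strands)
        genes = [GeneModel(f"g{i}", i * 1000, i * 1000 + 800, strands[i])
                 for i in range(100)]
        g = LinearGenome(id="x", sequence=seq, genes=genes)
        part = partition_replichores(g, gc_skew_profile(g))
        for (lo, hi), frac in zip(part.replichores, part.coding_fraction):
            inside = [x.strand for x in genes if lo <= (x.start + x.end) // 2 < hi]
            if not inside:
                assert np.isnan(frac)
                continue
            plus = inside.count("+")
            assert frac == pytest.approx(max(plus, len(inside) - plus) / len(inside))

    def test_no_genes_errors(self):
        g = LinearGenome(id="x", sequence=random_dna(10_000, 0))
        with pytest.raises(ValueError, match="no genes"):
            partition_replichores(g, gc_skew_profile(g))


class TestDetectITR:
    def test_perfect_planted_itr_exact(self):
        rng = np.random.default_rng(1)
        arm = random_dna(2000, 10)
        core = random_dna(30_000, 11)
        seq = arm + core + revcomp(arm)
        # pin flanks so the arm is maximal
        itr = detect_itr(seq)
        assert itr is not None
        assert itr.identity >= 0.999
        assert abs(itr.arm_length - 2000) <= 2
        assert itr.left_arm[0] == 0 and itr.right_arm[1] == len(seq)

    def test_generator_itr_recovered_exactly(self, genome_and_truth):
        genome, truth = genome_and_truth
        itr = detect_itr(genome)
        assert itr is not None
        assert itr.arm_length == truth.itr_arm_length
        assert itr.identity == 1.0

    def test_random_genome_has_no_itr(self):
        assert detect_itr(random_dna(50_000, 3)) is None

    def test_mutated_itr_within_50bp_and_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        arm = random_dna(3000, 20)
        core = random_dna(20_000, 21)
        right = list(revcomp(arm))
        for i in rng.choice(3000, size=60, replace=False):   # 2% subs
            right[i] = "ACGT"[(("ACGT".index(right[i])) + 1) % 4]
        seq = arm + core + "".join(right)
        itr = detect_itr(seq)
        assert itr is not None
        assert abs(itr.arm_length - 3000) <= 50
        # oracle: score every arm length exhaustively with edlib
        pre, sufrc = seq[:5000], revcomp(seq[-5000:])
        scores = [n - 4 * edlib.align(pre[:n], sufrc[:n], task="distance")["editDistance"]
                  for n in range(500, 4001)]
        best = 500 + int(np.argmax(scores))
        assert itr.arm_length == best

    def test_symmetric_under_revcomp(self, genome_and_truth):
        genome, _ = genome_and_truth
        fwd = detect_itr(genome.sequence)
        rev = detect_itr(revcomp(genome.sequence))
        assert fwd is not None and rev is not None
        assert fwd.arm_length == rev.arm_length


class TestGCJumps:
    def test_single_junction_flagged(self):
        lo = "".join(np.random.default_rng(0).choice(
            list("ACGT"), size=10_000, p=[0.34, 0.16, 0.16, 0.34]))
        hi = "".join(np.random.default_rng(1).choice(
            list("ACGT"), size=10_000, p=[0.25, 0.25, 0.25, 0.25]))
        prof = gc_skew_profile(lo + hi, window=1000, step=1000)
        flags = detect_gc_jumps(prof, delta_threshold=10)
        assert len(flags) == 1
        assert flags[0].interval[0] == 10_000
        # oracle: the flagged boundary is the argmax of |dGC|
        assert np.argmax(np.abs(np.diff(prof.gc))) == 9

    def test_homogeneous_genome_no_flags(self):
        prof = gc_skew_profile(random_dna(80_000, 5), window=1000, step=1000)
        assert detect_gc_jumps(prof, delta_threshold=15) == []

    def test_zero_threshold_flags_every_changing_boundary(self):
        prof = gc_skew_profile(random_dna(20_000, 6), window=1000, step=1000)
        flags = detect_gc_jumps(prof, delta_threshold=0)
        n_changes = int((np.abs(np.diff(prof.gc)) > 0).sum())
        # adjacent boundaries merge, so flags <= changes, but coverage is total
        assert len(flags) >= 1
        covered = sum(f.interval[1] - f.interval[0] for f in flags)
        assert covered == n_changes * 1000

    def test_chimera_artifact_junction_flagged(self, clean_genome_and_truth):
        genome, _ = clean_genome_and_truth
        corrupted, truth = generate_artifacts(genome, "chimera", seed=3)
        prof = gc_skew_profile(corrupted, window=1000, step=1000)
        flags = detect_gc_jumps(prof, delta_threshold=8)
        assert flags, "chimeric junction not flagged"
        a, b = truth["junctions"]
        assert any(f.interval[0] - 1500 <= a <= f.interval[1] + 1500
                   or f.interval[0] - 1500 <= b <= f.interval[1] + 1500
                   for f in flags)


def mirror_oracle(seq, min_block):
    """Brute force: all (i, j) revcomp block pairs of length >= min_block."""
    n = len(seq)
    rc = revcomp(seq)
    found = False
    for i in range(n - min_block + 1):
        block = seq[i : i + min_block]
        if "N" in block:
            continue
        j = rc.find(block)
        while j != -1:
            # fwd coords of the rc hit
            a, b = n - j - min_block, n - j
            if (a, b) != (i, i + min_block):
                found = True
                break
            j = rc.find(block, j + 1)
        if found:
            break
    return found


class TestMirrorBlocks:
    def test_planted_mirror_pair_found(self):
        s = random_dna(5000, 9)
        seq = s + revcomp(s)
        flags = detect_mirror_blocks(seq, min_block=200)
        assert len(flags) == 1
        f = flags[0]
        assert f.interval == (0, 5000) and f.partner == (5000, 10_000)

    def test_random_sequence_clean_and_matches_bruteforce(self):
        seq = random_dna(20_000, 12)
        assert detect_mirror_blocks(seq, min_block=200) == []
        assert not mirror_oracle(seq, 200)

    def test_itr_arms_excluded(self, genome_and_truth):
        genome, truth = genome_and_truth
        with_excl = detect_mirror_blocks(genome.sequence, min_block=500,
                                         itr=genome.itr)
        assert with_excl == []
        without = detect_mirror_blocks(genome.sequence, min_block=500)
        assert any(f.interval == (0, truth.itr_arm_length) for f in without)

    def test_mirror_artifact_recovered(self, clean_genome_and_truth):
        genome, _ = clean_genome_and_truth
        corrupted, truth = generate_artifacts(genome, "mirror", seed=4)
        flags = detect_mirror_blocks(corrupted, min_block=500, itr=genome.itr)
        src = truth["source_block"]

        def close(iv, target, tol=8):
            return abs(iv[0] - target[0]) <= tol and abs(iv[1] - target[1]) <= tol

        assert any(close(f.interval, src) or close(f.partner, src) for f in flags)

    def test_min_block_precondition(self):
        with pytest.raises(ValueError):
            detect_mirror_blocks("ACGT" * 100, min_block=10)
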