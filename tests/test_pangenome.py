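"""Protein similarity, subfamily clustering, marker classes, heme motifs."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from borgtools.pangenome import (SimilarityEdge, Subfamily, bit_score,
                                 classify_subfamilies, cluster_subfamilies,
                                 expect_value, pairwise_similarity,
                                 scan_heme_motifs, shared_subfamily_matrix)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def smith_waterman(a, b, open_gap=-11, extend_gap=-1):
    """Independent Gotoh local alignment, raw score only."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)
    F = np.full((n + 1, m + 1), -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + open_gap, E[i, j - 1] + extend_gap)
            F[i, j] = max(H[i - 1, j] + open_gap, F[i - 1, j] + extend_gap)
            s = blosum[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestPairwiseSimilarity:
    def test_identical_sequences_retained_full_coverage(self):
        p = random_protein(200, 0)
        edges = pairwise_similarity({"a": p, "b": p})
        assert len(edges) == 1
        e = edges[0]
        assert e.coverage == 1.0
        assert e.significance < 1e-50

    def test_unrelated_random_pair_dropped_consistent_with_sw_oracle(self):
        a, b = random_protein(200, 1), random_protein(200, 2)
        edges = pairwise_similarity({"a": a, "b": b})
        assert edges == []
        raw = smith_waterman(a, b)
        assert expect_value(raw, 200, 200) > 0.001

    def test_containment_covers_shorter_sequence(self):
        a = random_protein(300, 3)
        b = a[1:100]
        (e,) = pairwise_similarity({"a": a, "b": b})
        assert e.coverage >= 0.99

    def test_illegal_characters_name_the_record(self):
        with pytest.raises(ValueError, match="bad_rec"):
            pairwise_similarity({"ok": random_protein(50, 4), "bad_rec": "ACDB1"})


def greedy_cover_oracle(ids, pairs):
    """Independent greedy set cover with the same tie rule, built on plain
    dict scans rather than the package's data structures."""
    neigh = {i: set() for i in ids}
    for a, b in pairs:
        neigh[a].add(b)
        neigh[b].add(a)
    covered, clusters = set(), []
    while True:
        rest = [i for i in ids if i not in covered]
        if not rest:
            break
        best = None
        for cand in rest:
            key = (len(neigh[cand] - covered), len(neigh[cand]))
            if best is None or key > best_key or (key == best_key and cand < best):
                best, best_key = cand, key
        members = {best} | (neigh[best] - covered)
        covered |= members
        clusters.append((best, frozenset(members)))
    return {frozenset(m) for _, m in clusters}


def make_edges(pairs):
    return [SimilarityEdge(a=a, b=b, score=100.0, significance=1e-10,
                           coverage=1.0) for a, b in pairs]


class TestClusterSubfamilies:
    def test_star_and_pair(self):
        subfams = cluster_subfamilies(
            list("abcde"), make_edges([("a", "b"), ("a", "c"), ("d", "e")]))
        parts = {frozenset(s.members) for s in subfams}
        assert parts == {frozenset("abc"), frozenset("de")}
        reps = {s.representative for s in subfams}
        assert reps == {"a", "d"}

    def test_no_edges_all_singletons(self):
        subfams = cluster_subfamilies(list("abc"), [])
        assert all(len(s.members) == 1 for s in subfams)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"p{i:02d}" for i in range(50)]
        pairs = [(ids[i], ids[j]) for i in range(50) for j in range(i + 1, 50)
                 if rng.random() < 0.06]
        got = {frozenset(s.members)
               for s in cluster_subfamilies(ids, make_edges(pairs))}
        assert got == greedy_cover_oracle(ids, pairs)

    def test_input_order_invariance(self):
        ids = [f"p{i}" for i in range(20)]
        pairs = [(ids[i], ids[(i * 7 + 3) % 20]) for i in range(15)
                 if i != (i * 7 + 3) % 20]
        a = cluster_subfamilies(ids, make_edges(pairs))
        b = cluster_subfamilies(ids[::-1], make_edges(pairs[::-1]))
        assert [(s.representative, s.members) for s in a] == \
               [(s.representative, s.members) for s in b]


def subfam(members_by_genome):
    members, pg = [], {}
    for g, n in members_by_genome.items():
        for i in range(n):
            pid = f"{g}.{len(members)}"
            members.append(pid)
            pg[pid] = g
    return Subfamily(id="s", representative=members[0], members=members), pg


class TestClassify:
    @pytest.mark.parametrize("counts,expected", [
        ({"g1": 1, "g2": 1, "g3": 1}, "marker"),
        ({"g1": 1, "g2": 1, "g3": 0}, "near_marker"),
        ({"g1": 2, "g2": 3, "g3": 2}, "multicopy_core"),
        ({"g1": 1, "g2": 2, "g3": 0}, "accessory"),
    ])
    def test_rules(self, counts, expected):
        sf, pg = subfam({g: n for g, n in counts.items() if n})
        classified, _ = classify_subfamilies([sf], pg, ["g1", "g2", "g3"])
        assert classified[0].cls == expected

    def test_empty_genome_set_errors(self):
        sf, pg = subfam({"g1": 1})
        with pytest.raises(ValueError):
            classify_subfamilies([sf], pg, [])

    def test_census_homolog_fraction(self):
        sf1, pg1 = subfam({"g1": 1, "g2": 1})   # spans 2 genomes
        sf2, pg2 = subfam({"g1": 1})
        sf2.members = ["solo"]
        sf2.representative = "solo"
        pg = {**pg1, "solo": "g1"}
        _, census = classify_subfamilies([sf1, sf2], pg, ["g1", "g2"])
        assert census["fraction_with_homolog"] == pytest.approx(2 / 3)


class TestSharedMatrix:
    def test_identical_and_disjoint_content(self):
        sf_shared, pg1 = subfam({"g1": 1, "g2": 1})
        sf_only1, _ = subfam({"g1": 1})
        sf_only1.members = ["x"]
        pg = {**pg1, "x": "g1"}
        subfams, _ = classify_subfamilies([sf_shared, sf_only1], pg, ["g1", "g2"])
        mat = shared_subfamily_matrix(subfams, ["g1", "g2"])
        assert mat.loc["g1", "g1"] == 2
        assert mat.loc["g2", "g2"] == 1
        assert mat.loc["g1", "g2"] == mat.loc["g2", "g1"] == 1

    def test_matches_bruteforce_set_intersections(self, rng):
        genomes = [f"g{i}" for i in range(5)]
        subfams = []
        presence = []
        for k in range(30):
            pres = {g for g in genomes if rng.random() < 0.5}
            if not pres:
                continue
            sf, pg = subfam({g: 1 for g in pres})
            sf.copy_counts = {g: (1 if g in pres else 0) for g in genomes}
            subfams.append(sf)
            presence.append(pres)
        mat = shared_subfamily_matrix(subfams, genomes)
        for a in genomes:
            for b in genomes:
                expected = sum(1 for p in presence if a in p and b in p)
                assert mat.loc[a, b] == expected


class TestHemeMotifs:
    def test_three_canonical_is_mhc(self):
        res = scan_heme_motifs("CAACHGGCAACHGGCAACH")
        assert res["canonical_count"] == 3
        assert res["is_mhc"]

    def test_cx14ch_noncanonical(self):
        res = scan_heme_motifs("C" + "A" * 14 + "CH")
        assert res["canonical_count"] == 0
        assert (14, 0) in res["noncanonical"]

    def test_33_canonical_motifs(self):
        prot = ("CAACH" + "GGG") * 33
        res = scan_heme_motifs(prot)
        assert res["canonical_count"] == 33
        assert res["is_mhc"]

    def test_spacing_beyond_30_ignored(self):
        res = scan_heme_motifs("C" + "A" * 31 + "CH")
        assert res["canonical_count"] == 0
        assert res["noncanonical"] == []
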