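"""Window scan: LD, K2P distances, neighbor joining, topology classes."""

import numpy as np
import pytest

from transbalance.models import BalancedLocus, MutationModel
from transbalance.orthoshare import find_shared_snps
from transbalance.simdata import GenotypeAlignment, simulate_balanced_window, simulate_neutral_window
from transbalance.tspscan import (
    classify_topology,
    k2p_distance,
    k2p_distance_matrix,
    ld_r2,
    nj_tree,
    scan_gene,
    window_iter,
)

CODE = {b: i for i, b in enumerate("ACGT-N")}


def _aln(rows_a, rows_c):
    geno = np.array([[CODE[c] for c in r] for r in rows_a + rows_c], dtype=np.uint8)
    samples = [("A", f"a{i}") for i in range(len(rows_a))] + [
        ("C", f"c{i}") for i in range(len(rows_c))
    ]
    L = geno.shape[1]
    return GenotypeAlignment(
        gene_id_a="gA", gene_id_c="gC", geno=geno, samples=samples,
        chrom_a="1", pos_a=np.arange(1, L + 1), chrom_c="1", pos_c=np.arange(1, L + 1),
    )


class TestWindowIter:
    def test_exact_length_yields_one_window(self):
        aln = _aln(["A" * 100, "A" * 100], ["A" * 100, "A" * 100])
        wins = list(window_iter(aln, [50], size=100))
        assert len(wins) == 1
        assert wins[0].valid

    def test_94_aligned_sites_invalid(self):
        row_gappy = "A" * 94 + "-" * 6
        aln = _aln([row_gappy, "A" * 100], ["A" * 100, "A" * 100])
        wins = list(window_iter(aln, [10], size=100))
        assert not wins[0].valid and wins[0].aligned_a == 94

    def test_enumeration_matches_bruteforce(self, m1, mut):
        aln = simulate_neutral_window(m1, mut, 6, 6, 500, seed=2)
        shared = [33, 150, 151, 400]
        got = [(w.start, w.end) for w in window_iter(aln, shared, size=100)]
        expected = [
            (s, s + 100)
            for s in range(0, 401)
            if any(s <= c < s + 100 for c in shared)
        ]
        assert got == expected


class TestLD:
    def test_perfect_coupling(self):
        aln = _aln(["AC", "AC", "GT", "GT"], ["AC", "AC", "GT", "GT"])
        ra, rc = ld_r2(aln, 0, 1)
        assert ra == pytest.approx(1.0) and rc == pytest.approx(1.0)

    def test_independence(self):
        aln = _aln(["AC", "AT", "GC", "GT"], ["AC", "AT", "GC", "GT"])
        ra, rc = ld_r2(aln, 0, 1)
        assert ra == pytest.approx(0.0) and rc == pytest.approx(0.0)

    def test_one_third(self):
        # haplotypes AB, AB, aB, ab -> r^2 = 1/3
        aln = _aln(["AC", "AC", "GC", "GT"], ["AC", "AC", "GC", "GT"])
        ra, rc = ld_r2(aln, 0, 1)
        assert ra == pytest.approx(1 / 3) and rc == pytest.approx(1 / 3)

    def test_monomorphic_returns_none(self):
        aln = _aln(["AC", "AC"], ["AC", "AT", "GC", "GT"])
        ra, rc = ld_r2(aln, 0, 1)
        assert ra is None and rc is not None


class TestK2P:
    def test_identical(self):
        s = np.array([CODE[c] for c in "ACGTACGT"])
        assert k2p_distance(s, s) == 0.0

    def test_worked_example(self):
        # one transversion over 4 sites: -0.5 ln(0.75) - 0.25 ln(0.5)
        s1 = np.array([CODE[c] for c in "ACGT"])
        s2 = np.array([CODE[c] for c in "ACGA"])
        assert k2p_distance(s1, s2) == pytest.approx(0.3171, abs=5e-4)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.integers(0, 4, 60).astype(np.uint8)
            b = a.copy()
            flip = rng.random(60) < 0.15  # moderate divergence, unsaturated
            b[flip] = (b[flip] + rng.integers(1, 4, int(flip.sum()))) % 4
            d1, d2 = k2p_distance(a, b), k2p_distance(b, a)
            assert (np.isnan(d1) and np.isnan(d2)) or d1 == d2

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 4, (6, 80)).astype(np.uint8)
        mat = k2p_distance_matrix(geno)
        for i in range(6):
            for j in range(6):
                expect = k2p_distance(geno[i], geno[j])
                if np.isnan(expect):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(expect)

    def test_saturation_returns_nan(self):
        s1 = np.array([CODE[c] for c in "AAAA"])
        s2 = np.array([CODE[c] for c in "CCCC"])  # Q = 1: saturated
        assert np.isnan(k2p_distance(s1, s2))


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        # tree ((a,b),(c,d)) with internal edge 1
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        tree = nj_tree(D, list("abcd"))
        assert tree.bipartitions() == {frozenset({2, 3})}

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        # random additive tree distances on 6 leaves via random metric + NJ determinism
        D = np.array(
            [[0, 3, 9, 9, 8, 8], [3, 0, 9, 9, 8, 8], [9, 9, 0, 4, 9, 9],
             [9, 9, 4, 0, 9, 9], [8, 8, 9, 9, 0, 2], [8, 8, 9, 9, 2, 0]], float,
        )
        base = nj_tree(D, [str(i) for i in range(6)])
        base_bips = {frozenset(base.labels[i] for i in side) for side in base.bipartitions()}
        for _ in range(5):
            perm = rng.permutation(6)
            Dp = D[np.ix_(perm, perm)]
            tp = nj_tree(Dp, [str(int(p)) for p in perm])
            bips = {frozenset(tp.labels[i] for i in side) for side in tp.bipartitions()}
            # bipartition sets agree up to complement relative to each labeling
            def norm(bipset):
                full = frozenset(str(i) for i in range(6))
                return {min(b, full - b, key=sorted) for b in bipset}
            assert norm(bips) == norm(base_bips)

    def test_against_scikit_bio_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (7, 3))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        ours = nj_tree(D, labels)
        theirs = skbio_nj(DistanceMatrix(D, ids=labels))
        their_bips = set()
        n = 7
        for node in theirs.non_tips():
            tipset = frozenset(labels.index(t.name) for t in node.tips())
            if 2 <= len(tipset) <= n - 2:
                full = frozenset(range(n))
                side = tipset if 0 not in tipset else full - tipset
                their_bips.add(side)
        assert ours.bipartitions() == their_bips

    def test_star_tree_gives_no_supported_bipartitions(self):
        D = np.ones((5, 5)) - np.eye(5)
        tree = nj_tree(D, list("abcde"))
        assert tree.bipartitions() == set()

    def test_newick_exports_all_leaves(self):
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        nwk = nj_tree(D, list("abcd")).newick()
        for leaf in "abcd":
            assert leaf in nwk


class TestClassification:
    def test_neutral_window_is_species_tree_or_unresolved(self, m1, mut):
        # deep divergence forces species monophyly whenever resolvable
        hits = {"species_tree": 0, "allelic_tree": 0, "unresolved": 0, "invalid": 0}
        found = 0
        for s in range(600):
            aln = simulate_neutral_window(m1, mut, 12, 8, 100, seed=90_000 + s)
            res = find_shared_snps(aln)
            rep = scan_gene(aln, shared_snps=res.snps)
            for w in rep.windows:
                hits[w.topology] += 1
                found += 1
        assert hits["allelic_tree"] == 0

    def test_balanced_window_is_allelic_tree(self, m1, mut, balanced_locus):
        n_allelic = 0
        for s in range(10):
            aln, _ = simulate_balanced_window(
                m1, mut, balanced_locus, 20, 10, 100, seed=300 + s
            )
            rep = scan_gene(aln)
            if rep.is_candidate:
                n_allelic += 1
                for w in rep.allelic_windows:
                    assert w.topology == "allelic_tree"
        assert n_allelic >= 8

    def test_allelic_partition_must_span_both_species(self):
        # tree clusters by allele but one side is single-species: not allelic
        tree_rows_a = ["AAAA", "AAAA", "TTTT", "TTTT"]
        tree_rows_c = ["AAAA", "AAAA"]
        aln = _aln(tree_rows_a, tree_rows_c)
        from transbalance.tspscan import TreeStructure

        part_one_species = frozenset({2, 3})  # both species-A samples
        dist = k2p_distance_matrix(aln.geno)
        tree = nj_tree(np.nan_to_num(dist, nan=0.75), [f"s{i}" for i in range(6)])
        assert (
            classify_topology(tree, ["A", "A", "A", "A", "C", "C"], [part_one_species])
            != "allelic_tree"
        )

    def test_single_shared_snp_never_candidate(self, m1, mut):
        # construct: one shared SNP only
        rows_a = ["A" * 50 + "C" + "A" * 49] * 3 + ["A" * 50 + "T" + "A" * 49] * 3
        rows_c = ["G" * 50 + "C" + "G" * 49] * 3 + ["G" * 50 + "T" + "G" * 49] * 3
        aln = _aln(rows_a, rows_c)
        rep = scan_gene(aln)
        assert not rep.is_candidate
        assert rep.n_shared_snps == 1

    def test_allelic_windows_cover_balanced_column(self, m1, mut, balanced_locus):
        aln, _ = simulate_balanced_window(m1, mut, balanced_locus, 20, 10, 100, seed=77)
        rep = scan_gene(aln)
        if rep.is_candidate:
            span = rep.supporting_span
            assert span[0] <= balanced_locus.position < span[1]

    def test_scan_order_invariance(self, m1, mut, balanced_locus):
        aln, _ = simulate_balanced_window(m1, mut, balanced_locus, 15, 8, 100, seed=11)
        r1 = scan_gene(aln)
        r2 = scan_gene(aln)
        assert [w.topology for w in r1.windows] == [w.topology for w in r2.windows]
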