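import numpy as np
import pytest

from feralsweep import popstruct as ps
from feralsweep import windows as fw
from feralsweep.datatypes import MISSING

from conftest import make_vt


class TestFstDistanceMatrix:
    def test_clone_populations_near_zero(self, two_pop_cohort):
        vt, pmap, _ = two_pop_cohort
        a = sorted(pmap.group_samples("A"))
        dm = ps.fst_distance_matrix(vt, {"A1": a[:25], "A2": a[25:]})
        assert dm.matrix[0, 1] < 0.02

    def test_fixed_difference_is_one(self):
        vt = make_vt([[2, 2, 0, 0]] * 3)
        dm = ps.fst_distance_matrix(vt, {"X": ["s0", "s1"], "Y": ["s2", "s3"]})
        assert dm.matrix[0, 1] == pytest.approx(1.0)

    def test_matches_window_fst_aggregation(self, two_pop_cohort):
        vt, pmap, _ = two_pop_cohort
        a, b = sorted(pmap.group_samples("A")), sorted(pmap.group_samples("B"))
        dm = ps.fst_distance_matrix(vt, {"A": a, "B": b})
        whole = fw.fst_window(vt, a, b, fw.Window("chr1", 0, 1_000_000))
        assert dm.matrix[0, 1] == pytest.approx(whole, abs=1e-12)
        assert np.allclose(dm.matrix, dm.matrix.T)

    def test_small_population_errors(self):
        vt = make_vt([[0, 1, 2]])
        with pytest.raises(ValueError):
            ps.fst_distance_matrix(vt, {"X": ["s0"], "Y": ["s1", "s2"]})


class TestAlleleDistances:
    def test_identical_samples_zero(self):
        vt = make_vt([[1, 1], [2, 2], [0, 0]])
        dm = ps.allele_sharing_distance(vt, ["s0", "s1"])
        assert dm.matrix[0, 1] == 0.0

    def test_opposite_homozygotes_2L(self):
        vt = make_vt([[2, 0]] * 7)
        dm = ps.allele_sharing_distance(vt, ["s0", "s1"])
        assert dm.matrix[0, 1] == 14.0

    def test_missing_sites_skipped(self):
        vt = make_vt([[2, 0], [MISSING, 2], [1, 0]])
        dm = ps.allele_sharing_distance(vt, ["s0", "s1"])
        assert dm.matrix[0, 1] == 3.0

    def test_freq_distance_toy(self):
        # pop X alt freqs: 1.0, 0.5, 0.0 ; pop Y: 0.5, 0.5, 0.5
        vt = make_vt([[2, 2, 1, 1], [1, 1, 1, 1], [0, 0, 1, 1]])
        dm = ps.allele_freq_distance(vt, {"X": ["s0", "s1"], "Y": ["s2", "s3"]})
        assert dm.matrix[0, 1] == pytest.approx((0.5 + 0.0 + 0.5) / 3)

    def test_identical_pops_zero(self):
        vt = make_vt([[0, 1, 0, 1], [2, 0, 2, 0]])
        dm = ps.allele_freq_distance(vt, {"X": ["s0", "s1"], "Y": ["s2", "s3"]})
        assert dm.matrix[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = ps.neighbor_joining(ps.DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        # a = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(7.0)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     float)
        tree = ps.neighbor_joining(ps.DistanceMatrix(list("ABCD"), d))
        # split AB|CD is recovered
        for pair in (("A", "B"), ("C", "D")):
            lca = tree.lca(list(pair))
            assert {t.name for t in lca.tips()} <= set(pair) or \
                   {t.name for t in tree.tips()} - {t.name for t in lca.tips()} <= set("ABCD") - set(pair)
        # and the tree reproduces the input distances exactly
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert tree.find(x).distance(tree.find(y)) == pytest.approx(d[i, j], abs=1e-9)

    def test_newick_serializable(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = ps.neighbor_joining(ps.DistanceMatrix(["x", "y", "z"], d))
        assert str(tree).strip().endswith(";")

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            ps.neighbor_joining(ps.DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestPCA:
    def test_two_pops_separate_on_pc1(self, two_pop_cohort):
        vt, pmap, _ = two_pop_cohort
        a = sorted(pmap.group_samples("A"))
        b = sorted(pmap.group_samples("B"))
        coords, explained = ps.pca_genotypes(vt, a + b)
        pc1_a, pc1_b = coords.loc[a, "PC1"], coords.loc[b, "PC1"]
        assert pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()
        assert explained[0] > explained[1]

    def test_identical_samples_error(self):
        vt = make_vt([[1, 1, 1], [0, 0, 0]])
        with pytest.raises(ValueError):
            ps.pca_genotypes(vt, ["s0", "s1", "s2"])

    def test_order_invariance_up_to_sign(self, two_pop_cohort):
        vt, pmap, _ = two_pop_cohort
        samples = sorted(vt.samples)
        c1, _ = ps.pca_genotypes(vt, samples)
        c2, _ = ps.pca_genotypes(vt, samples[::-1])
        np.testing.assert_allclose(c1.loc[samples, "PC1"],
                                   c2.loc[samples, "PC1"], atol=1e-8)


def random_table(rng):
    f = rng.dirichlet([1, 1, 1, 1])
    n = 200
    probs = np.array([
        [f[0] ** 2, 2 * f[0] * f[1], f[1] ** 2],
        [2 * f[0] * f[2], 2 * f[0] * f[3] + 2 * f[1] * f[2], 2 * f[1] * f[3]],
        [f[2] ** 2, 2 * f[2] * f[3], f[3] ** 2]])
    draws = rng.multinomial(n, probs.ravel()).reshape(3, 3)
    return draws


def grid_oracle_ll(counts):
    """Best log-likelihood over haplotype freqs with observed allele margins,
    scanning the one free parameter on a 0.001 grid."""
    c = np.asarray(counts, float)
    n = c.sum()
    pA = (c[1].sum() + 2 * c[2].sum()) / (2 * n)   # alt freq locus 1
    pB = (c[:, 1].sum() + 2 * c[:, 2].sum()) / (2 * n)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    best = -np.inf
    for faa in np.arange(lo, hi + 1e-12, 0.001):
        f = np.array([1 - pA - pB + faa, pB - faa, pA - faa, faa])
        if (f < -1e-12).any():
            continue
        best = max(best, ps.hap_log_likelihood(c, np.clip(f, 0, 1)))
    return best


class TestEMHaplotypes:
    def test_no_double_heterozygote_exact(self):
        counts = np.array([[10, 0, 0], [0, 0, 0], [0, 0, 10]])
        f = ps.em_haplotype_freq(counts)
        np.testing.assert_allclose(f, [0.5, 0, 0, 0.5], atol=1e-12)

    def test_generative_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.4, 0.1, 0.2, 0.3])
        n = 100_000
        probs = np.array([
            [truth[0] ** 2, 2 * truth[0] * truth[1], truth[1] ** 2],
            [2 * truth[0] * truth[2],
             2 * truth[0] * truth[3] + 2 * truth[1] * truth[2],
             2 * truth[1] * truth[3]],
            [truth[2] ** 2, 2 * truth[2] * truth[3], truth[3] ** 2]])
        counts = rng.multinomial(n, probs.ravel()).reshape(3, 3)
        f = ps.em_haplotype_freq(counts)
        assert np.abs(f - truth).max() < 0.01

    def test_em_beats_grid_search(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            counts = random_table(rng)
            if counts.sum() == 0:
                continue
            f = ps.em_haplotype_freq(counts)
            assert ps.hap_log_likelihood(counts, f) >= grid_oracle_ll(counts) - 1e-6

    def test_em_monotone_likelihood(self):
        rng = np.random.default_rng(23)
        counts = random_table(rng)
        f = np.full(4, 0.25)
        prev = ps.hap_log_likelihood(counts, f)
        for _ in range(40):
            # one manual EM step via the package with max_iter=1 from f:
            f = _one_em_step(counts, f)
            ll = ps.hap_log_likelihood(counts, f)
            assert ll >= prev - 1e-9
            prev = ll

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            ps.em_haplotype_freq(np.zeros((3, 3)))


def _one_em_step(counts, f):
    """Single EM update, re-derived independently for the monotonicity check."""
    c = np.asarray(counts, float)
    n = c.sum()
    new = np.zeros(4)
    cis = f[0] * f[3]
    trans = f[1] * f[2]
    w = cis / (cis + trans) if cis + trans > 0 else 0.5
    for i in range(3):
        for j in range(3):
            ni = c[i, j]
            if ni == 0:
                continue
            if (i, j) == (1, 1):
                new[0] += ni * w
                new[3] += ni * w
                new[1] += ni * (1 - w)
                new[2] += ni * (1 - w)
            else:
                # at most one locus heterozygous: gamete pair is determined
                a1 = [0, 0] if i == 0 else ([1, 1] if i == 2 else [0, 1])
                a2 = [0, 0] if j == 0 else ([1, 1] if j == 2 else [0, 1])
                for (x, y) in ((a1[0], a2[0]), (a1[1], a2[1])):
                    new[2 * x + y] += ni
    return new / (2 * n)


class TestLDPair:
    def test_independent_loci(self):
        f = np.array([0.25, 0.25, 0.25, 0.25])
        ld = ps.ld_pair(f)
        assert ld.D == pytest.approx(0.0)
        assert ld.r2 == pytest.approx(0.0)

    def test_complete_association(self):
        ld = ps.ld_pair(np.array([0.5, 0.0, 0.0, 0.5]))
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_hand_example(self):
        # pA = pB = 0.5, f(AB) = 0.35
        ld = ps.ld_pair(np.array([0.35, 0.15, 0.15, 0.35]))
        assert ld.D == pytest.approx(0.1)
        assert ld.d_prime == pytest.approx(0.4)
        assert ld.r2 == pytest.approx(0.16)

    def test_monomorphic_undefined(self):
        ld = ps.ld_pair(np.array([1.0, 0.0, 0.0, 0.0]))
        assert np.isnan(ld.r2)


class TestLDDecay:
    def cohort(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(1, 40))
        # duplicated adjacent columns -> r2 = 1 within 0-1 kb
        d = np.vstack([base, base, rng.integers(0, 3, size=(1, 40))])
        return make_vt(d.astype(np.int8), pos=[100, 400, 50_000])

    def test_duplicated_adjacent_sites_r2_one(self):
        vt = self.cohort()
        out = ps.ld_decay(vt, vt.samples, max_dist=60_000,
                          bin_edges=[0, 1000, 60_000])
        assert out["mean_r2"][0] == pytest.approx(1.0)

    def test_pairs_beyond_max_dist_dropped(self):
        vt = self.cohort()
        out = ps.ld_decay(vt, vt.samples, max_dist=1000, bin_edges=[0, 1000])
        assert out["n_pairs"].sum() == 1  # only the adjacent duplicated pair

    def test_seeded_determinism(self):
        vt = self.cohort()
        a = ps.ld_decay(vt, vt.samples, max_dist=60_000, max_pairs=2, seed=4)
        b = ps.ld_decay(vt, vt.samples, max_dist=60_000, max_pairs=2, seed=4)
        assert a.equals(b)

    def test_empty_bin_is_nan(self):
        vt = self.cohort()
        out = ps.ld_decay(vt, vt.samples, max_dist=60_000,
                          bin_edges=[0, 1000, 2000, 60_000])
        assert np.isnan(out["mean_r2"][1])


class TestLDPrune:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 30).astype(np.int8)
        b = rng.integers(0, 3, 30).astype(np.int8)
        vt = make_vt(np.vstack([a, a, b]))
        kept = ps.ld_prune(vt)
        assert kept.tolist() == [0, 2]  # later duplicate removed

    def test_independent_sites_untouched(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        vt = make_vt(d)
        assert len(ps.ld_prune(vt)) == 10

    def test_postcondition_no_high_r2_pairs(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, size=(5, 60)).astype(np.int8)
        noisy = base.copy()
        noisy[rng.random(base.shape) < 0.1] = 0
        d = np.vstack([base, noisy, rng.integers(0, 3, size=(5, 60))]).astype(np.int8)
        vt = make_vt(d)
        kept = ps.ld_prune(vt)
        dd = vt.dosages
        for x in range(len(kept)):
            for y in range(x + 1, len(kept)):
                r2 = ps.r2_between_sites(dd[kept[x]], dd[kept[y]])
                assert not (np.isfinite(r2) and r2 > 0.2)

    def test_prune_is_fixed_point(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, size=(5, 60)).astype(np.int8)
        d = np.vstack([base, base]).astype(np.int8)
        vt = make_vt(d)
        kept = ps.ld_prune(vt)
        pruned = vt.take_sites(kept)
        again = ps.ld_prune(pruned)
        assert len(again) == pruned.n_sites
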