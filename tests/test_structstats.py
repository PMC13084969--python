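"""F_ST, Rousset's a-hat, Mantel, private alleles, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from demescope import structstats as ss

from conftest import make_table


def two_deme_assignments(t, n_a):
    return {s: ("A" if i < n_a else "B") for i, s in enumerate(t.samples)}


def naive_wc_two_pops(g_a, g_b):
    """Independent per-locus Weir-Cockerham reference (loops, r = 2)."""
    a_sum = abc_sum = 0.0
    r = 2
    for l in range(g_a.shape[1]):
        pops = []
        for g in (g_a[:, l], g_b[:, l]):
            g = g[~np.isnan(g)]
            if len(g) < 2:
                break
            pops.append((len(g), g.mean() / 2, np.mean(g == 1)))
        else:
            n = np.array([x[0] for x in pops], float)
            p = np.array([x[1] for x in pops])
            h = np.array([x[2] for x in pops])
            nbar = n.mean()
            nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 / r - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 / r - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            if a + b + c != 0 and np.isfinite(a + b + c):
                a_sum += a
                abc_sum += a + b + c
    return a_sum / abc_sum


class TestWcTheta:
    def test_fixed_difference_approaches_one(self):
        codes = np.vstack([np.zeros((30, 40), int), np.full((30, 40), 2)])
        t = make_table(codes)
        res = ss.wc_theta(t, two_deme_assignments(t, 30), "A", "B")
        assert res.theta > 0.97

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 500)
        codes = (rng.random((40, 500, 2)) < p[None, :, None]).sum(axis=2)
        t = make_table(codes)
        res = ss.wc_theta(t, two_deme_assignments(t, 20), "A", "B")
        assert abs(res.theta) < 0.02

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2, -1], size=(25, 80),
                           p=[0.4, 0.3, 0.2, 0.1])
        t = make_table(codes)
        demes = two_deme_assignments(t, 12)
        res = ss.wc_theta(t, demes, "A", "B")
        g = t.dosage()
        expect = naive_wc_two_pops(g[:12], g[12:])
        assert res.theta == pytest.approx(expect, abs=1e-12)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([0, 1, 2], size=(30, 60))
        t1 = make_table(codes)
        t2 = make_table(2 - codes)  # ref/alt exchanged at every locus
        d = two_deme_assignments(t1, 15)
        r1 = ss.wc_theta(t1, d, "A", "B")
        r2 = ss.wc_theta(t2, d, "A", "B")
        assert r1.theta == pytest.approx(r2.theta, abs=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # locus 1 strongly differentiated, locus 2 barely informative
        codes = np.zeros((20, 2), int)
        codes[10:, 0] = 2
        codes[0, 1] = 1
        t = make_table(codes)
        d = two_deme_assignments(t, 10)
        a, abc = ss.wc_components(t, d, ["A", "B"])
        ratio_of_sums = a.sum() / abc.sum()
        mean_of_ratios = np.mean(a / abc)
        res = ss.wc_theta(t, d, "A", "B")
        assert res.theta == pytest.approx(ratio_of_sums)
        assert abs(ratio_of_sums - mean_of_ratios) > 0.05

    def test_empty_deme_rejected(self):
        t = make_table(np.zeros((4, 5), int))
        with pytest.raises(ValueError, match="no samples"):
            ss.wc_theta(t, {s: "A" for s in t.samples}, "A", "B")

    def test_balding_nichols_recovery(self):
        from demescope.simdata import (
            draw_hierarchical_frequencies, sample_individuals,
        )
        from demescope.config import SimConfig

        thetas = []
        for rep in range(8):
            cfg = SimConfig(
                seed=900 + rep, n_demes=2, deme_names=["A", "B"],
                deme_sizes=[30, 30], region_split=[["A"], ["B"]],
                f_range_per_deme=[[0, 0]] * 2,
                deme_centroids=[(146.0, -41.0), (147.0, -43.0)],
                n_contigs=5, contig_length=50_000, n_sites=2000,
                prop_variable=1.0, theta_deme=0.10, theta_region=1e-4,
                n_sib_pairs=0, ibd_slope=0.0, missing_rate=0.0,
            )
            freqs = draw_hierarchical_frequencies(cfg)
            table, _, meta = sample_individuals(freqs, cfg)
            res = ss.wc_theta(table, meta.set_index("sample")["deme"], "A", "B")
            thetas.append(res.theta)
        assert np.mean(thetas) == pytest.approx(0.10, abs=0.02)


class TestBootstrap:
    def test_fixed_difference_p_zero(self):
        codes = np.vstack([np.zeros((15, 30), int), np.full((15, 30), 2)])
        t = make_table(codes)
        res = ss.fst_bootstrap(t, two_deme_assignments(t, 15), n_boot=500,
                               seed=1)
        assert res["p"].iat[0] == 0.0
        assert res["significant"].iat[0]
        assert res["ci_low"].iat[0] > 0.9

    def test_ci_contains_point_estimate(self, small_sim):
        demes = small_sim.meta.set_index("sample")["deme"]
        res = ss.fst_bootstrap(
            small_sim.table, demes, pairs=[("NW", "TP"), ("DW", "DE")],
            n_boot=500, seed=2,
        )
        assert ((res["ci_low"] <= res["theta"])
                & (res["theta"] <= res["ci_high"])).all()

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(7)
        codes = rng.choice([0, 1, 2], size=(20, 60))
        t = make_table(codes)
        d = two_deme_assignments(t, 10)
        r1 = ss.fst_bootstrap(t, d, n_boot=300, seed=11)
        r2 = ss.fst_bootstrap(t, d, n_boot=300, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_p_values_roughly_uniform(self):
        """Permuted labels: one-sided bootstrap p near uniform on average."""
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(30):
            p = rng.uniform(0.2, 0.8, 300)
            codes = (rng.random((30, 300, 2)) < p[None, :, None]).sum(axis=2)
            t = make_table(codes)
            res = ss.fst_bootstrap(t, two_deme_assignments(t, 15),
                                   n_boot=199, seed=int(rng.integers(2**31)))
            ps.append(res["p"].iat[0])
        assert 0.25 < np.mean(ps) < 0.75

    def test_small_n_boot_warns(self):
        codes = np.random.default_rng(1).choice([0, 1, 2], size=(10, 30))
        t = make_table(codes)
        with pytest.warns(UserWarning, match="n_boot"):
            ss.fst_bootstrap(t, two_deme_assignments(t, 5), n_boot=50, seed=0)


class TestPrivateAlleles:
    def test_shared_allele_not_private(self):
        codes = np.array([[1], [1]])
        t = make_table(codes)
        res = ss.private_alleles(t, {"S000": "A", "S001": "B"})
        assert res["private_alleles"].sum() == 0

    def test_singleton_alt_is_private(self):
        codes = np.array([[1, 0], [0, 0], [0, 0], [0, 0]])
        t = make_table(codes)
        res = ss.private_alleles(t, two_deme_assignments(t, 2))
        assert res.set_index("deme")["private_alleles"]["A"] == 1
        assert res.set_index("deme")["private_alleles"]["B"] == 0

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(21)
        codes = rng.choice([0, 1, 2, -1], size=(20, 50),
                           p=[0.55, 0.2, 0.15, 0.1])
        t = make_table(codes)
        demes = {s: ("A" if i < 7 else "B" if i < 14 else "C")
                 for i, s in enumerate(t.samples)}
        res = ss.private_alleles(t, demes).set_index("deme")["private_alleles"]
        expect = {"A": 0, "B": 0, "C": 0}
        for j in range(t.n_sites):
            for allele in (0, 1):
                holders = set()
                for i, s in enumerate(t.samples):
                    if t.alleles[i, j, 0] >= 0 and allele in t.alleles[i, j]:
                        holders.add(demes[s])
                if len(holders) == 1:
                    expect[holders.pop()] += 1
        assert res.to_dict() == expect


class TestRoussetA:
    def test_self_pair_near_zero_in_homogeneous_sample(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.3, 0.7, 800)
        codes = (rng.random((20, 800, 2)) < p[None, :, None]).sum(axis=2)
        t = make_table(codes)
        r = ss.rousset_a(t, "S000", "S000")
        assert not r.degenerate
        assert abs(r.a_hat) < 0.2

    def test_degenerate_when_no_within_individual_diversity(self):
        codes = np.array([[0, 0], [2, 2], [0, 2], [2, 0]])
        t = make_table(codes)
        r = ss.rousset_a(t, "S000", "S001")
        assert r.degenerate and np.isnan(r.a_hat)

    def test_no_shared_loci_rejected(self):
        codes = np.array([[0, -1], [-1, 1]])
        t = make_table(codes)
        with pytest.raises(ValueError, match="shared"):
            ss.rousset_a(t, "S000", "S001")

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(6)
        codes = rng.choice([0, 1, 2, -1], size=(8, 300),
                           p=[0.35, 0.3, 0.25, 0.1])
        t = make_table(codes)
        mat = ss.rousset_a_matrix(t)
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            r = ss.rousset_a(t, t.samples[i], t.samples[j])
            assert mat.iloc[i, j] == pytest.approx(r.a_hat, abs=1e-12)
            assert mat.iloc[j, i] == pytest.approx(r.a_hat, abs=1e-12)

    def test_between_deme_exceeds_within(self, small_sim):
        t, meta = small_sim.table, small_sim.meta
        mat = ss.rousset_a_matrix(t).to_numpy()
        deme = meta["deme"].to_numpy()
        iu, ju = np.triu_indices(len(deme), k=1)
        same = deme[iu] == deme[ju]
        assert np.nanmean(mat[iu, ju][~same]) > np.nanmean(mat[iu, ju][same])


class TestMantel:
    def _sym(self, rng, n):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_identical_matrices(self):
        rng = np.random.default_rng(1)
        a = self._sym(rng, 10)
        res = ss.mantel(a, a.copy(), n_perm=999, seed=3)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_constant_matrix_rejected(self):
        a = np.zeros((5, 5))
        with pytest.raises(ValueError, match="constant"):
            ss.mantel(a, a, n_perm=99)

    def test_asymmetric_rejected(self):
        a = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            ss.mantel(a, a, n_perm=99)

    def test_p_matches_exhaustive_enumeration_4x4(self):
        """All 24 label permutations enumerated as the exact null."""
        rng = np.random.default_rng(9)
        a, b = self._sym(rng, 4), self._sym(rng, 4)
        iu, ju = np.triu_indices(4, k=1)
        r_obs = np.corrcoef(a[iu, ju], b[iu, ju])[0, 1]
        exact = []
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            exact.append(np.corrcoef(a[iu, ju], b[p[iu], p[ju]])[0, 1])
        exact_frac = np.mean(np.array(exact) >= r_obs - 1e-12)
        res = ss.mantel(a, b, n_perm=9999, seed=17)
        # sampled permutations converge on the enumerated fraction
        assert res.p == pytest.approx(exact_frac, abs=0.02)


class TestGeoDistances:
    def test_identical_points_excluded(self):
        d, logd, excl = ss.geo_distances(np.array([147.0, 147.0, 148.0]),
                                         np.array([-42.0, -42.0, -42.0]))
        assert excl == [(0, 1)]
        assert np.isnan(logd[0, 1])

    def test_antipodal_half_circumference(self):
        d, _, _ = ss.geo_distances(np.array([0.0, 180.0]),
                                   np.array([0.0, 0.0]))
        assert d[0, 1] == pytest.approx(np.pi * ss.EARTH_RADIUS_KM, rel=1e-6)

    def test_one_degree_longitude_at_equator(self):
        d, _, _ = ss.geo_distances(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert d[0, 1] == pytest.approx(
            2 * np.pi * ss.EARTH_RADIUS_KM / 360, rel=1e-6
        )

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ss.geo_distances(np.array([0.0]), np.array([95.0]))


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(4)
        a = rng.choice([0, 1, 2], size=60)
        b = rng.choice([0, 1, 2], size=60)
        codes = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))])
        # tiny jitter so loci are not perfectly duplicated
        flip = rng.random(codes.shape) < 0.02
        codes = np.where(flip, rng.choice([0, 1, 2], size=codes.shape), codes)
        t = make_table(codes)
        scores, explained = ss.pca_scores(t, n_components=3)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()
        assert np.all(np.diff(explained) <= 1e-12)

    def test_distances_preserved_by_full_decomposition(self):
        rng = np.random.default_rng(8)
        codes = rng.choice([0, 1, 2], size=(8, 40))
        t = make_table(codes)
        scores, _ = ss.pca_scores(t, n_components=8)
        g = t.dosage()
        centered = g - g.mean(axis=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(
            pdist(scores.to_numpy()), pdist(centered), atol=1e-8
        )

    def test_too_few_loci_rejected(self):
        codes = np.random.default_rng(1).choice([0, 1], size=(6, 3))
        with pytest.raises(ValueError, match="polymorphic"):
            ss.pca_scores(make_table(codes), n_components=5)
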