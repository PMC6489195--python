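import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from founderpop import popgen
from founderpop.data_model import MISSING, PopulationSpec, SimConfig
from founderpop.synthetic_data import simulate_dataset, simulate_frequencies
from conftest import make_genotypes


def two_pop_sample(f, n_per_pop, n_snps, seed, maf=(0.05, 0.5)):
    """Unrelated individuals from two Balding-Nichols populations."""
    cfg = SimConfig(
        populations=[
            PopulationSpec("a", n_singletons=n_per_pop),
            PopulationSpec("b", n_singletons=n_per_pop),
        ],
        n_snps=n_snps,
        maf_low=maf[0],
        maf_high=maf[1],
        fst_target=f,
        missing_rate=0.0,
        genotyping_error_rate=0.0,
        seed=seed,
    )
    return simulate_dataset(cfg)


class TestHeterozygosity:
    def test_known_subset_values(self):
        g = make_genotypes(np.array([[0], [1], [1], [2]]))
        table = popgen.heterozygosity(g, {"p": g.individual_ids})
        assert table.means["p"]["h_obs"] == pytest.approx(0.5)
        assert table.means["p"]["h_exp"] == pytest.approx(0.5)

    def test_monomorphic_snp_is_zero(self):
        g = make_genotypes(np.zeros((10, 1), dtype=int))
        table = popgen.heterozygosity(g, {"p": g.individual_ids})
        assert table.means["p"]["h_obs"] == 0.0
        assert table.means["p"]["h_exp"] == 0.0

    def test_small_sample_correction_factor(self):
        g = make_genotypes(np.array([[0], [1], [1], [2]]))
        table = popgen.heterozygosity(g, {"p": g.individual_ids}, correction=True)
        assert table.means["p"]["h_exp"] == pytest.approx(0.5 * 4 / 3)

    def test_paired_t_detects_het_deficit(self):
        # founders in HWE: H_obs ~ H_exp; excess-homozygote data: t < 0
        rng = np.random.default_rng(0)
        calls = rng.binomial(1, 0.5, size=(100, 200)) * 2  # no hets at all
        g = make_genotypes(calls)
        table = popgen.heterozygosity(g, {"p": g.individual_ids})
        assert table.t_tests["p"]["t"] < 0
        assert table.t_tests["p"]["p"] < 1e-6


class TestHexpPermutationTest:
    def test_overlapping_subsets_rejected(self, toy_genotypes):
        with pytest.raises(ValueError, match="overlap"):
            popgen.hexp_permutation_test(
                toy_genotypes, ["i0", "i1"], ["i1", "i2"]
            )

    def test_zero_simulations_rejected(self, toy_genotypes):
        with pytest.raises(ValueError, match="n_sim"):
            popgen.hexp_permutation_test(
                toy_genotypes, ["i0"], ["i1"], n_sim=0
            )

    def test_detects_different_maf_spectra(self):
        # one group simulated at low-MAF spectrum, the other high
        _, pops_low = simulate_frequencies(400, 0.05, 0.2, ["x"], 0.0, seed=1)
        _, pops_high = simulate_frequencies(400, 0.35, 0.5, ["x"], 0.0, seed=2)
        rng = np.random.default_rng(3)
        a = rng.binomial(2, pops_low["x"].p, size=(40, 400))
        b = rng.binomial(2, pops_high["x"].p, size=(40, 400))
        g = make_genotypes(np.vstack([a, b]))
        p = popgen.hexp_permutation_test(
            g,
            g.individual_ids[:40],
            g.individual_ids[40:],
            n_sim=199,
            seed=4,
        )
        assert p <= 0.05


class TestWcFst:
    def test_complete_differentiation_theta_one(self):
        a = np.zeros((10, 50), dtype=int)
        b = np.full((10, 50), 2, dtype=int)
        g = make_genotypes(np.vstack([a, b]))
        res = popgen.wc_fst(
            g, g.individual_ids[:10], g.individual_ids[10:], n_boot=50, seed=0
        )
        assert res.theta == pytest.approx(1.0)

    def test_single_locus_hand_table(self):
        # pop A genotype counts (3,5,2), pop B (6,3,1): components worked
        # out by direct evaluation of the variance-component formulas
        col_a = [0] * 3 + [1] * 5 + [2] * 2
        col_b = [0] * 6 + [1] * 3 + [2] * 1
        other = [0, 2] * 10  # second polymorphic locus, identical in both
        calls = np.column_stack([col_a + col_b, other])
        g = make_genotypes(calls)
        res = popgen.wc_fst(
            g, g.individual_ids[:10], g.individual_ids[10:], n_boot=10, seed=0
        )
        row = res.components[res.components.snp_id == "s0"].iloc[0]
        assert row.a == pytest.approx(0.006944444444, abs=1e-9)
        assert row.b == pytest.approx(0.030555555556, abs=1e-9)
        assert row.c == pytest.approx(0.2, abs=1e-12)

    def test_too_few_polymorphic_loci_rejected(self):
        g = make_genotypes(np.zeros((8, 3), dtype=int))
        with pytest.raises(ValueError, match="polymorphic"):
            popgen.wc_fst(g, g.individual_ids[:4], g.individual_ids[4:])

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_components_match_scalar_oracle(self, seed):
        # independent scalar transliteration of the per-locus formulas
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 12, size=2)
        col = rng.integers(0, 3, size=na + nb)
        if len(np.unique(col[:na])) == 1 and len(np.unique(col[na:])) == 1:
            col[0] = (col[0] + 1) % 3
        other = np.tile([0, 2], (na + nb + 1) // 2)[: na + nb]
        g = make_genotypes(np.column_stack([col, other]))
        res = popgen.wc_fst(
            g, g.individual_ids[:na], g.individual_ids[na:], n_boot=5, seed=0
        )

        def oracle(ca, cb):
            r = 2
            ns, ps, hs = [], [], []
            for c in (ca, cb):
                n = len(c)
                ns.append(n)
                ps.append(sum(c) / (2 * n))
                hs.append(sum(1 for x in c if x == 1) / n)
            nbar = sum(ns) / r
            rn = r * nbar
            nc = (rn - sum(n * n for n in ns) / rn) / (r - 1)
            pbar = sum(n * p for n, p in zip(ns, ps)) / rn
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / rn
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            return a, b, hbar / 2

        ea, eb, ec = oracle(list(col[:na]), list(col[na:]))
        row = res.components[res.components.snp_id == "s0"].iloc[0]
        assert row.a == pytest.approx(ea, abs=1e-10)
        assert row.b == pytest.approx(eb, abs=1e-10)
        assert row.c == pytest.approx(ec, abs=1e-10)

    def test_parameter_recovery_balding_nichols(self):
        data = two_pop_sample(f=0.01, n_per_pop=100, n_snps=2000, seed=5)
        g = data.genotypes
        res = popgen.wc_fst(
            g,
            g.individuals_of("a"),
            g.individuals_of("b"),
            n_boot=200,
            seed=1,
        )
        assert res.theta == pytest.approx(0.01, abs=0.005)
        assert res.ci_low <= res.theta <= res.ci_high


class TestAmova:
    def test_identical_individuals_zero_components(self):
        g = make_genotypes(np.ones((8, 10), dtype=int), populations=["a"] * 4 + ["b"] * 4)
        res = popgen.amova(
            g,
            {"a": g.individual_ids[:4], "b": g.individual_ids[4:]},
            n_perm=49,
        )
        assert res.sigma_among == 0.0
        assert res.sigma_within == 0.0
        assert res.proportion_among == 0.0

    def test_opposite_fixation_full_partition(self):
        a = np.zeros((6, 20), dtype=int)
        b = np.full((6, 20), 2, dtype=int)
        g = make_genotypes(np.vstack([a, b]))
        res = popgen.amova(
            g,
            {"a": g.individual_ids[:6], "b": g.individual_ids[6:]},
            n_perm=99,
            seed=0,
        )
        assert res.proportion_among == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_six_individual_hand_worked_table(self):
        # 2 loci; distances computable by hand.  Pop A: (0,0), (0,2),
        # (2,2); pop B: (2,2), (2,2), (2,0).
        calls = np.array(
            [[0, 0], [0, 2], [2, 2], [2, 2], [2, 2], [2, 0]]
        )
        g = make_genotypes(calls)
        subsets = {"A": g.individual_ids[:3], "B": g.individual_ids[3:]}
        res = popgen.amova(g, subsets, n_perm=99, seed=1)
        # squared Hamming distances (sum |ci-cj| over loci, squared):
        d2 = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                d2[i, j] = abs(calls[i] - calls[j]).sum() ** 2
        n, r = 6, 2
        iu = np.triu_indices(6, k=1)
        ss_total = d2[iu].sum() / n
        ss_within = (
            d2[:3, :3][np.triu_indices(3, k=1)].sum() / 3
            + d2[3:, 3:][np.triu_indices(3, k=1)].sum() / 3
        )
        ss_among = ss_total - ss_within
        sigma_w = ss_within / (n - r)
        n0 = (n - (9 + 9) / n) / (r - 1)
        sigma_a = (ss_among / (r - 1) - sigma_w) / n0
        assert res.sigma_within == pytest.approx(sigma_w)
        assert res.sigma_among == pytest.approx(sigma_a)
        assert res.proportion_among == pytest.approx(
            sigma_a / (sigma_a + sigma_w)
        )

    def test_high_missing_loci_dropped_and_pvalue_in_range(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(12, 30)).astype(np.int16)
        calls[:5, 0] = MISSING  # 42% missing at locus 0
        g = make_genotypes(calls, populations=["a"] * 6 + ["b"] * 6)
        res = popgen.amova(
            g,
            {"a": g.individual_ids[:6], "b": g.individual_ids[6:]},
            missing_cutoff=0.1,
            n_perm=99,
            seed=3,
        )
        assert res.n_loci == 29
        assert 0 < res.p_value <= 1

    def test_single_individual_population_rejected(self):
        g = make_genotypes(np.zeros((3, 5), dtype=int))
        with pytest.raises(ValueError, match="fewer than two"):
            popgen.amova(g, {"a": g.individual_ids[:1], "b": g.individual_ids[1:]})


class TestRarefiedRichness:
    def test_single_copy_sample_sees_one_allele(self):
        g = make_genotypes(np.array([[0], [1], [2], [1]]))
        res = popgen.rarefied_richness(g, {"p": g.individual_ids}, max_g=1)
        row = res.curves[res.curves.g == 1].iloc[0]
        assert row.richness == pytest.approx(1.0)

    def test_full_sample_recovers_observed_allele_count(self):
        g = make_genotypes(np.column_stack([[0, 1, 2, 1], [0, 0, 0, 0]]))
        res = popgen.rarefied_richness(g, {"p": g.individual_ids}, max_g=8)
        row = res.curves[res.curves.g == 8].iloc[0]
        # locus 1 polymorphic (2 alleles), locus 2 monomorphic (1)
        assert row.richness == pytest.approx(1.5)

    def test_curves_monotone_and_private_bounded(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(20, 40))
        g = make_genotypes(calls, populations=["a"] * 10 + ["b"] * 10)
        res = popgen.rarefied_richness(
            g,
            {"a": g.individual_ids[:10], "b": g.individual_ids[10:]},
            max_g=20,
        )
        for pop in ("a", "b"):
            curve = res.curves[res.curves.population == pop].sort_values("g")
            assert (np.diff(curve.richness) >= -1e-12).all()
            assert (curve.private_richness <= curve.richness + 1e-12).all()

    def test_oversized_sample_names_population(self):
        g = make_genotypes(np.zeros((3, 4), dtype=int), populations=["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            popgen.rarefied_richness(g, {"tiny": g.individual_ids}, max_g=7)

    def test_matches_exact_hypergeometric_toy(self):
        # N = 10 copies, allele counts (7, 3), q = 4:
        # E[alleles] = 2 - C(3,4)/C(10,4) - C(7,4)/C(10,4) = 11/6
        calls = np.array([[2], [2], [2], [1], [0]])  # 7 alt, 3 ref copies
        g = make_genotypes(calls)
        res = popgen.rarefied_richness(g, {"p": g.individual_ids}, max_g=4)
        row = res.curves[res.curves.g == 4].iloc[0]
        assert row.richness == pytest.approx(11 / 6, abs=1e-9)


class TestPcaKmeansBic:
    def test_single_population_optimum_is_one(self):
        data = two_pop_sample(f=0.0, n_per_pop=40, n_snps=300, seed=9)
        g = data.genotypes.subset_individuals(data.genotypes.individuals_of("a"))
        scan = popgen.pca_kmeans_bic(g, max_k=8, seed=0)
        assert scan.optimum_k == 1

    def test_two_separated_populations_optimum_is_two(self):
        data = two_pop_sample(f=0.2, n_per_pop=40, n_snps=400, seed=10)
        scan = popgen.pca_kmeans_bic(data.genotypes, max_k=8, seed=0)
        assert scan.optimum_k == 2

    def test_degenerate_k_equal_n_guarded(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.integers(0, 3, size=(6, 20)))
        scan = popgen.pca_kmeans_bic(g, max_k=6, seed=0)
        # K = n reaches WSS = 0 and must be excluded without crashing
        assert np.isnan(scan.bic.bic.iloc[-1]) or scan.bic.wss.iloc[-1] > 0
        assert 1 <= scan.optimum_k <= 6

    def test_max_k_above_n_rejected(self):
        g = make_genotypes(np.zeros((4, 5), dtype=int))
        with pytest.raises(ValueError, match="max_k"):
            popgen.pca_kmeans_bic(g, max_k=10)
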