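import numpy as np
import pytest
from scipy.special import expit


import rfgrs
from rfgrs import (ConfigError, EffectModel, LDBlockSpec, SimConfig,
                   calibrate_intercept, draw_effects, draw_target_indices,
                   make_base_target, simulate_genotypes, simulate_phenotype)

CFG = SimConfig(seed=0)


class TestGenotypeSimulation:
    def test_deterministic_given_seed(self):
        spec = LDBlockSpec.uniform_blocks(30)
        a = simulate_genotypes(50, spec, seed=5)
        b = simulate_genotypes(50, spec, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert simulate_genotypes(50, spec, seed=6).counts.tolist() != a.counts.tolist()

    def test_zero_rho_gives_independent_adjacent_snps(self):
        spec = LDBlockSpec.uniform_blocks(60, block_size=10, rho=0.0,
                                          maf_range=(0.2, 0.5))
        G = simulate_genotypes(5000, spec, seed=1)
        X = G.counts.astype(float)
        r2 = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] ** 2 for j in range(59)]
        assert np.mean(r2) < 0.01

    def test_positive_rho_gives_within_block_ld(self):
        spec = LDBlockSpec.uniform_blocks(20, block_size=10, rho=0.8,
                                          maf_range=(0.2, 0.5))
        G = simulate_genotypes(3000, spec, seed=2)
        X = G.counts.astype(float)
        within = np.corrcoef(X[:, 0], X[:, 1])[0, 1] ** 2
        across = np.corrcoef(X[:, 9], X[:, 10])[0, 1] ** 2  # block boundary
        assert within > 0.25
        assert across < 0.01

    def test_empirical_maf_matches_drawn_maf(self):
        spec = LDBlockSpec(block_sizes=(20,), rho=0.0, maf_range=(0.3, 0.3))
        G = simulate_genotypes(5000, spec, seed=3)
        emp = G.counts.mean(axis=0) / 2
        assert np.all(np.abs(emp - 0.3) < 0.02)

    def test_hardy_weinberg_genotype_frequencies(self):
        spec = LDBlockSpec.uniform_blocks(50, rho=0.5, maf_range=(0.05, 0.5))
        G = simulate_genotypes(5000, spec, seed=4)
        n = G.n_samples
        failures = 0
        for j in range(G.n_snps):
            col = G.counts[:, j]
            f = col.mean() / 2
            exp = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            obs = np.bincount(col, minlength=3)
            stat = ((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            # 1 df (allele freq estimated); alpha = 0.001
            from scipy.stats import chi2
            if chi2.sf(stat, df=1) < 0.001:
                failures += 1
        assert failures <= 2

    def test_maf_range_validation(self):
        with pytest.raises(ConfigError):
            LDBlockSpec(block_sizes=(10,), maf_range=(0.001, 0.4))
        with pytest.raises(ConfigError):
            LDBlockSpec(block_sizes=(10,), rho=1.0)

    def test_positions_are_block_contiguous(self):
        spec = LDBlockSpec.uniform_blocks(10, block_size=5, bp_spacing=100)
        G = simulate_genotypes(5, spec, seed=1)
        assert [v.pos for v in G.snps] == list(range(1, 1000, 100))


class TestEffectModels:
    def test_scenario1_exactly_half_negative(self):
        em = draw_effects("1", CFG, seed=11)
        betas = np.array([b for _, b in em.main_terms])
        assert len(em.main_terms) == 100
        assert (betas < 0).sum() == 50
        assert not em.pair_terms and not em.triple_terms and not em.quad_terms

    def test_scenario2_pair_structure(self):
        em = draw_effects("2", CFG, seed=12)
        assert len(em.pair_terms) == 100
        pairs = {(l, m) for l, m, _ in em.pair_terms}
        assert len(pairs) == 100  # all distinct
        first50 = set(em.causal_ids[:50])
        last50 = set(em.causal_ids[50:])
        assert all(l in first50 and m in last50 for l, m, _ in em.pair_terms)
        assert not em.main_terms

    def test_scenario3_mixed_structure(self):
        em = draw_effects("3", CFG, seed=13)
        assert len(em.main_terms) == 50
        assert len(em.pair_terms) == 100
        betas = np.array([b for _, b in em.main_terms])
        assert (betas < 0).sum() == 25

    def test_scenario4_triples_one_per_group_of_33(self):
        em = draw_effects("4", CFG, seed=14)
        assert len(em.triple_terms) == 30
        g1 = set(em.causal_ids[:33])
        g2 = set(em.causal_ids[33:66])
        g3 = set(em.causal_ids[66:99])
        for l, m, n, _ in em.triple_terms:
            assert l in g1 and m in g2 and n in g3
        assert len({t[:3] for t in em.triple_terms}) == 30

    def test_scenario5_quadratic_and_maf_restriction(self):
        em = draw_effects("5a", CFG, seed=15)
        assert len(em.quad_terms) == 100 and not em.main_terms
        mafs = np.concatenate([np.full(300, 0.45), np.full(700, 0.05)])
        em_b = draw_effects("5b", CFG, seed=15, snp_mafs=mafs)
        assert all(c < 300 for c in em_b.causal_ids)
        with pytest.raises(ConfigError, match="MAF > 0.3"):
            draw_effects("5b", CFG, seed=15, snp_mafs=np.full(1000, 0.1))

    def test_interaction_betas_not_sign_flipped(self):
        em = draw_effects("2", SimConfig(mu_int=np.log(2.0)), seed=16)
        betas = np.array([b for *_, b in em.pair_terms])
        assert (betas > 0).all()  # Normal(log 2, 0.1), no negation


class TestBaseTargetPairing:
    def test_full_overlap_gives_identical_models(self):
        t, b = make_base_target("1", SimConfig(q=100), seed=21)
        assert t == b

    def test_partial_overlap_set_arithmetic(self):
        t, b = make_base_target("1", SimConfig(q=30), seed=22)
        shared = set(t.causal_ids) & set(b.causal_ids)
        t_only = set(t.causal_ids) - shared
        b_only = set(b.causal_ids) - shared
        assert len(shared) == 30
        assert len(t_only) == len(b_only) == 70
        assert not (t_only & b_only)

    def test_shared_snp_betas_bitwise_equal(self):
        t, b = make_base_target("1", SimConfig(q=70), seed=23)
        shared = set(t.causal_ids) & set(b.causal_ids)
        t_betas = dict(t.main_terms)
        b_betas = dict(b.main_terms)
        for s in shared:
            assert t_betas[s] == b_betas[s]
        # non-shared SNPs get fresh draws
        assert any(b_betas[s] != t_betas.get(s) for s in b_betas if s not in shared)

    def test_pair_terms_shared_when_both_members_shared(self):
        t, b = make_base_target("2", SimConfig(q=70), seed=24)
        shared = set(t.causal_ids) & set(b.causal_ids)
        t_pairs = {p[:2]: p[2] for p in t.pair_terms}
        for l, m, beta in b.pair_terms:
            if l in shared and m in shared and (l, m) in t_pairs:
                assert beta == t_pairs[(l, m)]

    def test_infeasible_when_pool_exhausted(self):
        with pytest.raises(ConfigError, match="disjoint"):
            make_base_target("1", SimConfig(n_snps=120, q=30), seed=25)


class TestPhenotypes:
    def test_null_model_prevalence_half(self):
        G = simulate_genotypes(5000, LDBlockSpec.uniform_blocks(100), seed=31)
        em = EffectModel(scenario="1", causal_ids=tuple(range(100)),
                         main_terms=tuple((j, 0.0) for j in range(100)))
        y = simulate_phenotype(G, em, seed=32)
        assert abs(y.mean() - 0.5) < 0.02

    def test_linear_predictor_hand_computed(self):
        counts = np.array([[0, 1, 2], [2, 2, 1]], dtype=np.int8)
        em = EffectModel(scenario="3", causal_ids=(0, 1, 2), beta0=0.5,
                         main_terms=((0, 0.3),), pair_terms=((1, 2, -0.2),))
        eta = em.linear_predictor(counts)
        np.testing.assert_allclose(
            eta, [0.5 + 0.0 - 0.2 * 1 * 2, 0.5 + 0.6 - 0.2 * 2 * 1])

    def test_quadratic_and_triple_terms(self):
        counts = np.array([[2, 1, 1]], dtype=np.int8)
        em = EffectModel(scenario="4", causal_ids=(0, 1, 2),
                         triple_terms=((0, 1, 2, 0.5),))
        assert em.linear_predictor(counts)[0] == pytest.approx(0.5 * 2)
        em5 = EffectModel(scenario="5a", causal_ids=(0,),
                          quad_terms=((0, 0.25),))
        assert em5.linear_predictor(counts)[0] == pytest.approx(0.25 * 4)

    def test_prevalence_tracks_mean_expit_eta(self):
        G = simulate_genotypes(5000, LDBlockSpec.uniform_blocks(100), seed=33)
        em = calibrate_intercept(G, draw_effects("2", SimConfig(n_snps=100), seed=34))
        y = simulate_phenotype(G, em, seed=35)
        expected = expit(em.linear_predictor(G.counts)).mean()
        assert abs(y.mean() - expected) < 0.02

    def test_seeded_reproducibility(self):
        G = simulate_genotypes(200, LDBlockSpec.uniform_blocks(100), seed=36)
        em = draw_effects("1", SimConfig(n_snps=100), seed=37)
        np.testing.assert_array_equal(simulate_phenotype(G, em, seed=38),
                                      simulate_phenotype(G, em, seed=38))

    def test_effect_model_outside_matrix_rejected(self):
        G = simulate_genotypes(10, LDBlockSpec.uniform_blocks(5), seed=39)
        em = EffectModel(scenario="1", causal_ids=(9,), main_terms=((9, 0.5),))
        with pytest.raises(ConfigError):
            simulate_phenotype(G, em, seed=40)

    def test_calibrated_intercept_centers_eta(self):
        G = simulate_genotypes(500, LDBlockSpec.uniform_blocks(200), seed=41)
        em = calibrate_intercept(G, draw_effects("2", SimConfig(n_snps=200), seed=42))
        assert em.linear_predictor(G.counts).mean() == pytest.approx(0.0, abs=1e-9)


def test_pool_partition_is_disjoint_and_exhaustive():
    tgt, base = draw_target_indices(1200, 200, seed=1)
    assert len(tgt) == 200 and len(base) == 1000
    assert not np.intersect1d(tgt, base).size
    assert np.array_equal(np.sort(np.concatenate([tgt, base])), np.arange(1200))
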