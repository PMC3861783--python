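import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from seqdesign import famprior, pedsim
from seqdesign.famprior import _T, _hwe, penetrance_from, pedigree_peel_loglik


@pytest.fixture(scope="module")
def family_dataset(small_pop, effect_model, intercept):
    ds = pedsim.gene_drop_ascertain(
        small_pop, effect_model, intercept, min_cases=4,
        n_families=60, seed=23,
    )
    for f in range(ds.n_fam):
        mask = pedsim.select_members(ds.pedigree, ds.y[f], "SSu", seed=50 + f)
        if not mask.any():
            mask = pedsim.select_members(ds.pedigree, ds.y[f], "SS", seed=50 + f)
        if not mask.any():  # fall back: first two cases + a control
            cases = np.flatnonzero(ds.y[f] == 1)[:2]
            ctrls = np.flatnonzero(ds.y[f] == 0)[:1]
            mask = np.zeros(ds.pedigree.n, bool)
            mask[np.concatenate([cases, ctrls])] = True
        ds.sequenced[f] = mask
    return ds


def enumeration_loglik(ped, q, y, gobs, pen):
    """Brute-force sum over all genotype vectors (oracle for peeling)."""
    hw = _hwe(np.array([q]))[0]
    tot = 0.0
    for g in itertools.product(range(3), repeat=ped.n):
        p = 1.0
        for i in range(ped.n):
            f, m = ped.father[i], ped.mother[i]
            p *= hw[g[i]] if f == -1 else _T[g[f], g[m], g[i]]
            if pen is not None and y is not None:
                p *= pen[0][g[i]] if y[0, i] == 1 else 1 - pen[0][g[i]]
            if gobs is not None and gobs[0, i] >= 0 and g[i] != gobs[0, i]:
                p = 0.0
                break
        tot += p
    return np.log(tot)


class TestRuleCount:
    def test_absent_variant_counts_zero(self, family_dataset):
        mono = np.argmin(family_dataset.pop.maf)
        # pick a variant carried by nobody in the sequenced subsets
        for v in np.argsort(family_dataset.pop.maf):
            G = family_dataset.genotypes(v)
            if not (np.where(family_dataset.sequenced, G, 0) > 0).any():
                assert famprior.rule_count(family_dataset, v) == 0
                return
        pytest.skip("no uncarried variant in fixture")

    def test_matches_brute_force(self, family_dataset):
        ds = family_dataset
        for v in np.argsort(ds.pop.maf)[-10:]:
            G = ds.genotypes(v)
            expected = 0
            for f in range(ds.n_fam):
                seq = np.flatnonzero(ds.sequenced[f])
                cases = [i for i in seq if ds.y[f, i] == 1]
                ctrls = [i for i in seq if ds.y[f, i] == 0]
                if not cases:
                    continue
                if all(G[f, i] > 0 for i in cases) and all(
                    G[f, i] == 0 for i in ctrls
                ):
                    expected += 1
            assert famprior.rule_count(ds, v) == expected

    def test_single_family_hand_case(self, small_pop):
        ped = pedsim.standard_subpedigree()
        hap = np.zeros((1, ped.n, 2), dtype=np.int32)
        # make members 6,7 carriers via a haplotype carrying variant 0
        carrier_hap = int(np.argmax(small_pop.haplotypes[:, 0] == 1))
        hap[0, 6, 0] = carrier_hap
        hap[0, 7, 0] = carrier_hap
        y = np.zeros((1, ped.n), dtype=np.int8)
        y[0, [6, 7]] = 1
        seq = np.zeros((1, ped.n), dtype=bool)
        seq[0, [6, 7, 9]] = True
        noncarrier = int(np.argmax(small_pop.haplotypes[:, 0] == 0))
        hap[hap == 0] = noncarrier
        ds = pedsim.FamilyDataset(ped, small_pop, hap, y, seq)
        assert famprior.rule_count(ds, 0) == 1


class TestPeeling:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        sub = pedsim.standard_subpedigree()
        rng = np.random.default_rng(seed)
        q, beta, a = 0.15, 1.1, -2.8
        y = rng.integers(0, 2, (1, sub.n))
        gobs = np.full((1, sub.n), -1, np.int8)
        for i in rng.choice(sub.n, 3, replace=False):
            gobs[0, i] = rng.integers(0, 3)
        pen = penetrance_from(np.array([beta]), np.array([q]), a)
        for (yy, gg, pp) in [(y, gobs, pen), (y, None, pen), (None, gobs, None)]:
            mine = pedigree_peel_loglik(sub, q, yy, gg, pp)[0, 0]
            oracle = enumeration_loglik(sub, q, yy, gg, pp)
            assert mine == pytest.approx(oracle, abs=1e-10)


class TestRetrospectiveLR:
    def test_null_beta_is_exactly_one(self, family_dataset):
        v = int(np.argmax(family_dataset.pop.maf))
        assert famprior.retrospective_lr(
            family_dataset, v, 0.0, family_dataset.pop.maf[v], -2.0
        ) == 0.0

    def test_fully_observed_trio_matches_hand_product(self, small_pop):
        """3-member family (couple + child), everyone sequenced: the LR is
        a ratio of explicit products, no summation."""
        ped = pedsim.Pedigree(
            np.array([-1, -1, 0]), np.array([-1, -1, 1]), np.array([1, 1, 2])
        )
        q, beta, a = 0.3, 0.9, -1.5
        g = np.array([[1, 0, 1]], dtype=np.int8)
        y = np.array([[1, 0, 1]], dtype=np.int8)
        hw = _hwe(np.array([q]))[0]
        pen = expit(a + beta * np.arange(3))
        pr_g = hw[1] * hw[0] * _T[1, 0, 1]
        pr_y_given_g = pen[1] * (1 - pen[0]) * pen[1]
        # Pr(Y): sum over genotypes
        pr_y = 0.0
        for gf in range(3):
            for gm in range(3):
                for gc in range(3):
                    pr_y += (
                        hw[gf] * hw[gm] * _T[gf, gm, gc]
                        * pen[gf] * (1 - pen[gm]) * pen[gc]
                    )
        hand = np.log(pr_y_given_g * pr_g / pr_y) - np.log(pr_g)
        mine = pedigree_peel_loglik(
            ped, q, y, g, penetrance_from(np.array([beta]), np.array([q]), a)
        )[0, 0]
        mine -= pedigree_peel_loglik(
            ped, q, y, None,
            penetrance_from(np.array([beta]), np.array([q]), a),
        )[0, 0]
        mine -= pedigree_peel_loglik(ped, q, None, g, None)[0, 0]
        assert mine == pytest.approx(hand, abs=1e-12)

    def test_invalid_q_rejected(self, family_dataset):
        with pytest.raises(ValueError):
            famprior.retrospective_lr(family_dataset, 0, 0.5, 0.0, -2.0)

    def test_causal_variant_scores_higher_than_null(self):
        """In an LD-free pool with one strong causal variant, its log LR in
        ascertained families exceeds that of matched null variants."""
        from seqdesign.hapsim import HaplotypePopulation

        rng = np.random.default_rng(77)
        n_hap, n_site = 600, 40
        q = np.full(n_site, 0.05)
        H = (rng.random((n_hap, n_site)) < q).astype(np.uint8)
        H[0, :] = 1  # guard against monomorphic columns
        H[1, :] = 0
        pop = HaplotypePopulation(H, np.arange(n_site, dtype=float), 1e4)
        causal = np.zeros(n_site, dtype=bool)
        beta = np.zeros(n_site)
        causal[0], beta[0] = True, np.log(6)
        from seqdesign.disease_models import VariantEffectModel, calibrate_intercept

        model = VariantEffectModel(causal, beta)
        a = calibrate_intercept(pop, model, 0.05, seed=1)
        ds = pedsim.gene_drop_ascertain(
            pop, model, a, min_cases=4, n_families=80, seed=5
        )
        ds.sequenced[:, [14, 15, 16, 17]] = True
        lr_at = lambda v: famprior.retrospective_lr(
            ds, v, np.log(6), float(pop.maf[v]), a
        )
        lr_causal = lr_at(0)
        lr_null = [lr_at(v) for v in range(1, 15)]
        assert lr_causal > np.mean(lr_null)
        assert lr_causal > 0


class TestBayesFactor:
    def test_point_mass_prior_equals_lr(self, family_dataset, intercept):
        ds = family_dataset
        v = int(np.argsort(ds.pop.maf)[-3])
        q = float(ds.pop.maf[v])
        beta = 0.8
        prior = famprior.PriorSpec(q1=[q], beta1=[beta], q0=[q])
        bf = famprior.bayes_factor(ds, v, prior, intercept)
        lr = famprior.retrospective_lr(ds, v, beta, q, intercept)
        assert bf == pytest.approx(lr, abs=1e-10)

    def test_mc_error_scales_inverse_root_n(self, family_dataset, intercept):
        """The spread of log BF over prior re-draws shrinks roughly like
        1/sqrt(n_draws)."""
        ds = family_dataset
        v = int(np.argsort(ds.pop.maf)[-2])

        def maf_sampler(rng, n):
            return np.exp(rng.uniform(np.log(0.01), np.log(0.3), n))

        def beta_sampler(rng, qv):
            return np.abs(rng.normal(0, 0.8, qv.size))

        def spread(n_draws):
            vals = [
                famprior.bayes_factor(
                    ds, v,
                    famprior.PriorSpec.sample(
                        maf_sampler, beta_sampler, n_draws, seed=s
                    ),
                    intercept,
                )
                for s in range(12)
            ]
            return np.std(vals)

        s_small, s_big = spread(25), spread(400)
        assert s_big < s_small  # 4x draws must not be noisier
        assert s_big < 0.6 * s_small  # ~sqrt(16)=4x reduction expected

    def test_batch_matches_single(self, family_dataset, intercept):
        ds = family_dataset
        prior = famprior.PriorSpec.sample(
            lambda rng, n: np.full(n, 0.05),
            lambda rng, qv: np.full(qv.size, 0.5),
            n_draws=5, seed=1,
        )
        vs = list(np.argsort(ds.pop.maf)[-3:])
        batch = famprior.bayes_factor_many(ds, vs, prior, intercept)
        singles = [famprior.bayes_factor(ds, v, prior, intercept) for v in vs]
        assert np.allclose(batch, singles)


class TestFamilyScore:
    def test_all_carrier_family_is_uninformative_within(self, small_pop):
        ped = pedsim.standard_subpedigree()
        carrier_hap = int(np.argmax(small_pop.haplotypes[:, 0] == 1))
        hap = np.full((1, ped.n, 2), carrier_hap, dtype=np.int32)
        y = np.zeros((1, ped.n), dtype=np.int8)
        y[0, :4] = 1
        seq = np.ones((1, ped.n), dtype=bool)
        ds = pedsim.FamilyDataset(ped, small_pop, hap, y, seq)
        r = famprior.family_score(ds, 0, mode="within")
        assert r.t_fam[0] == pytest.approx(0.0)
        assert not r.informative

    def test_singleton_reduces_to_centered_product(self, small_pop):
        ped = pedsim.Pedigree(np.array([-1]), np.array([-1]), np.array([1]))
        carrier_hap = int(np.argmax(small_pop.haplotypes[:, 0] == 1))
        non = int(np.argmax(small_pop.haplotypes[:, 0] == 0))
        hap = np.array([[[carrier_hap, non]], [[non, non]]], dtype=np.int32)
        y = np.array([[1], [0]], dtype=np.int8)
        seq = np.ones((2, 1), dtype=bool)
        ds = pedsim.FamilyDataset(ped, small_pop, hap, y, seq)
        r = famprior.family_score(ds, 0, mode="combined")
        G = ds.genotypes(0).astype(float).ravel()
        p, q = y.mean(), G.mean()
        expected = 0.5 * (y.ravel() - p) * (G - q)  # phi(self) = 1/2
        assert np.allclose(r.t_fam, expected)

    def test_combined_recovers_between_family_signal(self, family_dataset):
        ds = family_dataset
        v = int(np.argsort(ds.pop.maf)[-1])
        within = famprior.family_score(ds, v, "within")
        combined = famprior.family_score(ds, v, "combined")
        assert within.informative or combined.informative

    def test_null_mean_zero(self, small_pop, null_model):
        """Under the null gene-drop model the score sums to ~0 and the
        empirical variance of T matches sum of t^2."""
        ds = pedsim.gene_drop_ascertain(
            small_pop, null_model, logit(0.05), min_cases=4,
            n_families=200, seed=31,
        )
        ds.sequenced[:, [14, 15, 16]] = True
        v = int(np.argsort(small_pop.maf)[-1])
        r = famprior.family_score(ds, v, "within")
        assert abs(r.T) < 4 * np.sqrt(r.var)

    def test_unknown_mode_rejected(self, family_dataset):
        with pytest.raises(ValueError):
            famprior.family_score(family_dataset, 0, mode="between")


class TestRegionalScore:
    def test_single_variant_region_reduces_to_score_test(self, family_dataset):
        ds = family_dataset
        v = int(np.argsort(ds.pop.maf)[-1])
        single = famprior.family_score(ds, v)
        Q, p = famprior.regional_score(ds, [v])
        assert Q == pytest.approx(single.T**2)
        assert p == pytest.approx(single.p_value, rel=1e-10)

    def test_empty_region_rejected(self, family_dataset):
        with pytest.raises(ValueError):
            famprior.regional_score(family_dataset, [])

    def test_strong_causal_variant_drives_region(
        self, family_dataset, effect_model
    ):
        ds = family_dataset
        common = np.argsort(ds.pop.maf)[-6:]
        Q, p = famprior.regional_score(ds, common)
        assert Q >= 0 and 0 < p <= 1


class TestRoc:
    def test_identical_distributions_auc_half(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 4000)
        b = rng.normal(0, 1, 4000)
        *_, auc = famprior.roc(a, b)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_perfect_separation(self):
        *_, auc = famprior.roc([2, 3, 4], [-1, 0, 1])
        assert auc == 1.0

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.7, 1, 60)
        b = rng.normal(0.0, 1, 80)
        *_, auc = famprior.roc(a, b)
        u = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in a for y in b
        )
        assert auc == pytest.approx(u / (60 * 80), abs=1e-10)
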