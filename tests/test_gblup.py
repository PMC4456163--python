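"""Genomic relationship matrix, mixed-model equations, REML and selection."""

import numpy as np
import pytest

from imfnet import gblup, simdata
from oracles import welch_t_bruteforce


def _geno(rows):
    arr = np.asarray(rows)
    return gblup.GenotypeMatrix(
        dosages=arr,
        animal_ids=[f"a{i}" for i in range(arr.shape[0])],
        snp_ids=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "column, expected",
        [([0, 1, 2, 1], 0.5), ([0, 0, 0], 0.0), ([2, 2, 2, 2], 1.0)],
    )
    def test_single_column(self, column, expected):
        geno = _geno(np.asarray(column)[:, None])
        assert gblup.allele_frequencies(geno)[0] == pytest.approx(expected)

    def test_codes_validated(self):
        with pytest.raises(ValueError, match="dosage codes"):
            _geno([[0, 3], [1, 1]])


class TestVanRadenG:
    def test_hand_computed_two_animals(self):
        # one SNP, p = 0.5, dosages (0, 2): W = (-1, 1), denominator 0.5
        geno = _geno([[0], [2]])
        g = gblup.vanraden_g(geno)
        assert g.denominator == pytest.approx(0.5)
        assert np.allclose(g.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_animals_share_structure(self, rng):
        row = rng.integers(0, 3, size=20)
        geno = _geno(np.vstack([row, row, rng.integers(0, 3, size=20)]))
        g = gblup.vanraden_g(geno).values
        assert g[0, 0] == pytest.approx(g[1, 1])
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gblup.vanraden_g(_geno([[2, 0], [2, 0]]))

    def test_hwe_mean_diagonal_near_one(self):
        geno = simdata.simulate_genotypes(100, 5000, (0.05, 0.5), seed=3)
        g = gblup.vanraden_g(geno)
        assert np.mean(np.diag(g.values)) == pytest.approx(1.0, abs=0.05)

    def test_symmetry(self, rng):
        geno = _geno(rng.integers(0, 3, size=(30, 80)))
        g = gblup.vanraden_g(geno).values
        assert np.max(np.abs(g - g.T)) < 1e-10


class TestSolveMME:
    def test_two_animal_closed_form(self):
        # identity design, lambda = 1 (h2 = 0.5): u_hat = (y - ybar)/2
        spec = gblup.MixedModelSpec(response=[1.0, 3.0], fixed_design=np.ones((2, 1)))
        fit = gblup.solve_mme(spec, gblup.VarianceComponents(1.0, 1.0))
        assert np.allclose(fit.gebv, [-0.5, 0.5], atol=1e-10)
        assert fit.heritability == pytest.approx(0.5)

    def test_shrinkage_closed_form_identity_design(self, rng):
        y = rng.normal(size=12)
        spec = gblup.MixedModelSpec(response=y, fixed_design=np.ones((12, 1)))
        for lam in (0.25, 1.0, 4.0):
            fit = gblup.solve_mme(spec, gblup.VarianceComponents(1.0, lam))
            assert np.allclose(fit.gebv, (y - y.mean()) / (1 + lam), atol=1e-8)
            assert fit.gebv.sum() == pytest.approx(0.0, abs=1e-8)

    def test_no_shrinkage_limit(self, rng):
        y = rng.normal(size=8)
        spec = gblup.MixedModelSpec(response=y, fixed_design=np.ones((8, 1)))
        fit = gblup.solve_mme(spec, gblup.VarianceComponents(1e9, 1.0))
        assert np.allclose(fit.gebv, y - y.mean(), atol=1e-6)

    def test_rank_deficient_fixed_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            gblup.MixedModelSpec(response=np.arange(4.0), fixed_design=X)


class TestEmReml:
    def test_zero_variance_response_errors(self):
        spec = gblup.MixedModelSpec(response=np.ones(10), fixed_design=np.ones((10, 1)))
        with pytest.raises(ValueError, match="zero variance"):
            gblup.em_reml(spec)

    def test_pure_noise_hits_zero_boundary(self, rng):
        geno = simdata.simulate_genotypes(150, 500, seed=8)
        y = rng.normal(size=150)
        spec = gblup.MixedModelSpec(
            response=y, fixed_design=np.ones((150, 1)),
            relationship=gblup.vanraden_g(geno),
        )
        vc = gblup.em_reml(spec)
        # estimate is attracted to the zero boundary (REML noise at n=150
        # keeps it from reaching 0 exactly)
        assert gblup.heritability(vc) < 0.12

    def test_nonconvergence_carries_last_iterate(self, rng):
        geno = simdata.simulate_genotypes(60, 200, seed=9)
        trait = simdata.simulate_trait(geno, 0.4, 30, seed=9, include_fixed=False)
        spec = gblup.MixedModelSpec(
            response=trait.phenotypes["trait"].to_numpy(),
            fixed_design=np.ones((60, 1)),
            relationship=gblup.vanraden_g(geno),
        )
        with pytest.raises(gblup.ConvergenceError) as err:
            gblup.em_reml(spec, max_iter=2)
        assert err.value.last.sigma2_m > 0

    def test_gebv_beats_permuted_phenotypes(self, rng):
        geno = simdata.simulate_genotypes(300, 1000, seed=5)
        trait = simdata.simulate_trait(geno, 0.29, 100, seed=5, include_fixed=False)
        y = trait.phenotypes["trait"].to_numpy()
        G = gblup.vanraden_g(geno)

        def corr_with_truth(resp):
            spec = gblup.MixedModelSpec(response=resp, fixed_design=np.ones((300, 1)),
                                        relationship=G)
            fit = gblup.solve_mme(spec, gblup.em_reml(spec))
            return np.corrcoef(fit.gebv, trait.breeding_values)[0, 1]

        real = corr_with_truth(y)
        permuted = corr_with_truth(rng.permutation(y))
        assert real > 0.5
        assert real > abs(permuted)


class TestHeritability:
    def test_reported_variance_components(self):
        h2 = gblup.heritability(gblup.VarianceComponents(0.196, 0.490))
        assert round(h2, 2) == 0.29

    @pytest.mark.parametrize("vc, expected", [((1.0, 1.0), 0.5), ((0.0, 5.0), 0.0)])
    def test_simple_ratios(self, vc, expected):
        assert gblup.heritability(gblup.VarianceComponents(*vc)) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            gblup.VarianceComponents(0.0, 0.0)


class TestSelectExtremes:
    def test_simple_partition(self):
        groups = gblup.select_extremes([-2, -1, 0, 1, 2], 2, list("abcde"))
        assert set(groups.high_ids) == {"e", "d"}
        assert set(groups.low_ids) == {"a", "b"}

    def test_half_and_half_partitions_everything(self):
        groups = gblup.select_extremes([3.0, 1.0, 2.0, 0.0], 2, list("abcd"))
        assert set(groups.high_ids) | set(groups.low_ids) == set("abcd")

    def test_all_ties_use_id_order_and_warn(self):
        with pytest.warns(UserWarning, match="tie"):
            groups = gblup.select_extremes([1.0] * 5, 2, list("edcba"))
        assert groups.low_ids == ["a", "b"]
        assert set(groups.high_ids) == {"d", "e"}

    def test_order_invariance(self, rng):
        vals = rng.normal(size=30)
        ids = [f"x{i}" for i in range(30)]
        ref = gblup.select_extremes(vals, 7, ids)
        perm = rng.permutation(30)
        shuffled = gblup.select_extremes(vals[perm], 7, [ids[i] for i in perm])
        assert set(ref.high_ids) == set(shuffled.high_ids)
        assert set(ref.low_ids) == set(shuffled.low_ids)

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            gblup.select_extremes([1, 2, 3], 2)


class TestWelchTTest:
    def test_identical_groups(self):
        t, df, p = gblup.welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_derived_example(self):
        # means differ by 10, each variance 1/3, SE = sqrt(1/6); df = 6 by symmetry
        t, df, p = gblup.welch_t_test([0, 0, 1, 1], [10, 10, 11, 11])
        assert t == pytest.approx(-10 / np.sqrt(1 / 6), rel=1e-12)
        assert df == pytest.approx(6.0)
        ot, odf, op = welch_t_bruteforce([0, 0, 1, 1], [10, 10, 11, 11])
        assert (t, df, p) == pytest.approx((ot, odf, op))

    def test_extreme_imf_groups_strongly_separated(self):
        low = [1.70, 1.94, 1.86, 1.60, 1.32, 1.58, 1.62]
        high = [4.42, 4.35, 4.38, 5.27, 5.02, 4.74, 4.35]
        t, df, p = gblup.welch_t_test(low, high)
        assert p < 1e-7
        assert (t, df, p) == pytest.approx(welch_t_bruteforce(low, high))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            gblup.welch_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            gblup.welch_t_test([1.0, 1.0], [2.0, 2.0])
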