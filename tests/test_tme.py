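import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellmix import (
    build_state_reference,
    malignant_specificity_filter,
    rank_correlation,
    regress_out_filter,
    signature_score,
)


class TestRankCorrelation:
    def test_identical_column_gives_rho_one(self):
        theta = np.array([0.1, 0.2, 0.3, 0.4])
        Z = np.column_stack([theta, theta[::-1]])
        rho = rank_correlation(Z, theta)
        np.testing.assert_allclose(rho.to_numpy(), [1.0, -1.0], atol=1e-12)

    def test_constant_column_flagged_nan(self):
        theta = np.array([0.1, 0.2, 0.3])
        Z = np.column_stack([np.full(3, 5.0), theta])
        rho = rank_correlation(Z, theta)
        assert np.isnan(rho.iloc[0]) and rho.iloc[1] == pytest.approx(1.0)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(0)
        theta = rng.random(20)
        Z = rng.random((20, 5))
        base = rank_correlation(Z, theta).to_numpy()
        np.testing.assert_allclose(
            rank_correlation(np.exp(Z), theta**3).to_numpy(), base, atol=1e-12
        )

    def test_matches_rank_then_pearson_oracle(self):
        # planted monotone signal plus noise, checked against an
        # independent rank-then-Pearson computation on the same draws
        rng = np.random.default_rng(1)
        medians = []
        for _ in range(20):
            theta = rng.random(30)
            expr = 2 * theta + 0.5 * rng.standard_normal(30)
            rho = rank_correlation(expr[:, None], theta).iloc[0]
            oracle = stats.pearsonr(stats.rankdata(expr), stats.rankdata(theta))[0]
            assert rho == pytest.approx(oracle, abs=1e-12)
            medians.append(rho)
        assert np.median(medians) > 0.5

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            rank_correlation(np.ones((2, 1)), np.array([0.1, 0.2]))


class TestRegressOutFilter:
    def test_type_one_error_calibrated(self):
        # null: fraction depends only on query expression
        rng = np.random.default_rng(2)
        n_sims, N = 1000, 40
        for alpha in (0.01, 0.05):
            hits = 0
            for _ in range(n_sims):
                xq = rng.standard_normal(N)
                y = 0.5 * xq + rng.standard_normal(N)
                xm = rng.standard_normal(N)  # independent malignant track
                _, passes = regress_out_filter(y, xq, xm, alpha_level=alpha)
                hits += passes
            se = np.sqrt(alpha * (1 - alpha) / n_sims)
            assert abs(hits / n_sims - alpha) < 2 * se + 1e-9

    def test_power_when_malignant_expression_drives_fraction(self):
        rng = np.random.default_rng(3)
        N, hits = 200, 0
        for _ in range(50):
            xq = rng.standard_normal(N)
            xm = rng.standard_normal(N)
            y = 0.3 * xq + 0.5 * xm + 0.3 * rng.standard_normal(N)
            _, passes = regress_out_filter(y, xq, xm, alpha_level=0.01)
            hits += passes
        assert hits / 50 > 0.9

    def test_borderline_p_fails_stricter_alpha(self):
        # a gene at p = 0.02 passes alpha 0.05 but not alpha 0.01
        rng = np.random.default_rng(8)
        for _ in range(500):
            xq = rng.standard_normal(30)
            xm = rng.standard_normal(30)
            y = 0.5 * xq + 0.35 * xm + rng.standard_normal(30)
            p, passes_strict = regress_out_filter(y, xq, xm, alpha_level=0.01)
            if 0.015 < p < 0.03:
                assert not passes_strict
                assert regress_out_filter(y, xq, xm, alpha_level=0.05)[1]
                return
        pytest.fail("no borderline p-value generated")

    def test_rank_deficient_design_returns_one(self):
        y = np.array([0.1, 0.2, 0.3, 0.4])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p, passes = regress_out_filter(y, x, 2 * x)  # collinear
        assert p == 1.0 and not passes

    def test_pure_no_mutation(self):
        rng = np.random.default_rng(4)
        y, xq, xm = rng.random(10), rng.random(10), rng.random(10)
        copies = (y.copy(), xq.copy(), xm.copy())
        p1 = regress_out_filter(y, xq, xm)
        p2 = regress_out_filter(y, xq, xm)
        assert p1 == p2
        for a, b in zip((y, xq, xm), copies):
            np.testing.assert_array_equal(a, b)


class TestMalignantSpecificity:
    def _ref(self):
        # gene0: malignant-dominant; gene1: environment; gene2: flat
        counts = np.array(
            [
                [800, 100, 100],
                [750, 150, 100],
                [40, 800, 160],
                [50, 750, 200],
            ]
        )
        return build_state_reference(
            counts,
            ["m1", "m1", "env1", "env1"],
            ["mal", "mal", "env", "env"],
            ["gA", "gB", "gC"],
            malignant_type="mal",
        )

    def test_dominant_gene_passes_absent_and_flat_fail(self):
        flags = self._ref()
        out = malignant_specificity_filter(flags)
        assert bool(out["gA"]) is True
        assert bool(out["gB"]) is False  # environment gene
        assert bool(out["gC"]) is False  # no fold advantage

    def test_no_malignant_type_errors(self):
        ref = build_state_reference(
            np.ones((2, 2)), ["s", "s"], ["t", "t"], ["a", "b"]
        )
        with pytest.raises(ValueError, match="malignant"):
            malignant_specificity_filter(ref)


class TestSignatureScore:
    def _inputs(self):
        genes = ["m1", "m2", "m3", "m4"]
        sig = pd.DataFrame(
            {"A": [10.0, 5.0, 2.0, 1.0], "B": [1.0, 2.0, 5.0, 10.0]}, index=genes
        )
        return genes, sig

    def test_matching_profile_scores_highest(self):
        genes, sig = self._inputs()
        expr = np.array([[10.0, 5.0, 2.0, 1.0], [1.0, 2.0, 5.0, 10.0]])
        theta = np.array([0.5, 0.5])
        out = signature_score(expr, ["s1", "s2"], genes, sig, genes, theta)
        assert out.scores.loc["s1", "A"] == pytest.approx(1.0, abs=1e-9)
        assert out.scores.loc["s1", "A"] > out.scores.loc["s1", "B"]
        assert out.scores.loc["s2", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_low_fraction_sample_excluded(self):
        genes, sig = self._inputs()
        expr = np.ones((2, 4))
        theta = np.array([0.04, 0.5])  # first sample below the 5% floor
        out = signature_score(expr, ["lo", "hi"], genes, sig, genes, theta)
        assert list(out.scores.index) == ["hi"]

    def test_reflected_profiles_give_opposite_scores(self):
        genes = ["m1", "m2", "m3", "m4"]
        a = np.array([10.0, 5.0, 2.0, 1.0])
        # B is an affine reflection of A, so Pearson scores flip sign
        sig = pd.DataFrame({"A": a, "B": 11.0 - a}, index=genes)
        rng = np.random.default_rng(5)
        expr = rng.random((3, 4))
        theta = np.full(3, 0.5)
        out = signature_score(expr, list("xyz"), genes, sig, genes, theta,
                              transform="none")
        # profile B is the reflection of A, so scores are mirror images
        np.testing.assert_allclose(
            out.scores["A"].to_numpy(), -out.scores["B"].to_numpy(), atol=1e-9
        )

    def test_no_passing_sample_errors(self):
        genes, sig = self._inputs()
        with pytest.raises(ValueError, match="fraction filter"):
            signature_score(np.ones((1, 4)), ["s"], genes, sig, genes,
                            np.array([0.01]))
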