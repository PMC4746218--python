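"""Scalar DE statistics against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tcut.core import split_by_threshold
from tcut.de_stats import (
    ALL_STATS,
    ModerationPriors,
    b_stat,
    batch_stat_values,
    compute_stat_matrix,
    estimate_eb_priors,
    estimate_sam_s0,
    fold_change,
    moderated_t,
    ordinary_t,
    sam_stat,
    wmw_pvalue,
    wmw_pvalues,
)

from conftest import make_study


def exact_wmw_oracle(x_small, x_large):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x_small, x_large])
    n1 = len(x_small)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n1)]
    )
    pl = np.mean(ws <= w_obs)
    pg = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(pl, pg))


class TestWMW:
    def test_small_exact_case(self):
        # all C(4,2)=6 assignments: rank-sum of {1,2} is the unique minimum
        assert wmw_pvalue([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples(self):
        assert wmw_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_n4(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert wmw_pvalue(a, b) == pytest.approx(exact_wmw_oracle(a, b), abs=1e-12)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            wmw_pvalue([], [1.0, 2.0])

    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=6, unique=True),
           st.lists(st.integers(51, 100), min_size=3, max_size=6, unique=True))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, a, b):
        # ranks are invariant under strictly increasing maps of the pooled data
        # (integer inputs so the transform cannot create float ties)
        a, b = np.array(a, dtype=float), np.array(b, dtype=float)
        f = lambda x: np.exp(x / 25.0) + x
        assert wmw_pvalue(a, b) == pytest.approx(wmw_pvalue(f(a), f(b)), rel=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10_000, 60))
        mask = np.arange(60) < 30
        p = wmw_pvalues(X, mask)
        ks = sps.kstest(p, "uniform").statistic
        assert ks < 0.02

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 20))
        mask = np.arange(20) < 9
        vec = wmw_pvalues(X, mask)
        scal = [wmw_pvalue(row[mask], row[~mask]) for row in X]
        np.testing.assert_allclose(vec, scal, atol=1e-12)


class TestTandFC:
    def test_t_hand_computed(self):
        # pooled sd 1, se sqrt(2/3): t = -3 / 0.8165
        assert ordinary_t([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.674, abs=5e-4)

    def test_t_symmetry_zero(self):
        assert ordinary_t([1, 2, 3], [1, 2, 3]) == 0.0

    def test_t_constant_equal_groups(self):
        assert ordinary_t([2, 2, 2], [2, 2, 2]) == 0.0

    def test_fc_arithmetic(self):
        assert fold_change([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)
        assert fold_change([1, 2], [1, 2]) == 0.0

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6),
           st.lists(st.floats(-10, 10), min_size=2, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_antisymmetry_under_group_swap(self, a, b):
        for f in (ordinary_t, fold_change, lambda x, y: sam_stat(x, y, 0.5)):
            assert f(a, b) == pytest.approx(-f(b, a), abs=1e-9)


class TestSAM:
    def test_s0_zero_is_ordinary_t(self):
        a, b = [1.0, 2.5, 3.0], [4.0, 5.5, 7.0]
        assert sam_stat(a, b, 0.0) == pytest.approx(ordinary_t(a, b))

    def test_large_s0_shrinks_to_zero(self):
        assert abs(sam_stat([1, 2, 3], [4, 5, 6], 1e9)) < 1e-8

    def test_hand_computed(self):
        # -3 / (0.8165 + 1) = -1.6515
        assert sam_stat([1, 2, 3], [4, 5, 6], 1.0) == pytest.approx(
            -3.0 / (np.sqrt(2 / 3) + 1.0)
        )

    def test_s0_selection_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        diff = rng.normal(size=200)
        se = np.abs(rng.normal(1.0, 0.5, size=200)) + 0.01

        # plain nested-loop re-implementation of the percentile/CV recipe
        cands = np.percentile(se, np.arange(0, 101, 5))
        order = np.argsort(se, kind="stable")
        bins = np.array_split(order, 10)
        cvs = []
        for s0 in cands:
            d = diff / (se + s0)
            mads = [np.median(np.abs(d[b] - np.median(d[b]))) for b in bins]
            cvs.append(np.std(mads, ddof=1) / np.mean(mads))
        expected = cands[int(np.argmin(cvs))]

        assert estimate_sam_s0(diff, se) == pytest.approx(expected)

    def test_zero_se_guarded(self):
        diff = np.array([1.0, -1.0, 0.5, 2.0])
        se = np.zeros(4)
        s0 = estimate_sam_s0(diff, se)
        assert s0 > 0
        assert np.isfinite(sam_stat([1, 1], [1, 1], s0))

    def test_identical_se_degenerate(self):
        diff = np.linspace(-1, 1, 50)
        se = np.full(50, 0.7)
        s0 = estimate_sam_s0(diff, se)
        assert np.isfinite(s0) and s0 > 0


class TestModeration:
    def test_prior_recovery_from_simulated_variances(self):
        # gene variances ~ scaled-inv-chi2(df0=4, scale=2); sample variances
        # are then chi-square noisy versions with residual df 10
        rng = np.random.default_rng(0)
        d0, s02, df = 4.0, 2.0, 10
        sigma2 = d0 * s02 / rng.chisquare(d0, size=10_000)
        s2 = sigma2 * rng.chisquare(df, size=10_000) / df
        priors = estimate_eb_priors(s2, df)
        assert priors.prior_df == pytest.approx(d0, rel=0.20)
        assert priors.prior_var == pytest.approx(s02, rel=0.10)

    def test_equal_variances_hit_cap(self):
        priors = estimate_eb_priors(np.full(100, 3.0), 8)
        assert priors.prior_df >= 1e5
        assert priors.prior_var == pytest.approx(3.0, rel=1e-3)

    def test_single_gene_fallback(self):
        with pytest.warns(RuntimeWarning):
            priors = estimate_eb_priors(np.array([1.0]), 5)
        assert priors.prior_df == 0.0

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        priors = ModerationPriors(prior_df=0.0, prior_var=1.0)
        mod_t, mod_f = moderated_t(a, b, priors)
        assert mod_t == pytest.approx(ordinary_t(a, b))
        assert mod_f == pytest.approx(mod_t**2)

    def test_infinite_prior_df_full_shrinkage(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        priors = ModerationPriors(prior_df=1e12, prior_var=4.0)
        mod_t, _ = moderated_t(a, b, priors)
        diff = np.mean(a) - np.mean(b)
        assert mod_t == pytest.approx(diff / np.sqrt(4.0 * (1 / 3 + 1 / 3)), rel=1e-4)

    def test_moderated_between_limits(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        t0 = abs(ordinary_t(a, b))
        priors = ModerationPriors(prior_df=3.0, prior_var=9.0)
        tm = abs(moderated_t(a, b, priors)[0])
        tinf = abs(moderated_t(a, b, ModerationPriors(1e12, 9.0))[0])
        lo, hi = sorted([t0, tinf])
        assert lo <= tm <= hi


class TestBStat:
    priors = ModerationPriors(prior_df=4.0, prior_var=1.0, de_proportion=0.01,
                              effect_var_scale=2.0)

    def test_symmetric_in_t(self):
        for t in (0.0, 1.3, 4.2):
            assert b_stat(t, 10, self.priors) == pytest.approx(
                b_stat(-t, 10, self.priors)
            )

    def test_strictly_increasing_in_abs_t(self):
        grid = np.linspace(0, 20, 200)
        vals = b_stat(grid, 10, self.priors)
        assert np.all(np.diff(vals) > 0)

    def test_vanishing_de_proportion_clamped(self):
        tiny = ModerationPriors(4.0, 1.0, de_proportion=1e-300, effect_var_scale=2.0)
        assert b_stat(0.0, 10, tiny, floor=-500.0) == -500.0


class TestComputeStatMatrix:
    def test_columns_match_scalar_ops(self, toy_study):
        split = split_by_threshold(toy_study, 3.0)
        sm = compute_stat_matrix(toy_study, split, ALL_STATS, fold=False)
        xs = toy_study.expression[:, split.small_mask]
        xl = toy_study.expression[:, ~split.small_mask]

        np.testing.assert_allclose(
            sm.column("t"), [ordinary_t(a, b) for a, b in zip(xs, xl)], atol=1e-10
        )
        np.testing.assert_allclose(
            sm.column("FC"), [fold_change(a, b) for a, b in zip(xs, xl)], atol=1e-10
        )
        # SAM: one s0 shared across genes, matching the estimator on this panel
        n1, n2 = xs.shape[1], xl.shape[1]
        diffs = np.array([fold_change(a, b) for a, b in zip(xs, xl)])
        pooled_sd = np.sqrt(
            ((n1 - 1) * np.var(xs, axis=1, ddof=1) + (n2 - 1) * np.var(xl, axis=1, ddof=1))
            / (n1 + n2 - 2)
        )
        ses = pooled_sd * np.sqrt(1 / n1 + 1 / n2)
        s0 = estimate_sam_s0(diffs, ses)
        np.testing.assert_allclose(
            sm.column("SAM"),
            [sam_stat(a, b, s0) for a, b in zip(xs, xl)],
            atol=1e-8,
        )
        # moderated t from the panel-level priors
        df = toy_study.n_samples - 2
        pooled = np.array(
            [
                ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
                for a, b in zip(xs, xl)
            ]
        )
        priors = estimate_eb_priors(pooled, df)
        np.testing.assert_allclose(
            sm.column("modT"),
            [moderated_t(a, b, priors)[0] for a, b in zip(xs, xl)],
            rtol=1e-6,
        )
        np.testing.assert_allclose(sm.column("modF"), sm.column("modT") ** 2, rtol=1e-9)

    def test_folding_non_negative(self, toy_study):
        split = split_by_threshold(toy_study, 3.0)
        sm = compute_stat_matrix(toy_study, split, ALL_STATS, fold=True)
        for name in ("t", "SAM", "FC", "modT"):
            assert np.all(sm.column(name) >= 0)

    def test_fold_matches_abs_of_unfolded(self, toy_study):
        split = split_by_threshold(toy_study, 3.0)
        folded = compute_stat_matrix(toy_study, split, ALL_STATS, fold=True)
        raw = compute_stat_matrix(toy_study, split, ALL_STATS, fold=False)
        for name in ("t", "SAM", "FC", "modT"):
            np.testing.assert_allclose(folded.column(name), np.abs(raw.column(name)))
        for name in ("B", "modF"):
            np.testing.assert_allclose(folded.column(name), raw.column(name))

    def test_invalid_split_rejected(self, toy_study):
        split = split_by_threshold(toy_study, 0.5)  # everything "large"
        with pytest.raises(ValueError, match="invalid split"):
            compute_stat_matrix(toy_study, split)

    def test_de_rows_have_larger_t(self):
        study = make_study(n_features=200, n_small=20, n_large=20, n_de=50,
                           effect=3.0, seed=9)
        split = split_by_threshold(study, 3.0)
        sm = compute_stat_matrix(study, split, ("t",), fold=True)
        t = sm.column("t")
        assert np.median(t[:50]) > 3 * np.median(t[50:])

    def test_batch_rows_match_single_mask_calls(self, toy_study):
        rng = np.random.default_rng(0)
        masks = np.zeros((4, toy_study.n_samples), dtype=bool)
        for b in range(4):
            masks[b, rng.choice(toy_study.n_samples, 5, replace=False)] = True
        batch = batch_stat_values(toy_study.expression, masks, ALL_STATS, fold=True)
        for b in range(4):
            single = batch_stat_values(
                toy_study.expression, masks[b][None, :], ALL_STATS, fold=True
            )[0]
            np.testing.assert_allclose(batch[b], single, rtol=1e-10)
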