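"""Statistical primitives against independent oracles, plus cohort analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stnbeta.stats import (
    bh_fdr,
    build_cohort,
    compare_biomarkers,
    correlation_profile,
    explained_variance,
    hotelling_dependent_corr_test,
    spearman,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def spearman_bruteforce(x, y):
    """Rank both vectors (average ties), then plain Pearson."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def wilcoxon_enumeration(d):
    """Full 2^n sign-flip null for W = min(T+, T-)."""
    d = np.asarray(d, float)
    ranks = rankdata(np.abs(d))
    total = ranks.sum()
    t_plus = ranks[d > 0].sum()
    w_obs = min(t_plus, total - t_plus)
    stats = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        tp = ranks[np.array(signs, bool)].sum()
        stats.append(tp)
    stats = np.array(stats)
    p = 2.0 * np.mean(stats <= w_obs + 1e-9)
    return w_obs, min(p, 1.0)


def bh_stepup_enumeration(p):
    """Literal q_i = min_{j >= i} p_(j) * m / j on the sorted vector."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6)  # 1 - 6*8/(5*24)

    def test_monotone_identity(self):
        x = np.array([1.0, 4.0, 9.0, 16.0, 30.0])
        assert spearman(x, np.exp(x / 10))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 20).astype(float)  # heavy ties
        y = x + rng.integers(0, 4, 20)
        assert spearman(x, y)[0] == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# hotelling
# ---------------------------------------------------------------------------

class TestHotelling:
    def test_null_identity(self):
        t, p = hotelling_dependent_corr_test(0.4, 0.4, 0.7, 26)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, p1 = hotelling_dependent_corr_test(0.6, 0.2, 0.5, 26)
        t2, p2 = hotelling_dependent_corr_test(0.2, 0.6, 0.5, 26)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_matrix_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            hotelling_dependent_corr_test(0.95, -0.95, 0.9, 26)

    def test_against_monte_carlo_null(self):
        """Closed-form p agrees with a simulated sampling-distribution p.

        The null keeps both predictors equally correlated with the
        criterion (Spearman structure matching the observed r12); the
        simulated two-sided tail beyond the observed statistic must
        match the t-distribution p within ±0.01.
        """
        r1, r2, r12, n = 0.6, 0.2, 0.5, 26
        t_obs, p_closed = hotelling_dependent_corr_test(r1, r2, r12, n)
        rng = np.random.default_rng(123)
        reps = 100_000
        rho_c, rho_p = 0.4, r12  # common criterion corr; predictor corr
        cov = np.array([[1, rho_p, rho_c], [rho_p, 1, rho_c], [rho_c, rho_c, 1]])
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((reps, n, 3)) @ L.T
        ranks = np.empty_like(z)
        for j in range(3):
            ranks[:, :, j] = rankdata(z[:, :, j], axis=1)
        ranks -= ranks.mean(axis=1, keepdims=True)
        ranks /= np.sqrt((ranks**2).sum(axis=1, keepdims=True))
        s1 = (ranks[:, :, 0] * ranks[:, :, 2]).sum(axis=1)
        s2 = (ranks[:, :, 1] * ranks[:, :, 2]).sum(axis=1)
        s12 = (ranks[:, :, 0] * ranks[:, :, 1]).sum(axis=1)
        det = 1 - s1**2 - s2**2 - s12**2 + 2 * s1 * s2 * s12
        t_sim = (s1 - s2) * np.sqrt((n - 3) * (1 + s12) / (2 * det))
        p_mc = np.mean(np.abs(t_sim) >= abs(t_obs))
        assert p_mc == pytest.approx(p_closed, abs=0.01)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_single_p(self):
        q, reject = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03) and reject[0]

    def test_stepup_example(self):
        q, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_no_rejections(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_empty_error(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_stepup_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 21))
        q, _ = bh_fdr(p)
        np.testing.assert_allclose(q, bh_stepup_enumeration(p), atol=1e-12)

    def test_fdr_controlled_under_null(self):
        """Empirical FDR under independent uniform nulls stays <= alpha."""
        rng = np.random.default_rng(99)
        m, reps, alpha = 100, 2000, 0.05
        fdp = np.empty(reps)
        for r in range(reps):
            _, reject = bh_fdr(rng.uniform(size=m), alpha=alpha)
            n_rej = reject.sum()
            fdp[r] = 1.0 if n_rej else 0.0  # all rejections are false here
        assert fdp.mean() <= alpha + 0.02


# ---------------------------------------------------------------------------
# wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_hand_example_vs_enumeration(self):
        d = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        w, p = wilcoxon_signed_rank(d, np.zeros(5))
        w_o, p_o = wilcoxon_enumeration(d)
        assert w == w_o and p == pytest.approx(p_o, abs=1e-12)

    @pytest.mark.parametrize("n", range(5, 11))
    def test_matches_enumeration_all_small_n(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.standard_normal(n)
            d += 0.3  # mix of signs with nonzero shift
            d[d == 0] = 0.1
            w, p = wilcoxon_signed_rank(d, np.zeros(n))
            w_o, p_o = wilcoxon_enumeration(d)
            assert w == pytest.approx(w_o) and p == pytest.approx(p_o, abs=1e-12)

    def test_constant_shift_extreme(self):
        y = np.arange(8, dtype=float)
        w, p = wilcoxon_signed_rank(y + 2.0, y)
        assert w == 0.0
        assert p == pytest.approx(2.0 * 0.5**8)  # minimal two-sided p at n=8

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        assert wilcoxon_signed_rank(x, y)[1] == pytest.approx(
            wilcoxon_signed_rank(y, x)[1]
        )

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40) + 0.8
        _, p = wilcoxon_signed_rank(x, np.zeros(40))
        assert p < 0.01  # strong planted shift must be detected


# ---------------------------------------------------------------------------
# explained variance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rho, pct", [(np.sqrt(0.47), 47.0), (1.0, 100.0), (-0.5, 25.0), (0.0, 0.0)]
)
def test_explained_variance(rho, pct):
    assert explained_variance(rho) == pytest.approx(pct)


# ---------------------------------------------------------------------------
# cohort-level
# ---------------------------------------------------------------------------

def _toy_cohort(n=26, seed=0, contamination=0.0, rho=0.75):
    """Biomarker+clinical table with a planted beta-score coupling."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    rho_p = 2 * np.sin(np.pi * rho / 6)
    score = rho_p * z + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    without = 2.0 + z
    with_bb = without + contamination * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "hemisphere_id": [f"h{i}" for i in range(n)],
            "beta_without_bb": without,
            "beta_with_bb": with_bb,
            "actual_without_bb": without + 0.05 * rng.standard_normal(n),
            "actual_with_bb": with_bb + 0.05 * rng.standard_normal(n),
            "bradykinesia": score,
            "rigidity": score + 0.3 * rng.standard_normal(n),
            "tremor": rng.standard_normal(n),
            "age": rng.uniform(45, 78, n),
        }
    )


class TestCompareBiomarkers:
    def test_zero_contamination_limit(self):
        """With no broadband variance the two biomarkers are identical."""
        cohort = _toy_cohort(contamination=0.0)
        out = compare_biomarkers(cohort, n_boot=0)
        m = out[out.pathway == "modeled"]
        np.testing.assert_allclose(m.r_without, m.r_with, atol=1e-12)
        np.testing.assert_allclose(m.t_stat, 0.0, atol=1e-12)

    def test_planted_contamination_detected(self):
        cohort = _toy_cohort(contamination=4.0, seed=3)
        m = compare_biomarkers(cohort, n_boot=0).query("pathway=='modeled'")
        r = m.set_index("symptom")
        assert r.loc["B", "q_without"] < 0.05
        assert r.loc["B", "r_without"] > r.loc["B", "r_with"]

    def test_shuffled_scores_rarely_survive_fdr(self):
        rng = np.random.default_rng(17)
        survived = 0
        n_shuffles = 20
        for _ in range(n_shuffles):
            cohort = _toy_cohort(contamination=3.0, seed=5)
            perm = rng.permutation(len(cohort))
            for col in ("bradykinesia", "rigidity", "tremor"):
                cohort[col] = cohort[col].to_numpy()[perm]
            m = compare_biomarkers(cohort, n_boot=0).query("pathway=='modeled'")
            survived += (m.q_compare < 0.05).any()
        assert survived <= 2  # >= 90% of shuffles show nothing

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="at least 10"):
            compare_biomarkers(_toy_cohort(n=8))

    def test_power_with_calibrated_attenuation(self):
        """Planted Spearman rho=0.6 at n=26; independent contamination
        attenuates the with-background correlation to <= 0.2.

        The dependent-correlation comparison must then reject the
        equality null in a clear majority of replicates.  (At this
        effect size the test's power plateaus around 0.65 regardless of
        how heavy the contamination is made, because the correlation
        between the two biomarkers — which drives the test's precision
        — shrinks together with the with-background correlation.)
        """
        rng = np.random.default_rng(42)
        n, reps = 26, 500
        rho_p = 2 * np.sin(np.pi * 0.6 / 6)
        rejections = 0
        r_with_all = []
        for _ in range(reps):
            z = rng.standard_normal(n)
            score = rho_p * z + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
            with_bb = z + 6.0 * rng.standard_normal(n)
            r1, _ = spearman(z, score)
            r2, _ = spearman(with_bb, score)
            r12, _ = spearman(z, with_bb)
            r_with_all.append(r2)
            try:
                _, p = hotelling_dependent_corr_test(r1, r2, r12, n)
            except ValueError:
                continue
            rejections += p < 0.05
        assert abs(np.mean(r_with_all)) <= 0.2  # calibration of the attenuation
        assert rejections / reps >= 0.60


class TestCorrelationProfile:
    def test_planted_bands_recovered(self):
        rng = np.random.default_rng(6)
        n, grid = 26, np.arange(1.0, 201.0)
        age = rng.uniform(45, 78, n)
        # low frequencies decrease with age, high frequencies increase
        low = np.exp(-grid / 15)[None, :] * (80 - age)[:, None]
        high = (grid > 120)[None, :] * 0.02 * age[:, None]
        profiles = low + high + 0.3 * rng.standard_normal((n, grid.size))
        prof = correlation_profile(profiles, age, grid)
        assert (prof[(prof.frequency_hz < 30) & prof.reject].rho < 0).any()
        assert (prof[(prof.frequency_hz > 150) & prof.reject].rho > 0).any()

    def test_independent_covariate_few_rejections(self):
        rng = np.random.default_rng(7)
        n, grid = 26, np.arange(1.0, 101.0)
        profiles = rng.standard_normal((n, grid.size))
        cov = rng.standard_normal(n)
        prof = correlation_profile(profiles, cov, grid)
        assert prof.reject.sum() <= 0.05 * grid.size

    def test_permutation_destroys_significance(self):
        rng = np.random.default_rng(8)
        n, grid = 26, np.arange(1.0, 201.0)
        age = rng.uniform(45, 78, n)
        profiles = np.exp(-grid / 15)[None, :] * (80 - age)[:, None]
        profiles += 0.2 * rng.standard_normal((n, grid.size))
        rejections = [
            correlation_profile(profiles, rng.permutation(age), grid).reject.sum()
            for _ in range(20)
        ]
        assert np.median(rejections) == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="n_hemispheres"):
            correlation_profile(np.ones((5, 3)), np.ones(4), np.arange(3.0))


class TestBuildCohort:
    def test_unmatched_ids_listed(self):
        bio = pd.DataFrame({"hemisphere_id": ["a", "b"], "beta_without_bb": [1, 2],
                            "beta_with_bb": [2, 3]})
        clin = pd.DataFrame({"hemisphere_id": ["a", "c"], "bradykinesia": [1, 2],
                             "rigidity": [1, 2], "tremor": [0, 0], "age": [60, 61]})
        with pytest.raises(ValueError, match="b, c"):
            build_cohort(bio, clin)

    def test_missing_column_named(self):
        bio = pd.DataFrame({"hemisphere_id": ["a"], "beta_without_bb": [1],
                            "beta_with_bb": [2]})
        clin = pd.DataFrame({"hemisphere_id": ["a"], "bradykinesia": [1],
                             "tremor": [0], "age": [60]})
        with pytest.raises(ValueError, match="rigidity"):
            build_cohort(bio, clin)
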