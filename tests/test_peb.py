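import numpy as np
import pytest

from dcmrel.peb import (
    DesignMatrix,
    PEBConfig,
    build_design,
    fit_peb,
    flag_differences,
    peb_of_pebs,
    peb_per_family,
    second_level_precision,
)
from dcmrel.priors import ParameterDensity, ParameterIndex

P = 4
INDEX = ParameterIndex([f"H[x{i}]" for i in range(P)], ["H"] * P)
PRIOR = ParameterDensity(np.zeros(P), 0.5 * np.eye(P), INDEX)
PRIOR_SD = np.sqrt(0.5)


def _subject_posterior(theta, rng, obs=0.05):
    """Informative Gaussian posterior as produced by a first-level fit."""
    P_like = np.eye(P) / obs**2
    P_post = P_like + PRIOR.precision()
    S = np.linalg.inv(P_post)
    m = S @ (P_like @ (theta + rng.normal(0, obs, P)))
    return ParameterDensity(m, S, INDEX)


def _group(mu, rng, n=8, tau=0.1, obs=0.05):
    return [
        _subject_posterior(mu + rng.normal(0, tau, P), rng, obs) for _ in range(n)
    ]


class TestBuildDesign:
    def test_mean_only(self):
        d = build_design(3)
        assert d.X.shape == (3, 1)
        assert np.allclose(d.X, 1.0)
        assert d.labels == ("mean",)

    def test_group_indicator(self):
        d = build_design(4, covariates=[0.0, 0.0, 1.0, 1.0], labels=["group"])
        assert d.X.shape == (4, 2)
        assert np.allclose(d.X[:, 1], [0, 0, 1, 1])
        assert d.labels[1] == "group"

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            build_design(3, covariates=np.ones((3, 1)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            build_design(3, covariates=[1.0, 2.0])


class TestSecondLevelPrecision:
    def test_block_structure_matches_brute_force_kron(self):
        cfg = PEBConfig(precision_floor=1e-4, q1=np.diag([1.0, 2.0, 3.0]))
        gamma = 0.7
        Pi2 = second_level_precision(gamma, cfg, p=3, n=4)
        block = 1e-4 * np.eye(3) + np.exp(-gamma) * np.diag([1.0, 2.0, 3.0])
        assert np.allclose(Pi2, np.kron(np.eye(4), block))

    def test_gamma_limits(self):
        cfg = PEBConfig(precision_floor=1e-6, q1=np.eye(2))
        hi = second_level_precision(40.0, cfg, p=2, n=1)
        assert np.allclose(hi, 1e-6 * np.eye(2), atol=1e-12)
        at0 = second_level_precision(0.0, cfg, p=2, n=1)
        assert np.allclose(at0, (1e-6 + 1.0) * np.eye(2))

    def test_identical_diagonal_blocks(self):
        cfg = PEBConfig(q1=np.eye(3))
        Pi2 = second_level_precision(0.3, cfg, p=3, n=5)
        assert Pi2.shape == (15, 15)
        b0 = Pi2[:3, :3]
        for k in range(1, 5):
            assert np.allclose(Pi2[3 * k : 3 * k + 3, 3 * k : 3 * k + 3], b0)
        off = Pi2.copy()
        for k in range(5):
            off[3 * k : 3 * k + 3, 3 * k : 3 * k + 3] = 0
        assert np.allclose(off, 0)

    def test_non_psd_q1_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            PEBConfig(q1=-np.eye(2))


class TestFitPeb:
    def test_identical_posteriors_recover_shared_mean(self):
        rng = np.random.default_rng(1)
        shared = _subject_posterior(np.array([0.3, -0.2, 0.1, 0.4]), rng, obs=0.005)
        res = fit_peb([shared] * 12, PRIOR)
        assert np.abs(res.effect(0).mean - shared.mean).max() < 1e-3

    def test_single_subject_degenerate_hierarchy(self):
        rng = np.random.default_rng(2)
        q = _subject_posterior(np.array([0.2, 0.0, -0.3, 0.1]), rng)
        res = fit_peb([q], PRIOR)
        # the random-effects layer shrinks a lone subject mildly; the
        # group mean must stay within a fraction of the prior sd
        assert np.abs(res.effect(0).mean - q.mean).max() < 0.15 * PRIOR_SD

    def test_covariate_effect_recovered_with_coverage(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            beta = 0.6
            x = rng.normal(0, 1, 10)
            posts = [
                _subject_posterior(
                    np.array([0.2, -0.1, 0.0, 0.3]) + beta * xi * np.eye(P)[0],
                    rng,
                    obs=0.05,
                )
                for xi in x
            ]
            design = build_design(10, covariates=x, labels=["cov"])
            res = fit_peb(posts, PRIOR, design)
            eff = res.effect(1)
            lo = eff.mean[0] - 1.645 * np.sqrt(eff.cov[0, 0])
            hi = eff.mean[0] + 1.645 * np.sqrt(eff.cov[0, 0])
            hits += lo <= beta <= hi
        assert hits >= 16  # 90% CI covers in >= 80% of replicates

    def test_trajectory_monotone(self):
        rng = np.random.default_rng(3)
        res = fit_peb(_group(np.zeros(P), rng), PRIOR)
        assert np.all(np.diff(res.trajectory) >= -1e-9)

    def test_pooling_beats_no_pooling_under_shared_mean(self):
        # relative to the no-pooling baseline (delta F identically 0)
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            res = fit_peb(_group(np.array([0.3, 0.1, -0.2, 0.0]), rng), PRIOR)
            wins += res.free_energy > 0
        assert wins >= 5

    def test_index_mismatch_rejected(self):
        other = ParameterDensity(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            fit_peb([other], PRIOR)

    def test_reestimates_returned_per_subject(self):
        rng = np.random.default_rng(4)
        g = _group(np.zeros(P), rng, n=5)
        res = fit_peb(g, PRIOR)
        assert len(res.reestimated) == 5
        for q in res.reestimated:
            assert q.size == P
            assert np.linalg.eigvalsh(q.cov).min() > 0

    def test_per_family_split(self):
        names = ["H[a]", "H[b]", "A[x]", "A[y]"]
        idx = ParameterIndex(names, ["H", "H", "A", "A"])
        prior = ParameterDensity(np.zeros(4), np.eye(4) * 0.3, idx)
        rng = np.random.default_rng(5)
        posts = []
        for _ in range(6):
            m = rng.normal(0, 0.2, 4)
            posts.append(ParameterDensity(m, np.eye(4) * 0.01 + 0.29 * np.eye(4) * 0, idx))
        # make posterior precision exceed prior precision
        posts = [
            ParameterDensity(q.mean, np.linalg.inv(np.eye(4) * 100 + prior.precision()), idx)
            for q in posts
        ]
        out = peb_per_family(posts, prior)
        assert set(out) == {"H", "A"}
        assert out["H"].p == 2 and out["A"].p == 2


class TestPebOfPebs:
    def _two_groups(self, seed, shift=None):
        rng = np.random.default_rng(seed)
        mu = np.array([0.3, -0.2, 0.0, 0.5])
        g1 = _group(mu, rng)
        mu2 = mu.copy()
        if shift is not None:
            mu2 = mu2 + shift
        g2 = _group(mu2, rng)
        return fit_peb(g1, PRIOR, reestimate=False), fit_peb(
            g2, PRIOR, reestimate=False
        )

    def test_null_difference_effects_small(self):
        total_below = 0
        for seed in range(10):
            r1, r2 = self._two_groups(seed)
            tab = flag_differences(peb_of_pebs([r1, r2], PRIOR))
            total_below += (tab.posterior_prob < 0.95).sum()
        assert total_below >= 0.95 * 10 * P

    def test_injected_difference_flagged(self):
        flagged = 0
        for seed in range(10):
            shift = np.zeros(P)
            shift[2] = 4 * PRIOR_SD
            r1, r2 = self._two_groups(seed, shift)
            tab = flag_differences(peb_of_pebs([r1, r2], PRIOR))
            flagged += bool(tab.loc[tab.parameter == "H[x2]", "flagged"].iloc[0])
        assert flagged >= 9

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(6)
        g1 = _group(np.zeros(P), rng)
        a = fit_peb(g1, PRIOR, reestimate=False)
        b = fit_peb(list(reversed(g1)), PRIOR, reestimate=False)
        assert np.allclose(a.posterior.mean, b.posterior.mean, atol=1e-10)
        assert np.allclose(a.free_energy, b.free_energy, atol=1e-8)

    def test_wrong_group_count(self):
        r1, r2 = self._two_groups(0)
        with pytest.raises(ValueError):
            peb_of_pebs([r1], PRIOR)


class TestFlagDifferences:
    def test_no_indicator_column_rejected(self):
        rng = np.random.default_rng(7)
        res = fit_peb(_group(np.zeros(P), rng), PRIOR)
        with pytest.raises(ValueError, match="indicator"):
            flag_differences(res)

    def test_zero_effects_unflagged(self):
        r1, r2 = TestPebOfPebs()._two_groups(11)
        tab = flag_differences(peb_of_pebs([r1, r2], PRIOR))
        assert len(tab) == P
        assert tab.flagged.sum() <= P  # bound always holds
        assert not tab.flagged.any()

    def test_single_large_effect_flagged_exclusively(self):
        shift = np.zeros(P)
        shift[1] = 5 * PRIOR_SD
        r1, r2 = TestPebOfPebs()._two_groups(12, shift)
        tab = flag_differences(peb_of_pebs([r1, r2], PRIOR))
        assert list(tab[tab.flagged].parameter) == ["H[x1]"]
        row = tab[tab.flagged].iloc[0]
        assert row.ci_lower < row.expectation < row.ci_upper
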