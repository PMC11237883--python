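import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dcmrel.csd import CrossSpectrum, hermitian_psd_project
from dcmrel.forward import ModelContext, _predict_batch
from dcmrel.inversion import (
    InversionConfig,
    VariationalLaplace,
    csd_feature_vector,
    free_energy,
    gaussian_kl,
    invert,
)
from dcmrel.network import default_network
from dcmrel.priors import ParameterDensity, PriorTable
from .conftest import prior_sd_vector

FREQS = np.arange(2.0, 50.0, 4.0)


def _linear_predictor(A):
    def predict(thetas):
        return np.atleast_2d(thetas) @ A.T

    return predict


def _exact_linear_posterior(A, y, sigma, prior):
    P0 = np.linalg.inv(prior.cov)
    P = A.T @ A / sigma**2 + P0
    S = np.linalg.inv(P)
    mu = S @ (A.T @ y / sigma**2 + P0 @ prior.mean)
    return mu, S


@pytest.fixture(scope="module")
def dcm_fixture():
    priors = PriorTable()
    net = default_network(1)
    ctx = ModelContext(net, priors, freqs=FREQS)
    rng = np.random.default_rng(11)
    sd = prior_sd_vector(priors, ctx.index)
    theta_true = rng.normal(0, 0.4 * sd)
    vals, valid = _predict_batch(theta_true[None], ctx)
    assert valid[0]
    data = CrossSpectrum(FREQS, hermitian_psd_project(vals[0]), net.region_names)
    return priors, net, ctx, theta_true, data


class TestLinearGaussianOracles:
    def test_posterior_matches_gls_and_f_matches_evidence(self):
        rng = np.random.default_rng(0)
        n, d, sigma = 24, 5, 0.4
        A = rng.normal(size=(n, d))
        theta = rng.normal(size=d)
        y = A @ theta + sigma * rng.normal(size=n)
        prior = ParameterDensity(np.zeros(d), 2.0 * np.eye(d))
        vl = VariationalLaplace(
            _linear_predictor(A),
            y,
            prior,
            InversionConfig(max_iterations=16, f_tolerance=1e-9, patience=2),
            fixed_noise_log_precision=np.array([np.log(1 / sigma**2)]),
        )
        out = vl.run()
        mu, S = _exact_linear_posterior(A, y, sigma, prior)
        assert np.allclose(out["theta"], mu, atol=1e-6)
        assert np.allclose(out["cov"], S, atol=1e-6)
        log_ev = multivariate_normal.logpdf(
            y, mean=A @ prior.mean, cov=sigma**2 * np.eye(n) + A @ prior.cov @ A.T
        )
        assert out["free_energy"] == pytest.approx(log_ev, abs=1e-6)

    def test_uninformed_parameter_stays_at_prior(self):
        # read-out of the second parameter is ablated: its posterior must
        # remain (essentially) the prior
        rng = np.random.default_rng(1)
        A = np.column_stack([rng.normal(size=30), np.zeros(30)])
        y = A[:, 0] * 1.5 + 0.1 * rng.normal(size=30)
        prior = ParameterDensity(np.zeros(2), np.eye(2))
        vl = VariationalLaplace(
            _linear_predictor(A),
            y,
            prior,
            fixed_noise_log_precision=np.array([np.log(100.0)]),
        )
        out = vl.run()
        assert abs(out["theta"][1]) < 0.05
        assert out["cov"][1, 1] == pytest.approx(1.0, rel=1e-6)

    def test_posterior_no_larger_than_prior_when_informed(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(40, 3))
        y = A @ rng.normal(size=3) + 0.2 * rng.normal(size=40)
        prior = ParameterDensity(np.zeros(3), np.eye(3))
        vl = VariationalLaplace(
            _linear_predictor(A), y, prior,
            fixed_noise_log_precision=np.array([np.log(25.0)]),
        )
        out = vl.run()
        assert np.all(np.diag(out["cov"]) <= 1.0 + 1e-9)


class TestFreeEnergy:
    def test_kl_zero_at_prior(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        assert gaussian_kl(prior, prior) == pytest.approx(0.0, abs=1e-10)

    def test_noise_inflation_closed_form(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        # a sharply-peaked q makes the curvature term negligible
        q = ParameterDensity(prior.mean, 1e-16 * np.eye(prior.size), prior.index)
        lam1, lam2 = 0.0, np.log(4.0)
        F1 = free_energy(data, q, prior, ctx, lam1)
        F2 = free_energy(data, q, prior, ctx, lam2)
        pred, _ = _predict_batch(prior.mean[None], ctx)
        e = csd_feature_vector(data.values) - csd_feature_vector(pred[0])
        N = e.size
        expected = (
            -0.5 * float(e @ e) * (np.exp(lam2) - np.exp(lam1))
            + 0.5 * N * (lam2 - lam1)
        )
        assert F2 - F1 == pytest.approx(expected, rel=1e-9)

    def test_nonpsd_q_rejected(self, dcm_fixture):
        priors, net, ctx, _, data = dcm_fixture
        prior = priors.prior_density(net)
        bad = -np.eye(prior.size)
        with pytest.raises(ValueError):
            ParameterDensity(prior.mean, bad)


class TestInvertDCM:
    def test_noiseless_recovery(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        res = invert(data, prior, ctx, InversionConfig(max_iterations=32))
        sd = prior.sd()
        identifiable = res.posterior.sd() < 0.9 * sd
        assert identifiable.sum() >= 5
        r = np.corrcoef(theta_true[identifiable], res.posterior.mean[identifiable])[0, 1]
        assert r >= 0.9

    def test_trajectory_monotone(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        res = invert(data, prior, ctx, InversionConfig(max_iterations=16))
        assert np.all(np.diff(res.trajectory) >= -1e-9)

    def test_deterministic(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        cfg = InversionConfig(max_iterations=6)
        r1 = invert(data, prior, ctx, cfg)
        r2 = invert(data, prior, ctx, cfg)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.posterior.mean, r2.posterior.mean)

    def test_posterior_psd(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        res = invert(data, prior, ctx, InversionConfig(max_iterations=8))
        w = np.linalg.eigvalsh(res.posterior.cov)
        assert w.min() > 0

    def test_frequency_mismatch_rejected(self, dcm_fixture):
        priors, net, ctx, theta_true, data = dcm_fixture
        prior = priors.prior_density(net)
        other = ModelContext(net, priors, freqs=np.arange(1.0, 9.0))
        with pytest.raises(ValueError, match="frequency"):
            invert(data, prior, other)


class TestFeatureVector:
    def test_roundtrip_content(self, rng):
        vals = rng.normal(size=(3, 2, 2)) + 1j * rng.normal(size=(3, 2, 2))
        vals = vals + np.conj(np.swapaxes(vals, 1, 2))
        feat = csd_feature_vector(vals)
        assert feat.shape == (3 * 4,)
        assert feat[0] == vals[0, 0, 0].real
        assert feat[3] == vals[0, 0, 1].imag

    def test_batched(self, rng):
        vals = rng.normal(size=(5, 3, 2, 2)) * (1 + 0j)
        feat = csd_feature_vector(vals)
        assert feat.shape == (5, 12)
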