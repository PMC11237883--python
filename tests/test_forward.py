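import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmrel.constants import G_LEAK, ModelConstants
from dcmrel.forward import (
    FixedPointError,
    ModelContext,
    StabilityError,
    _derivatives_batch,
    _fixed_point_batch,
    _jacobian_batch,
    _delay_correct_batch,
    _predict_batch,
    _scale_batch,
    find_fixed_point,
    firing_rate,
    magnesium_switch,
    predict_csd,
    resolvent_transfer,
    scale_parameters,
    state_derivatives,
    system_jacobian,
    transfer_function,
)
from dcmrel.network import default_network
from dcmrel.priors import PriorTable
from .conftest import prior_sd_vector


class TestScaleParameters:
    def test_prior_mean_reproduces_scaling_constants(self, priors, net2, ctx2):
        p = scale_parameters(np.zeros(ctx2.index.size), priors, net2)
        assert np.allclose(p.kappa_ms[0], [[4.0, 16.0, 100.0]] * 2)
        assert np.allclose(
            p.capacitance[0], [[0.128, 0.128, 0.256, 0.032]] * 2
        )
        base = [m for (_, _, m, _) in priors.intrinsic_template]
        assert np.allclose(p.intrinsic[0], [base, base])
        assert np.allclose(p.ampa_ext[0], 1.0 / 8.0)
        assert np.allclose(p.nmda_ext[0], 1.0 / 8.0)
        assert np.allclose(p.gain[0], np.e)
        assert np.allclose(p.readout[0], [0.2, 0.2])
        assert np.allclose(p.delays_ms[0], [2.0, 16.0])

    def test_log_doubling_is_local(self, priors, net2, ctx2):
        theta = np.zeros(ctx2.index.size)
        k1 = ctx2.index.position("kappa[R1.ampa]")
        theta[k1] = np.log(2.0)
        p = scale_parameters(theta, priors, net2)
        assert np.isclose(p.kappa_ms[0, 0, 0], 8.0)
        assert np.isclose(p.kappa_ms[0, 0, 1], 16.0)
        assert np.isclose(p.kappa_ms[0, 1, 0], 4.0)

    def test_wrong_dimension_raises(self, priors, net2):
        with pytest.raises(KeyError, match="coordinates"):
            scale_parameters(np.zeros(7), priors, net2)

    def test_positive_for_positive_scaling(self, priors, net2, ctx2, rng):
        theta = rng.normal(0, 2, ctx2.index.size)
        p = scale_parameters(theta, priors, net2)
        for arr in (p.kappa_ms, p.capacitance, p.intrinsic, p.gain):
            assert np.all(arr > 0)


class TestNonlinearities:
    def test_magnesium_at_zero(self):
        assert np.isclose(magnesium_switch(0.0), 1.0 / 1.2)

    def test_magnesium_limits(self):
        assert magnesium_switch(1e4) == pytest.approx(1.0)
        assert magnesium_switch(-1e4) == pytest.approx(0.0, abs=1e-12)

    @given(
        v1=st.floats(-150, 150),
        delta=st.floats(1e-3, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_magnesium_monotone(self, v1, delta):
        assert magnesium_switch(v1) < magnesium_switch(v1 + delta)

    def test_firing_half_at_threshold(self, constants):
        assert firing_rate(constants.sigmoid_threshold, constants) == 0.5

    def test_firing_limits(self, constants):
        assert firing_rate(-1e5, constants) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e5, constants) == pytest.approx(1.0)

    def test_firing_derivative_maximal_at_threshold(self, constants):
        # finite-difference scan across the voltage axis
        v = np.linspace(-120.0, 40.0, 3201)
        s = firing_rate(v, constants)
        deriv = np.gradient(s, v)
        v_star = v[np.argmax(deriv)]
        assert abs(v_star - constants.sigmoid_threshold) < 0.1


class TestDerivativesAndFixedPoint:
    def test_leak_only_reduction(self, priors, net1, constants):
        ctx = ModelContext(net1, priors, constants)
        p = _scale_batch(np.zeros((1, ctx.index.size)), priors, net1)
        x = np.zeros(ctx.n_states)
        x[ctx.iV] = -55.0
        dx = state_derivatives(x, np.zeros(1), p, net1, constants)
        expected = G_LEAK * (constants.v_leak + 55.0) / p.capacitance[0].ravel()
        assert np.allclose(dx[ctx.iV], expected)

    def test_doubling_capacitance_halves_dv(self, priors, net1, constants, ctx1):
        theta = np.zeros(ctx1.index.size)
        p1 = scale_parameters(theta, priors, net1)
        theta_c = theta.copy()
        for pop in ("ss", "sp", "inh", "dp"):
            theta_c[ctx1.index.position(f"C[R1.{pop}]")] = np.log(2.0)
        p2 = scale_parameters(theta_c, priors, net1)
        x = np.zeros(ctx1.n_states)
        x[ctx1.iV] = -60.0
        x[ctx1.iA] = 1.0
        d1 = state_derivatives(x, np.zeros(1), p1, net1, constants)
        d2 = state_derivatives(x, np.zeros(1), p2, net1, constants)
        assert np.allclose(d2[ctx1.iV], d1[ctx1.iV] / 2)
        assert np.allclose(d2[ctx1.iA], d1[ctx1.iA])

    def test_nonfinite_state_rejected(self, priors, net1, constants):
        p = scale_parameters(np.zeros(33), priors, net1)
        x = np.full(16, np.nan)
        with pytest.raises(FloatingPointError):
            state_derivatives(x, np.zeros(1), p, net1, constants)

    def test_fixed_point_residual(self, priors, net2, constants, ctx2):
        p = scale_parameters(np.zeros(ctx2.index.size), priors, net2)
        x0 = find_fixed_point(p, net2, constants)
        dx = state_derivatives(x0, np.zeros(2), p, net2, constants)
        assert np.max(np.abs(dx)) < 1e-6

    def test_isolated_leak_equilibrium(self):
        # remove all synaptic wiring: equilibrium is the leak reversal
        priors = PriorTable(intrinsic_template=())
        net = default_network(1)
        p = scale_parameters(np.zeros(priors.build_index(net).size), priors, net)
        ctx = ModelContext(net, priors)
        x0, ok = _fixed_point_batch(p, ctx)
        assert ok.all()
        assert np.allclose(x0[0][ctx.iV], ModelConstants().v_leak)
        assert np.allclose(x0[0][ctx.iA], 0.0)

    def test_deterministic(self, priors, net2, constants):
        p = scale_parameters(np.zeros(54), priors, net2)
        x_a = find_fixed_point(p, net2, constants)
        x_b = find_fixed_point(p, net2, constants)
        assert np.array_equal(x_a, x_b)

    @pytest.mark.parametrize("nr", [1, 2, 4])
    def test_prior_mean_stable(self, priors, constants, nr):
        net = default_network(nr)
        ctx = ModelContext(net, priors, constants)
        p = _scale_batch(np.zeros((1, ctx.index.size)), priors, net)
        x0, ok = _fixed_point_batch(p, ctx)
        assert ok.all()
        Jd = _delay_correct_batch(_jacobian_batch(x0, p, ctx), p, ctx)
        lam = np.linalg.eigvals(Jd[0])
        assert lam.real.max() < 0


class TestSystemJacobian:
    def test_matches_finite_differences(self, priors, net2, constants, ctx2):
        p = _scale_batch(np.zeros((1, ctx2.index.size)), priors, net2)
        x0, _ = _fixed_point_batch(p, ctx2)
        J = _jacobian_batch(x0, p, ctx2)[0]
        eps = 1e-6
        u0 = np.zeros((1, 2))
        Jfd = np.empty_like(J)
        for j in range(ctx2.n_states):
            xp, xm = x0.copy(), x0.copy()
            xp[0, j] += eps
            xm[0, j] -= eps
            Jfd[:, j] = (
                _derivatives_batch(xp, u0, p, ctx2)[0]
                - _derivatives_batch(xm, u0, p, ctx2)[0]
            ) / (2 * eps)
        scale = np.abs(Jfd).max()
        assert np.abs(J - Jfd).max() / scale < 1e-5

    def test_random_draws_match_finite_differences(self, priors, net2, constants, ctx2):
        # 100 draws within +-2 prior sd; unstable/non-equilibrated draws
        # are excluded from the comparison but counted
        rng = np.random.default_rng(7)
        sd = prior_sd_vector(priors, ctx2.index)
        draws = np.clip(rng.normal(0, sd, (100, ctx2.index.size)), -2 * sd, 2 * sd)
        p = _scale_batch(draws, priors, net2)
        x0, ok = _fixed_point_batch(p, ctx2)
        assert ok.mean() > 0.5
        J = _jacobian_batch(x0, p, ctx2)
        eps = 1e-6
        u0 = np.zeros((100, 2))
        worst = 0.0
        for j in range(ctx2.n_states):
            xp, xm = x0.copy(), x0.copy()
            xp[:, j] += eps
            xm[:, j] -= eps
            col = (
                _derivatives_batch(xp, u0, p, ctx2)
                - _derivatives_batch(xm, u0, p, ctx2)
            ) / (2 * eps)
            err = np.abs(J[ok][:, :, j] - col[ok]).max()
            worst = max(worst, err)
        scale = np.abs(J[ok]).max()
        assert worst / scale < 1e-5

    def test_zero_delays_identity(self, net2, constants):
        priors = PriorTable(delay_scale=(0.0, 0.0))
        ctx = ModelContext(net2, priors, constants)
        p = _scale_batch(np.zeros((1, ctx.index.size)), priors, net2)
        x0, _ = _fixed_point_batch(p, ctx)
        raw = system_jacobian(p, net2, x0[0], constants, apply_delays=False)
        corrected = _delay_correct_batch(raw[None], p, ctx)[0]
        assert np.allclose(raw, corrected)

    def test_no_extrinsic_block_diagonal(self, net2, constants):
        priors = PriorTable()
        ctx = ModelContext(net2, priors, constants, extrinsic_gain=0.0)
        p = _scale_batch(np.zeros((1, ctx.index.size)), priors, net2)
        x0, _ = _fixed_point_batch(p, ctx)
        J = _jacobian_batch(x0, p, ctx)[0]
        off = J[:16, 16:], J[16:, :16]
        assert np.allclose(off[0], 0) and np.allclose(off[1], 0)


class TestTransferFunction:
    def test_scalar_lorentzian_oracle(self):
        lam = 3.0
        freqs = np.linspace(0.5, 20, 40)
        K = resolvent_transfer(np.array([[-lam]]), [[1.0]], [[1.0]], freqs)
        omega = 2 * np.pi * freqs
        assert np.allclose(np.abs(K[:, 0, 0]) ** 2, 1.0 / (lam**2 + omega**2))

    def test_dc_limit(self, priors, net2, constants, ctx2):
        p = _scale_batch(np.zeros((1, ctx2.index.size)), priors, net2)
        x0, _ = _fixed_point_batch(p, ctx2)
        Jd = _delay_correct_batch(_jacobian_batch(x0, p, ctx2), p, ctx2)[0]
        tf = transfer_function(p, net2, np.array([1e-9]), constants)
        # reconstruct W and B from the context for the direct formula
        K_direct = resolvent_transfer(Jd, _readout_matrix(p, ctx2), ctx2.input_matrix, [1e-9])
        assert np.allclose(tf.values[0], K_direct[0], rtol=1e-6)
        dc = -_readout_matrix(p, ctx2) @ np.linalg.solve(Jd, ctx2.input_matrix)
        assert np.allclose(tf.values[0], dc, rtol=1e-5, atol=1e-12)

    def test_conjugate_symmetry(self, priors, net2, constants, ctx2):
        p = _scale_batch(np.zeros((1, ctx2.index.size)), priors, net2)
        x0, _ = _fixed_point_batch(p, ctx2)
        Jd = _delay_correct_batch(_jacobian_batch(x0, p, ctx2), p, ctx2)[0]
        W = _readout_matrix(p, ctx2)
        Kp = resolvent_transfer(Jd, W, ctx2.input_matrix, [7.0])
        Km = resolvent_transfer(Jd, W, ctx2.input_matrix, [-7.0])
        assert np.allclose(Km, np.conj(Kp))

    def test_unstable_jacobian_raises(self, priors, net2, constants, ctx2):
        # implausibly long conduction delays flip the delay-corrected
        # Jacobian into the right half plane
        theta = np.zeros(ctx2.index.size)
        theta[ctx2.index.family_indices("D")] = 3.0
        theta[ctx2.index.family_indices("kappa")] = -1.0
        p = _scale_batch(theta[None], priors, net2)
        with pytest.raises(StabilityError, match="eigenvalue"):
            transfer_function(p, net2, np.arange(1.0, 10.0), constants)


def _readout_matrix(p, ctx):
    import numpy as np
    from dcmrel.constants import POPULATIONS

    nr = ctx.net.n_regions
    W = np.zeros((nr, ctx.n_states))
    jw = np.zeros(4)
    jw[POPULATIONS.index("ss")] = p.readout[0, 0]
    jw[POPULATIONS.index("sp")] = 0.8
    jw[POPULATIONS.index("dp")] = p.readout[0, 1]
    for r in range(nr):
        pops = np.arange(4 * r, 4 * r + 4)
        W[r, ctx.iV[pops]] = p.gain[0, r] * jw
    return W


class TestPredictCsd:
    def test_hermitian_psd_slices(self, priors, net2, constants, rng):
        sd = prior_sd_vector(priors, PriorTable().build_index(net2))
        ctx = ModelContext(net2, priors, constants)
        for _ in range(5):
            theta = rng.normal(0, 0.5 * sd)
            csd = predict_csd(theta, priors, net2, constants)
            assert csd.is_hermitian()
            for sl in csd.values:
                assert np.linalg.eigvalsh((sl + sl.conj().T) / 2).min() >= -1e-10

    def test_zero_input_reduces_to_noise(self, priors, net2, constants, ctx2):
        from dcmrel.spectra import noise_spectrum

        theta = np.zeros(ctx2.index.size)
        theta[ctx2.index.position("a[1]")] = -745.0  # exp underflows to exactly 0
        csd = predict_csd(theta, priors, net2, constants)
        go = noise_spectrum(
            np.zeros(2), np.zeros(2), np.zeros(2), csd.frequencies, 2
        )
        assert np.allclose(csd.values, go, atol=1e-20)

    def test_gain_scaling_is_quadratic(self, priors, net2, constants, ctx2):
        from dcmrel.spectra import noise_spectrum

        s = 1.7
        theta = np.zeros(ctx2.index.size)
        base = predict_csd(theta, priors, net2, constants)
        for r in ("R1", "R2"):
            theta[ctx2.index.position(f"L[{r}]")] = np.log(s)
        scaled = predict_csd(theta, priors, net2, constants)
        go = noise_spectrum(np.zeros(2), np.zeros(2), np.zeros(2), base.frequencies, 2)
        neuronal_base = base.values - go
        neuronal_scaled = scaled.values - go
        assert np.allclose(neuronal_scaled, s**2 * neuronal_base, rtol=1e-6)

    def test_no_extrinsic_factorises(self, priors, net2, constants):
        from dcmrel.spectra import noise_spectrum

        ctx = ModelContext(net2, priors, constants, extrinsic_gain=0.0)
        theta = np.zeros((1, ctx.index.size))
        csd, valid = _predict_batch(theta, ctx)
        assert valid.all()
        go = noise_spectrum(np.zeros(2), np.zeros(2), np.zeros(2), ctx.freqs, 2)
        # cross-region entries reduce to the common-noise term alone
        assert np.allclose(csd[0][:, 0, 1], go[:, 0, 1], atol=1e-18)

    def test_instability_propagates(self, priors, net2, constants):
        idx = PriorTable().build_index(net2)
        theta = np.zeros(idx.size)
        theta[idx.family_indices("D")] = 3.0
        theta[idx.family_indices("kappa")] = -1.0
        with pytest.raises((StabilityError, FixedPointError)):
            predict_csd(theta, priors, net2, constants)
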