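"""Conductance-based canonical microcircuit forward model.

Maps log-scale parameter deviations to predicted source-space
cross-spectral densities via:

1. natural-scale parameters (``theta0 * exp(theta_hat)``),
2. a stable fixed point of the population dynamics,
3. the delay-corrected system Jacobian at that fixed point,
4. the frequency transfer function (resolvent of the Jacobian),
5. the spectral response ``K gu K* + go``.

Each population carries four states: mean depolarisation ``V`` and the
AMPA, GABA and NMDA conductances.  State layout is region-major,
population-minor: for region ``r`` and population ``p`` (order ss, sp,
inh, dp), states ``(V, gA, gG, gN)`` occupy indices
``4*(4*r + p) ... 4*(4*r + p) + 3``.

All heavy routines are internally batched over a leading axis of
parameter vectors; the public single-model operations are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import G_LEAK, POPULATIONS, ModelConstants
from .csd import CrossSpectrum, hermitian_psd_project
from .network import NetworkSpec
from .priors import KAPPA_CHANNELS, EXTRINSIC_MASKS, ParameterDensity, PriorTable
from .spectra import frequency_scaling, input_spectrum, noise_spectrum

__all__ = [
    "StabilityError",
    "FixedPointError",
    "NaturalParameters",
    "ModelContext",
    "TransferFunction",
    "scale_parameters",
    "magnesium_switch",
    "firing_rate",
    "state_derivatives",
    "find_fixed_point",
    "system_jacobian",
    "transfer_function",
    "predict_csd",
]


class StabilityError(RuntimeError):
    """Raised when the linearised model is not asymptotically stable."""


class FixedPointError(RuntimeError):
    """Raised when no equilibrium could be located."""


# --------------------------------------------------------------------------
# scalar nonlinearities
# --------------------------------------------------------------------------

def magnesium_switch(V, constants: ModelConstants | None = None):
    """Voltage-dependent magnesium gate, ``1 / (1 + 0.2 exp(-alpha V))``."""
    constants = constants or ModelConstants()
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + 0.2 * np.exp(-constants.alpha_nmda * V))


def _magnesium_grad(V, constants: ModelConstants):
    m = magnesium_switch(V, constants)
    a = constants.alpha_nmda
    return 0.2 * a * np.exp(-a * np.asarray(V, dtype=float)) * m * m


def firing_rate(V, constants: ModelConstants | None = None):
    """Logistic firing sigmoid in [0, 1]; value 1/2 at the threshold."""
    constants = constants or ModelConstants()
    V = np.asarray(V, dtype=float)
    z = constants.sigmoid_slope * (V - constants.sigmoid_threshold)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _firing_grad(V, constants: ModelConstants):
    s = firing_rate(V, constants)
    return constants.sigmoid_slope * s * (1.0 - s)


# --------------------------------------------------------------------------
# natural-scale parameters
# --------------------------------------------------------------------------

@dataclass
class NaturalParameters:
    """Natural-scale parameter set (arrays carry a leading batch axis).

    Spectral families (a, d, b, c, f) are stored as log-scale values;
    they enter the spectral forms through their own parameterisation.
    """

    kappa_ms: np.ndarray   # (B, nr, 3) channel time constants, ms
    capacitance: np.ndarray  # (B, nr, 4)
    intrinsic: np.ndarray  # (B, nr, n_template) connection strengths
    ampa_ext: np.ndarray   # (B, n_edges)
    nmda_ext: np.ndarray   # (B, n_edges)
    gain: np.ndarray       # (B, nr) sensor gain L
    readout: np.ndarray    # (B, 2) natural J weights (ss, dp)
    a: np.ndarray          # (B, 2) log scale
    d: np.ndarray          # (B, 4) log scale
    b: np.ndarray          # (B, 2) log scale
    c: np.ndarray          # (B, 2) log scale
    f: np.ndarray          # (B, 2) log scale
    delays_ms: np.ndarray  # (B, 2) intrinsic, extrinsic

    @property
    def n_batch(self) -> int:
        return self.kappa_ms.shape[0]

    def single(self, i: int = 0) -> "NaturalParameters":
        return NaturalParameters(
            *(getattr(self, f.name)[i : i + 1] for f in self.__dataclass_fields__.values())
        )


def _family_slices(index) -> dict[str, slice]:
    slices: dict[str, slice] = {}
    for fam in index.present_families():
        idx = index.family_indices(fam)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"family {fam} is not contiguous in the index")
        if idx.size:
            slices[fam] = slice(int(idx[0]), int(idx[-1]) + 1)
    return slices


def _scale_batch(
    theta: np.ndarray, priors: PriorTable, net: NetworkSpec
) -> NaturalParameters:
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    index = priors.build_index(net)
    if theta.shape[1] != index.size:
        raise KeyError(
            f"theta has {theta.shape[1]} coordinates but the prior index "
            f"defines {index.size}"
        )
    sl = _family_slices(index)
    B, nr = theta.shape[0], net.n_regions
    ntpl = len(priors.intrinsic_template)

    def block(fam: str) -> np.ndarray:
        return theta[:, sl[fam]] if fam in sl else np.zeros((B, 0))

    kappa = np.exp(block("kappa")).reshape(B, nr, 3) * np.asarray(priors.kappa_scale)
    cap = np.exp(block("C")).reshape(B, nr, 4) * np.asarray(priors.capacitance_scale)
    h_base = np.array([m for (_, _, m, _) in priors.intrinsic_template])
    intrinsic = np.exp(block("H")).reshape(B, nr, ntpl) * h_base
    ampa = np.exp(block("A")) * priors.extrinsic_scale
    nmda = np.exp(block("AN")) * priors.extrinsic_scale
    gain = np.exp(theta[:, sl["L"]]) * priors.gain_scale
    readout = np.exp(theta[:, sl["J"]]) * np.asarray(priors.j_scale)
    delays = np.exp(theta[:, sl["D"]]) * np.asarray(priors.delay_scale)
    return NaturalParameters(
        kappa_ms=kappa,
        capacitance=cap,
        intrinsic=intrinsic,
        ampa_ext=ampa,
        nmda_ext=nmda,
        gain=gain,
        readout=readout,
        a=theta[:, sl["a"]],
        d=theta[:, sl["d"]],
        b=theta[:, sl["b"]],
        c=theta[:, sl["c"]],
        f=theta[:, sl["f"]],
        delays_ms=delays,
    )


def scale_parameters(
    theta_hat: np.ndarray, priors: PriorTable, net: NetworkSpec
) -> NaturalParameters:
    """Map log-scale deviations to natural-scale parameters.

    At ``theta_hat = 0`` every family reproduces its scaling constant
    exactly (e.g. kappa = (4, 16, 100) ms, C = (0.128, 0.128, 0.256,
    0.032)).
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_hat.ndim != 1:
        raise ValueError("theta_hat must be a vector; use the batch API otherwise")
    return _scale_batch(theta_hat[None, :], priors, net)


# --------------------------------------------------------------------------
# model context: fixed structural wiring
# --------------------------------------------------------------------------

#: Normalisation applied to connection strengths when assembling the
#: population drive matrices.  The printed intrinsic magnitudes are
#: interpreted relative to this reference drive; the value is chosen so
#: that the prior-mean network is asymptotically stable with margin.
COUPLING_NORM = 1.0 / 16.0

#: Extrinsic connections are additionally boosted relative to their 1/8
#: prior scaling so that between-region coupling is visible in the
#: cross-spectra at the prior mean.
EXTRINSIC_GAIN = 32.0


class ModelContext:
    """Precomputed wiring for a (network, priors, constants, freqs) tuple."""

    def __init__(
        self,
        net: NetworkSpec,
        priors: PriorTable | None = None,
        constants: ModelConstants | None = None,
        freqs: np.ndarray | None = None,
        coupling_norm: float = COUPLING_NORM,
        extrinsic_gain: float = EXTRINSIC_GAIN,
    ):
        self.coupling_norm = coupling_norm
        self.extrinsic_gain = extrinsic_gain
        self.net = net
        self.priors = priors or PriorTable()
        self.constants = constants or ModelConstants()
        self.freqs = np.asarray(
            freqs if freqs is not None else np.arange(1.0, 65.0), dtype=float
        )
        self.index = self.priors.build_index(net)

        nr, npop = net.n_regions, 4
        self.n_pop_total = nr * npop
        self.n_states = 4 * self.n_pop_total

        pop_ids = np.arange(self.n_pop_total)
        self.iV = 4 * pop_ids
        self.iA = 4 * pop_ids + 1
        self.iG = 4 * pop_ids + 2
        self.iN = 4 * pop_ids + 3
        self.region_of_pop = pop_ids // npop

        # intrinsic template -> (row, col) in the population coupling matrix
        tpl = self.priors.intrinsic_template
        rows, cols, exc = [], [], []
        for r in range(nr):
            for tgt, src, _, cls in tpl:
                rows.append(r * npop + POPULATIONS.index(tgt))
                cols.append(r * npop + POPULATIONS.index(src))
                exc.append(cls == "exc")
        self.h_rows = np.array(rows, dtype=int)
        self.h_cols = np.array(cols, dtype=int)
        self.h_exc = np.array(exc, dtype=bool)

        # extrinsic edges -> target rows / source columns
        e_rows, e_cols, e_edge = [], [], []
        for e, (kind, src, tgt) in enumerate(net.edges):
            mask = EXTRINSIC_MASKS[kind]
            src_pop = POPULATIONS.index(mask["source"])
            r_src, r_tgt = net.region_index(src), net.region_index(tgt)
            for tgt_pop in mask["targets"]:
                e_rows.append(r_tgt * npop + POPULATIONS.index(tgt_pop))
                e_cols.append(r_src * npop + src_pop)
                e_edge.append(e)
        self.e_rows = np.array(e_rows, dtype=int)
        self.e_cols = np.array(e_cols, dtype=int)
        self.e_edge = np.array(e_edge, dtype=int)

        # delay masks between states (same population: none)
        pop_of_state = np.repeat(pop_ids, 4)
        reg_of_state = np.repeat(self.region_of_pop, 4)
        same_pop = pop_of_state[:, None] == pop_of_state[None, :]
        same_reg = reg_of_state[:, None] == reg_of_state[None, :]
        self.delay_mask_intrinsic = (~same_pop & same_reg).astype(float)
        self.delay_mask_extrinsic = (~same_reg).astype(float)

        # endogenous input: one channel per region, driving ss depolarisation
        self.input_matrix = np.zeros((self.n_states, nr))
        for r in range(nr):
            ss = r * npop + POPULATIONS.index("ss")
            self.input_matrix[self.iV[ss], r] = 1.0

    # -- coupling matrices -------------------------------------------------

    def coupling(self, params: NaturalParameters):
        """Population-level drive matrices (S_ampa, S_gaba, S_nmda)."""
        B, n = params.n_batch, self.n_pop_total
        s_exc = np.zeros((B, n, n))
        s_inh = np.zeros((B, n, n))
        w = params.intrinsic.reshape(B, -1) * self.coupling_norm
        s_exc[:, self.h_rows[self.h_exc], self.h_cols[self.h_exc]] = w[:, self.h_exc]
        s_inh[:, self.h_rows[~self.h_exc], self.h_cols[~self.h_exc]] = w[:, ~self.h_exc]
        s_ampa = s_exc.copy()
        s_nmda = s_exc.copy()
        if self.e_edge.size:
            ext = self.coupling_norm * self.extrinsic_gain
            s_ampa[:, self.e_rows, self.e_cols] += ext * params.ampa_ext[:, self.e_edge]
            s_nmda[:, self.e_rows, self.e_cols] += ext * params.nmda_ext[:, self.e_edge]
        return s_ampa, s_inh, s_nmda

    def rates(self, params: NaturalParameters) -> np.ndarray:
        """Per-population channel rates in 1/s: (B, n_pop_total, 3)."""
        kappa = 1000.0 / params.kappa_ms  # (B, nr, 3)
        return np.repeat(kappa, 4, axis=1)

    def capacitance_per_pop(self, params: NaturalParameters) -> np.ndarray:
        return params.capacitance.reshape(params.n_batch, -1)  # (B, n_pop_total)


# --------------------------------------------------------------------------
# dynamics, equilibrium, Jacobian (batched)
# --------------------------------------------------------------------------

def _derivatives_batch(
    x: np.ndarray, u: np.ndarray, params: NaturalParameters, ctx: ModelContext
) -> np.ndarray:
    cst = ctx.constants
    B = x.shape[0]
    V, gA, gG, gN = x[:, ctx.iV], x[:, ctx.iA], x[:, ctx.iG], x[:, ctx.iN]
    C = ctx.capacitance_per_pop(params)
    m = magnesium_switch(V, cst)
    current = (
        G_LEAK * (cst.v_leak - V)
        + gA * (cst.v_ampa - V)
        + gG * (cst.v_gaba - V)
        + gN * m * (cst.v_nmda - V)
    )
    dV = current / C + np.einsum("sr,br->bs", ctx.input_matrix[ctx.iV], u)
    sig = firing_rate(V, cst)
    s_ampa, s_gaba, s_nmda = ctx.coupling(params)
    k = ctx.rates(params)  # (B, npt, 3)
    dgA = k[:, :, 0] * (np.einsum("bij,bj->bi", s_ampa, sig) - gA)
    dgG = k[:, :, 1] * (np.einsum("bij,bj->bi", s_gaba, sig) - gG)
    dgN = k[:, :, 2] * (np.einsum("bij,bj->bi", s_nmda, sig) - gN)
    dx = np.empty_like(x)
    dx[:, ctx.iV] = dV
    dx[:, ctx.iA] = dgA
    dx[:, ctx.iG] = dgG
    dx[:, ctx.iN] = dgN
    return dx


def _jacobian_batch(
    x: np.ndarray, params: NaturalParameters, ctx: ModelContext
) -> np.ndarray:
    """Analytic Jacobian of the flow at states x: (B, ns, ns)."""
    cst = ctx.constants
    B, ns = x.shape
    V, gA, gG, gN = x[:, ctx.iV], x[:, ctx.iA], x[:, ctx.iG], x[:, ctx.iN]
    C = ctx.capacitance_per_pop(params)
    m = magnesium_switch(V, cst)
    dm = _magnesium_grad(V, cst)
    J = np.zeros((B, ns, ns))
    iV, iA, iG, iN = ctx.iV, ctx.iA, ctx.iG, ctx.iN
    dVdV = (
        -G_LEAK - gA - gG + gN * (dm * (cst.v_nmda - V) - m)
    ) / C
    J[:, iV, iV] = dVdV
    J[:, iV, iA] = (cst.v_ampa - V) / C
    J[:, iV, iG] = (cst.v_gaba - V) / C
    J[:, iV, iN] = m * (cst.v_nmda - V) / C
    sig_grad = _firing_grad(V, cst)  # (B, npt)
    s_ampa, s_gaba, s_nmda = ctx.coupling(params)
    k = ctx.rates(params)
    # conductance wrt presynaptic depolarisation
    J[:, iA[:, None], iV[None, :]] = k[:, :, 0, None] * s_ampa * sig_grad[:, None, :]
    J[:, iG[:, None], iV[None, :]] = k[:, :, 1, None] * s_gaba * sig_grad[:, None, :]
    J[:, iN[:, None], iV[None, :]] = k[:, :, 2, None] * s_nmda * sig_grad[:, None, :]
    J[:, iA, iA] = -k[:, :, 0]
    J[:, iG, iG] = -k[:, :, 1]
    J[:, iN, iN] = -k[:, :, 2]
    return J


def _equilibrium_current(V, S, cst, scale=1.0):
    """Net membrane current per population with conductances eliminated.

    At equilibrium g* = S sigma(V); substituting reduces the root-finding
    problem to depolarisation space.  ``scale`` homotopes the synaptic
    coupling (0 = leak only).
    """
    s_ampa, s_gaba, s_nmda = S
    sig = firing_rate(V, cst)
    gA = scale * np.einsum("bij,bj->bi", s_ampa, sig)
    gG = scale * np.einsum("bij,bj->bi", s_gaba, sig)
    gN = scale * np.einsum("bij,bj->bi", s_nmda, sig)
    m = magnesium_switch(V, cst)
    F = (
        G_LEAK * (cst.v_leak - V)
        + gA * (cst.v_ampa - V)
        + gG * (cst.v_gaba - V)
        + gN * m * (cst.v_nmda - V)
    )
    return F, (gA, gG, gN)


def _equilibrium_current_jac(V, S, cst, scale=1.0):
    s_ampa, s_gaba, s_nmda = S
    sig = firing_rate(V, cst)
    dsig = _firing_grad(V, cst)
    gA = scale * np.einsum("bij,bj->bi", s_ampa, sig)
    gG = scale * np.einsum("bij,bj->bi", s_gaba, sig)
    gN = scale * np.einsum("bij,bj->bi", s_nmda, sig)
    m = magnesium_switch(V, cst)
    dm = _magnesium_grad(V, cst)
    n = V.shape[1]
    J = (
        scale * s_ampa * ((cst.v_ampa - V)[:, :, None] * dsig[:, None, :])
        + scale * s_gaba * ((cst.v_gaba - V)[:, :, None] * dsig[:, None, :])
        + scale * s_nmda * ((m * (cst.v_nmda - V))[:, :, None] * dsig[:, None, :])
    )
    diag = -G_LEAK - gA - gG + gN * (dm * (cst.v_nmda - V) - m)
    J[:, np.arange(n), np.arange(n)] += diag
    return J


def _fixed_point_batch(
    params: NaturalParameters,
    ctx: ModelContext,
    tol: float = 1e-8,
    max_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium via reduced Newton with coupling continuation.

    Conductances are eliminated analytically (g* = S sigma(V)), and the
    remaining depolarisation equations are solved by damped Newton while
    the synaptic coupling is ramped from zero (where V = v_leak exactly),
    which deterministically selects the branch continuous with the
    leak-only equilibrium.  Returns (x0, converged).
    """
    B, n = params.n_batch, ctx.n_pop_total
    cst = ctx.constants
    S = ctx.coupling(params)
    V = np.full((B, n), cst.v_leak)
    converged = np.ones(B, dtype=bool)
    # current-space tolerance implying a flow residual below tol
    c_min = float(np.min(params.capacitance)) if params.capacitance.size else 1.0
    tol_current = 0.5 * max(tol, 1e-12) * max(c_min, 1e-6)
    for scale in (0.25, 0.5, 0.75, 1.0):
        F, _ = _equilibrium_current(V, S, cst, scale)
        norm = np.max(np.abs(F), axis=1)
        for _ in range(max_iter):
            active = converged & (norm > tol_current)
            if not active.any():
                break
            Sa = tuple(s[active] for s in S)
            J = _equilibrium_current_jac(V[active], Sa, cst, scale)
            try:
                step = np.linalg.solve(J, -F[active][..., None])[..., 0]
            except np.linalg.LinAlgError:
                J = J + 1e-9 * np.eye(n)
                step = np.linalg.solve(J, -F[active][..., None])[..., 0]
            step = np.clip(step, -20.0, 20.0)
            v_act = V[active]
            best_v = v_act.copy()
            best_n = norm[active].copy()
            improved = np.zeros(v_act.shape[0], dtype=bool)
            s_bt = np.ones(v_act.shape[0])
            for _ in range(12):
                trial = v_act + s_bt[:, None] * step
                Ft, _ = _equilibrium_current(trial, Sa, cst, scale)
                nt = np.max(np.abs(Ft), axis=1)
                better = np.isfinite(nt) & (nt < best_n)
                best_v[better] = trial[better]
                best_n[better] = nt[better]
                improved |= better
                if improved.all():
                    break
                s_bt = np.where(improved, s_bt, s_bt / 2)
            V[active] = best_v
            norm_act = norm.copy()
            norm_act[active] = best_n
            norm = norm_act
            F, _ = _equilibrium_current(V, S, cst, scale)
            norm = np.max(np.abs(F), axis=1)
        converged &= norm <= max(tol_current, 1e-10)
    # assemble the full state and verify against the complete flow
    _, (gA, gG, gN) = _equilibrium_current(V, S, cst, 1.0)
    x = np.zeros((B, ctx.n_states))
    x[:, ctx.iV] = V
    x[:, ctx.iA] = gA
    x[:, ctx.iG] = gG
    x[:, ctx.iN] = gN
    f = _derivatives_batch(x, np.zeros((B, ctx.net.n_regions)), params, ctx)
    resid = np.max(np.abs(f), axis=1)
    return x, converged & (resid <= max(tol, 1e-7))


def params_subset(params: NaturalParameters, mask: np.ndarray) -> NaturalParameters:
    """Batch-subset view of a parameter set (boolean or index mask)."""
    if mask.dtype == bool and mask.all():
        return params
    return NaturalParameters(
        *(getattr(params, name)[mask] for name in params.__dataclass_fields__)
    )


def _delay_correct_batch(
    J: np.ndarray, params: NaturalParameters, ctx: ModelContext
) -> np.ndarray:
    """First-order delay operator: Jd = (I + D o J)^-1 J, D in seconds."""
    d_int = params.delays_ms[:, 0] / 1000.0
    d_ext = params.delays_ms[:, 1] / 1000.0
    D = (
        d_int[:, None, None] * ctx.delay_mask_intrinsic
        + d_ext[:, None, None] * ctx.delay_mask_extrinsic
    )
    ns = J.shape[-1]
    M = np.eye(ns) + D * J
    try:
        return np.linalg.solve(M, J)
    except np.linalg.LinAlgError as exc:
        conds = [float(np.linalg.cond(m)) for m in M]
        raise StabilityError(
            f"singular delay correction operator (cond={max(conds):.3e})"
        ) from exc


# --------------------------------------------------------------------------
# public single-model operations
# --------------------------------------------------------------------------

def state_derivatives(
    x: np.ndarray,
    u: np.ndarray,
    params: NaturalParameters,
    net: NetworkSpec,
    constants: ModelConstants | None = None,
) -> np.ndarray:
    """Time derivative of the state vector (single model)."""
    ctx = ModelContext(net, constants=constants)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite state vector")
    if x.shape != (ctx.n_states,):
        raise ValueError(f"state vector must have length {ctx.n_states}")
    u = np.zeros(net.n_regions) if u is None else np.asarray(u, dtype=float)
    if u.shape != (net.n_regions,):
        raise ValueError(f"input must have length {net.n_regions}")
    return _derivatives_batch(x[None], u[None], params, ctx)[0]


def find_fixed_point(
    params: NaturalParameters,
    net: NetworkSpec,
    constants: ModelConstants | None = None,
    tol: float = 1e-8,
) -> np.ndarray:
    """Equilibrium of the deterministic dynamics (zero input)."""
    ctx = ModelContext(net, constants=constants)
    x0, ok = _fixed_point_batch(params, ctx, tol=tol)
    if not ok.all():
        # fall back to long-horizon integration to steady state
        from scipy.integrate import solve_ivp

        def rhs(_, xv):
            return _derivatives_batch(
                xv[None], np.zeros((1, net.n_regions)), params, ctx
            )[0]

        sol = solve_ivp(rhs, (0.0, 10.0), x0[0], method="LSODA", rtol=1e-10, atol=1e-10)
        x_end = sol.y[:, -1]
        resid = np.max(np.abs(rhs(0.0, x_end)))
        if resid > max(tol, 1e-6):
            raise FixedPointError(
                f"fixed-point search failed (residual inf-norm {resid:.3e})"
            )
        return x_end
    return x0[0]


def system_jacobian(
    params: NaturalParameters,
    net: NetworkSpec,
    x0: np.ndarray,
    constants: ModelConstants | None = None,
    apply_delays: bool = True,
) -> np.ndarray:
    """System Jacobian at x0, with first-order delay correction."""
    ctx = ModelContext(net, constants=constants)
    J = _jacobian_batch(np.asarray(x0, dtype=float)[None], params, ctx)
    if apply_delays:
        J = _delay_correct_batch(J, params, ctx)
    return J[0]


def resolvent_transfer(
    jacobian: np.ndarray,
    readout: np.ndarray,
    input_matrix: np.ndarray,
    freqs: np.ndarray,
) -> np.ndarray:
    """Transfer function ``K(w) = W (i w I - J)^-1 B`` for given matrices.

    Direct per-frequency solve; used as an independent cross-check of the
    eigendecomposition-based fast path and for closed-form oracles.
    """
    jacobian = np.asarray(jacobian, dtype=complex)
    n = jacobian.shape[0]
    readout = np.atleast_2d(np.asarray(readout, dtype=complex))
    input_matrix = np.asarray(input_matrix, dtype=complex).reshape(n, -1)
    out = np.empty((len(freqs), readout.shape[0], input_matrix.shape[1]), dtype=complex)
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        A = 1j * 2 * np.pi * f * np.eye(n) - jacobian
        out[i] = readout @ np.linalg.solve(A, input_matrix)
    return out


@dataclass
class TransferFunction:
    """Complex gain from endogenous input channels to source outputs.

    The underlying kernel is real-valued, so ``K(-w) == conj(K(w))``
    holds identically; only non-negative frequencies are stored.
    """

    frequencies: np.ndarray  # (nf,)
    values: np.ndarray       # (nf, n_sources, n_inputs)


def _transfer_batch(
    params: NaturalParameters,
    ctx: ModelContext,
    Jd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer functions for a batch of delay-corrected Jacobians.

    Returns (K, stable): K has shape (B, nf, n_regions, n_regions) and
    stable is a boolean batch mask (True where all eigenvalues have
    negative real part).
    """
    lam, vec = np.linalg.eig(Jd)
    stable = np.max(lam.real, axis=1) < 0
    B, ns = Jd.shape[0], Jd.shape[1]
    nr = ctx.net.n_regions
    # read-out: gain * population weights on depolarisation states
    W = np.zeros((B, nr, ns))
    jw = np.zeros((B, 4))
    jw[:, POPULATIONS.index("ss")] = params.readout[:, 0]
    jw[:, POPULATIONS.index("sp")] = 0.8
    jw[:, POPULATIONS.index("dp")] = params.readout[:, 1]
    for r in range(nr):
        pops = np.arange(4 * r, 4 * r + 4)
        W[:, r, ctx.iV[pops]] = params.gain[:, r, None] * jw
    WV = W.astype(complex) @ vec
    VB = np.linalg.solve(vec, np.broadcast_to(
        ctx.input_matrix.astype(complex), (B, ns, nr)
    ).copy())
    omega = 2 * np.pi * ctx.freqs
    R = 1.0 / (1j * omega[None, :, None] - lam[:, None, :])  # (B, nf, ns)
    K = np.einsum("brs,bfs,bsq->bfrq", WV, R, VB)
    return K, stable


def _predict_batch(
    theta: np.ndarray,
    ctx: ModelContext,
    psd_clip: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted CSDs for a batch of log-scale parameter vectors.

    Returns (csd, valid): csd has shape (B, nf, nr, nr); invalid batch
    members (no fixed point or unstable Jacobian) contain NaNs.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    params = _scale_batch(theta, ctx.priors, ctx.net)
    x0, converged = _fixed_point_batch(params, ctx)
    J = _jacobian_batch(x0, params, ctx)
    Jd = _delay_correct_batch(J, params, ctx)
    K, stable = _transfer_batch(params, ctx, Jd)
    valid = converged & stable
    gu = input_spectrum(params.a, params.d, ctx.freqs)  # (B, nf)
    gx = gu[:, :, None, None] * np.einsum("bfrq,bfsq->bfrs", K, np.conj(K))
    go = noise_spectrum(params.b, params.c, params.f, ctx.freqs, ctx.net.n_regions)
    csd = gx + go
    if psd_clip:
        csd = hermitian_psd_project(csd, floor=0.0)
    csd[~valid] = np.nan
    return csd, valid


def transfer_function(
    params: NaturalParameters,
    net: NetworkSpec,
    freqs: np.ndarray,
    constants: ModelConstants | None = None,
) -> TransferFunction:
    """Frequency transfer function K(w) of the linearised model."""
    ctx = ModelContext(net, constants=constants, freqs=freqs)
    x0, ok = _fixed_point_batch(params, ctx)
    if not ok.all():
        raise FixedPointError("no equilibrium for transfer-function evaluation")
    J = _jacobian_batch(x0, params, ctx)
    Jd = _delay_correct_batch(J, params, ctx)
    lam = np.linalg.eigvals(Jd[0])
    offending = lam[lam.real >= 0]
    if offending.size:
        raise StabilityError(
            f"unstable Jacobian; eigenvalues with non-negative real part: {offending}"
        )
    K, _ = _transfer_batch(params, ctx, Jd)
    return TransferFunction(frequencies=ctx.freqs, values=K[0])


def predict_csd(
    theta_hat: np.ndarray,
    priors: PriorTable,
    net: NetworkSpec,
    constants: ModelConstants | None = None,
    freqs: np.ndarray | None = None,
    label: Mapping[str, str] | None = None,
) -> CrossSpectrum:
    """Predicted cross-spectral density ``K gu K* + go`` for one model."""
    ctx = ModelContext(net, priors, constants, freqs)
    csd, valid = _predict_batch(np.asarray(theta_hat, dtype=float)[None], ctx)
    if not valid[0]:
        params = _scale_batch(np.asarray(theta_hat)[None], priors, net)
        x0, ok = _fixed_point_batch(params, ctx)
        if not ok[0]:
            raise FixedPointError("no stable equilibrium at these parameters")
        J = _delay_correct_batch(_jacobian_batch(x0, params, ctx), params, ctx)
        lam = np.linalg.eigvals(J[0])
        raise StabilityError(
            "unstable Jacobian; offending eigenvalues: "
            f"{lam[lam.real >= 0]}"
        )
    values = hermitian_psd_project(csd[0], floor=0.0)
    label = dict(label or {})
    return CrossSpectrum(
        ctx.freqs,
        values,
        region_names=net.region_names,
        subject=label.get("subject", ""),
        session=label.get("session", ""),
        split=label.get("split", ""),
    )
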