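"""Bayesian model reduction over Gaussian densities.

Given a posterior obtained under a full prior, the posterior and the
change in log evidence under any alternative (reduced) prior follow in
closed form, without refitting:

    P_qr      = P_post + P_red - P_full
    mu_qr     = P_qr^-1 (P_post mu_post + P_red mu_red - P_full mu_full)
    delta F   = 1/2 log |S_qr| |S_full| / (|S_post| |S_red|)
                - 1/2 (mu'P mu + mu_r'P_r mu_r - mu_0'P_0 mu_0 - b'S_qr b)

with ``b = P_post mu_post + P_red mu_red - P_full mu_full``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .priors import ParameterDensity

__all__ = ["ReducedModelResult", "reduce_model", "bayes_factor", "SWITCHED_OFF_VARIANCE"]

#: Prior variance representing a parameter "switched off" (effectively
#: fixed at zero while keeping all covariances invertible).
SWITCHED_OFF_VARIANCE = 1e-8


@dataclass
class ReducedModelResult:
    """Posterior and relative log evidence under a reduced prior."""

    reduced_posterior: ParameterDensity
    delta_F: float

    @property
    def bayes_factor(self) -> float:
        return bayes_factor(self.delta_F)


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("matrix with non-positive determinant in reduction")
    return float(ld)


def reduce_model(
    posterior: ParameterDensity,
    prior: ParameterDensity,
    reduced_prior: ParameterDensity,
) -> ReducedModelResult:
    """Posterior and evidence change implied by swapping the prior.

    All three densities must share the same dimension (and index, when
    present).  ``delta_F`` is the log evidence of the reduced model minus
    that of the full model; positive values favour the reduction.
    """
    n = posterior.size
    if prior.size != n or reduced_prior.size != n:
        raise ValueError(
            f"dimension mismatch: posterior {n}, prior {prior.size}, "
            f"reduced {reduced_prior.size}"
        )
    P = np.linalg.inv(posterior.cov)
    P0 = np.linalg.inv(prior.cov)
    Pr = np.linalg.inv(reduced_prior.cov)
    Pqr = P + Pr - P0
    w = np.linalg.eigvalsh((Pqr + Pqr.T) / 2)
    if w.min() <= 0:
        raise ValueError(
            "reduced-posterior precision is not positive definite "
            f"(min eigenvalue {w.min():.3e}); the reduction is improper"
        )
    Sqr = np.linalg.inv(Pqr)
    Sqr = (Sqr + Sqr.T) / 2
    b = P @ posterior.mean + Pr @ reduced_prior.mean - P0 @ prior.mean
    mu_qr = Sqr @ b
    delta_F = 0.5 * (
        _logdet(Sqr)
        + _logdet(prior.cov)
        - _logdet(posterior.cov)
        - _logdet(reduced_prior.cov)
    ) - 0.5 * (
        posterior.mean @ P @ posterior.mean
        + reduced_prior.mean @ Pr @ reduced_prior.mean
        - prior.mean @ P0 @ prior.mean
        - b @ Sqr @ b
    )
    reduced = ParameterDensity(mu_qr, Sqr, posterior.index)
    return ReducedModelResult(reduced_posterior=reduced, delta_F=float(delta_F))


def switch_off(prior: ParameterDensity, positions: np.ndarray) -> ParameterDensity:
    """Reduced prior with the given coordinates pinned to zero."""
    positions = np.atleast_1d(np.asarray(positions, dtype=int))
    mean = prior.mean.copy()
    cov = prior.cov.copy()
    for i in positions:
        mean[i] = 0.0
        cov[i, :] = 0.0
        cov[:, i] = 0.0
        cov[i, i] = SWITCHED_OFF_VARIANCE
    return ParameterDensity(mean, cov, prior.index)


def bayes_factor(delta_F: float) -> float:
    """Bayes factor exp(delta_F); inf on overflow (use log10 to report)."""
    if not np.isfinite(delta_F):
        raise ValueError("delta_F must be finite")
    with np.errstate(over="ignore"):
        return float(np.exp(delta_F))


def log10_bayes_factor(delta_F: float) -> float:
    if not np.isfinite(delta_F):
        raise ValueError("delta_F must be finite")
    return float(delta_F / np.log(10.0))
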