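"""Reliability of fixed quantities (model evidences) and classical metrics.

Two measurement vectors per cohort (e.g. per-subject free energies from
two sessions) are modelled as repeated measurements whose pairwise
covariance has compound symmetry,

    Sigma_pair = sigma^2 [[1, rho], [rho, 1]],

with ``rho`` the interclass correlation.  Evidence for ``rho`` is
assessed by comparing the Laplace model evidence of the fit with the
correlation component against the same machinery with the component
removed; positive ``delta_F`` favours compound symmetry.

Also provides the modified Pearson correlation (pooled-mean centring)
and the one-way random-effects intraclass correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EvidencePair",
    "CovarianceModel",
    "ReliabilityComparison",
    "GLMFit",
    "modified_pearson",
    "icc_anova",
    "compound_symmetry_covariance",
    "fit_covariance_components",
    "compare_evidence_reliability",
]

#: log-evidence difference reported as "positive evidence"
POSITIVE_EVIDENCE_THRESHOLD = 3.0

# mild shrinkage priors on the standardised-scale hyperparameters
_PRIOR_VAR_MU = 4.0       # per-measurement intercepts
_PRIOR_VAR_LOGVAR = 4.0   # h1 = log sigma^2
_PRIOR_VAR_Z = 0.25        # h2 = atanh(rho)
_Z_BOUND = 5.0            # |atanh(rho)| cap (documents the degenerate case)


@dataclass
class EvidencePair:
    """Paired per-subject measurement vectors (e.g. free energies)."""

    k1: np.ndarray
    k2: np.ndarray
    labels: tuple[str, str] = ("measurement-1", "measurement-2")

    def __post_init__(self) -> None:
        self.k1 = np.asarray(self.k1, dtype=float).ravel()
        self.k2 = np.asarray(self.k2, dtype=float).ravel()
        if self.k1.size != self.k2.size:
            raise ValueError("k1 and k2 must have equal length")
        if not (np.isfinite(self.k1).all() and np.isfinite(self.k2).all()):
            raise ValueError("non-finite entries in evidence vectors")

    @property
    def n(self) -> int:
        return self.k1.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"subject": np.arange(self.n), "k1": self.k1, "k2": self.k2}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EvidencePair":
        df = pd.read_csv(path)
        return cls(df["k1"].to_numpy(), df["k2"].to_numpy())


@dataclass(frozen=True)
class CovarianceModel:
    sigma2: float
    rho: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        lo = -1.0 / (self.n - 1) if self.n > 1 else -1.0
        if not (lo < self.rho < 1.0):
            raise ValueError(
                f"rho={self.rho} outside the positive-definite range "
                f"({lo:.4f}, 1) for n={self.n}"
            )

    def matrix(self) -> np.ndarray:
        return compound_symmetry_covariance(self.sigma2, self.rho, self.n)


def compound_symmetry_covariance(sigma2: float, rho: float, n: int) -> np.ndarray:
    """n x n matrix with sigma^2 on the diagonal and rho sigma^2 off it."""
    CovarianceModel(sigma2, rho, n)  # validates
    return sigma2 * ((1.0 - rho) * np.eye(n) + rho * np.ones((n, n)))


def modified_pearson(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pooled-mean, pooled-variance correlation between paired vectors.

    Both vectors are centred by the common mean of all 2n values and
    normalised by the pooled variance.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size != x2.size or x1.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    n = x1.size
    c = np.sum(x1 + x2) / (2 * n)
    s2 = (np.sum((x1 - c) ** 2) + np.sum((x2 - c) ** 2)) / (2 * n)
    if s2 <= 0:
        raise ZeroDivisionError("pooled variance is zero; correlation undefined")
    return float(np.sum((x1 - c) * (x2 - c)) / (n * s2))


def icc_anova(y: np.ndarray) -> float:
    """One-way random-effects ICC sigma_a / (sigma_a + sigma_e).

    ``y`` is a (groups x replicates) table; variance components by the
    method of moments, with negative group-variance estimates clipped
    to zero.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 replicates per group")
    k, n = y.shape
    gm = y.mean()
    group_means = y.mean(axis=1)
    msb = n * np.sum((group_means - gm) ** 2) / (k - 1)
    msw = np.sum((y - group_means[:, None]) ** 2) / (k * (n - 1))
    if msw <= 0 and msb <= 0:
        raise ValueError("degenerate table: no variance")
    sigma_a = max((msb - msw) / n, 0.0)
    sigma_e = msw
    return float(sigma_a / (sigma_a + sigma_e))


# --------------------------------------------------------------------------
# covariance-component estimation
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    beta: float
    intercepts: tuple[float, float]
    sigma2: float
    rho: float
    free_energy: float
    converged: bool
    include_cs: bool


def _log_joint(params, k1, k2, include_cs):
    mu1, mu2, h1 = params[0], params[1], params[2]
    z = params[3] if include_cs else 0.0
    rho = np.tanh(z)
    s2 = np.exp(h1)
    n = k1.size
    d1 = k1 - mu1
    d2 = k2 - mu2
    det = s2**2 * (1 - rho**2)
    quad = (d1 @ d1 + d2 @ d2 - 2 * rho * (d1 @ d2)) / (s2 * (1 - rho**2))
    ll = -0.5 * n * np.log((2 * np.pi) ** 2 * det) - 0.5 * quad
    lp = (
        -0.5 * (mu1**2 + mu2**2) / _PRIOR_VAR_MU
        - 0.5 * np.log(2 * np.pi * _PRIOR_VAR_MU) * 2
        - 0.5 * h1**2 / _PRIOR_VAR_LOGVAR
        - 0.5 * np.log(2 * np.pi * _PRIOR_VAR_LOGVAR)
    )
    if include_cs:
        lp += -0.5 * z**2 / _PRIOR_VAR_Z - 0.5 * np.log(2 * np.pi * _PRIOR_VAR_Z)
    return ll + lp


def _numeric_hessian(fun, x, eps=1e-4):
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return H


def fit_covariance_components(pair: EvidencePair, include_cs: bool = True) -> GLMFit:
    """Laplace fit of the paired-measurement model.

    The two vectors are standardised jointly (shift and scale common to
    both models, so evidence differences are unaffected), the MAP of
    (intercepts, log variance[, atanh rho]) is located by quasi-Newton
    optimisation, and the evidence is approximated by the Laplace
    integral over the numeric Hessian.  With ``include_cs`` false the
    correlation component is removed and the same machinery reruns.
    """
    if pair.n < 3:
        raise ValueError("need at least 3 paired measurements")
    loc = 0.5 * (pair.k1.mean() + pair.k2.mean())
    scale = float(
        np.sqrt(0.5 * (np.var(pair.k1) + np.var(pair.k2)))
    )
    if scale <= 0:
        scale = max(abs(loc), 1.0)
    k1 = (pair.k1 - loc) / scale
    k2 = (pair.k2 - loc) / scale
    d = 4 if include_cs else 3
    x0 = np.zeros(d)

    def neg(x):
        return -_log_joint(x, k1, k2, include_cs)

    bounds = [(-20, 20), (-20, 20), (-20, 20)] + (
        [(-_Z_BOUND, _Z_BOUND)] if include_cs else []
    )
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    x = res.x
    H = _numeric_hessian(lambda v: _log_joint(v, k1, k2, include_cs), x)
    # Laplace: F = logjoint(MAP) + d/2 log 2pi - 1/2 log|-H|
    sign, ld = np.linalg.slogdet(-H)
    if sign <= 0:
        # flat direction (e.g. capped hyperparameter); regularise
        w, V = np.linalg.eigh(-(H + H.T) / 2)
        w = np.clip(w, 1e-6, None)
        ld = float(np.sum(np.log(w)))
    F = float(_log_joint(x, k1, k2, include_cs) + 0.5 * d * np.log(2 * np.pi) - 0.5 * ld)
    denom = float(pair.k2 @ pair.k2)
    beta = float(pair.k2 @ pair.k1 / denom) if denom > 0 else np.nan
    return GLMFit(
        beta=beta,
        intercepts=(float(x[0] * scale + loc), float(x[1] * scale + loc)),
        sigma2=float(np.exp(x[2]) * scale**2),
        rho=float(np.tanh(x[3])) if include_cs else 0.0,
        free_energy=F,
        converged=bool(res.success),
        include_cs=include_cs,
    )


@dataclass
class ReliabilityComparison:
    F_with_cs: float
    F_without_cs: float
    delta_F: float
    beta: float
    sigma2: float
    rho: float
    positive_evidence: bool = field(init=False)

    def __post_init__(self) -> None:
        assert np.isclose(self.delta_F, self.F_with_cs - self.F_without_cs)
        self.positive_evidence = self.delta_F > POSITIVE_EVIDENCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "F_with_cs": self.F_with_cs,
            "F_without_cs": self.F_without_cs,
            "delta_F": self.delta_F,
            "beta": self.beta,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "positive_evidence": bool(self.positive_evidence),
        }


def compare_evidence_reliability(pair: EvidencePair) -> ReliabilityComparison:
    """Evidence comparison with versus without the interclass correlation."""
    with_cs = fit_covariance_components(pair, include_cs=True)
    without = fit_covariance_components(pair, include_cs=False)
    return ReliabilityComparison(
        F_with_cs=with_cs.free_energy,
        F_without_cs=without.free_energy,
        delta_F=with_cs.free_energy - without.free_energy,
        beta=with_cs.beta,
        sigma2=with_cs.sigma2,
        rho=with_cs.rho,
    )
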