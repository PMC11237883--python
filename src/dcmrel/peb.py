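"""Parametric empirical Bayes over first-level Gaussian posteriors.

Second level: theta_1 = (X kron I) theta_2 + eps_2, with random-effect
precision ``Pi_2 = I_n kron (Q0 + exp(-gamma) Q1)``; Q0 is a small
positive floor and Q1 defaults to a multiple of the prior precision of
the group mean.  Subject-level evidence contributions are obtained by
Bayesian model reduction of each first-level posterior under the
empirical prior implied by theta_2, which makes the second-level
problem exactly Gaussian given gamma; gamma itself is optimised by a
guarded Newton search on the second-level free energy with a Gaussian
prior.

A third level ("PEB of PEBs") applies the same machinery to the
group-mean posteriors of two cohorts under a ones-plus-indicator
design, and parameters showing evidence of a difference are flagged by
switching off individual indicator effects via BMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bmr import SWITCHED_OFF_VARIANCE, reduce_model
from .priors import ParameterDensity, ParameterIndex

__all__ = [
    "DesignMatrix",
    "PEBConfig",
    "PEBResult",
    "build_design",
    "second_level_precision",
    "fit_peb",
    "peb_per_family",
    "peb_of_pebs",
    "flag_differences",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Between-subject design; the first column is the group mean."""

    X: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be constant 1")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if len(self.labels) != X.shape[1]:
            raise ValueError("one label per design column required")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def r(self) -> int:
        return self.X.shape[1]


def build_design(
    n: int,
    covariates: np.ndarray | Sequence | None = None,
    labels: Sequence[str] | None = None,
) -> DesignMatrix:
    """Ones column plus optional covariate columns."""
    cols = [np.ones(n)]
    names = ["mean"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError(
                f"covariate columns must have length {n}; got {cov.shape}"
            )
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(
                labels[j] if labels is not None and j < len(labels) else f"cov{j + 1}"
            )
    return DesignMatrix(np.column_stack(cols), tuple(names))


@dataclass(frozen=True)
class PEBConfig:
    """Random-effect precision and gamma-search settings."""

    precision_floor: float = 1e-6           # Q0 = floor * I
    precision_scale: float = 16.0           # Q1 = scale * prior precision
    q1: np.ndarray | None = None            # explicit Q1 overrides the default
    gamma_prior_mean: float = 2.0
    gamma_prior_var: float = 0.25
    gamma_grid_half_width: float = 4.0
    gamma_grid_points: int = 17
    newton_iterations: int = 12
    joint: bool = False                     # per-family default; joint behind a flag

    def __post_init__(self) -> None:
        if self.precision_floor <= 0:
            raise ValueError("precision_floor (Q0) must be > 0")
        if self.q1 is not None:
            q1 = np.asarray(self.q1, dtype=float)
            w = np.linalg.eigvalsh((q1 + q1.T) / 2)
            if w.min() < -1e-12:
                raise ValueError("Q1 must be positive semidefinite")
            object.__setattr__(self, "q1", q1)


def _q1_matrix(config: PEBConfig, prior: ParameterDensity) -> np.ndarray:
    if config.q1 is not None:
        if config.q1.shape != (prior.size, prior.size):
            raise ValueError("explicit Q1 has the wrong dimension")
        return config.q1
    return config.precision_scale * prior.precision()


def second_level_precision(
    gamma: float, config: PEBConfig, p: int, n: int
) -> np.ndarray:
    """Random-effects precision ``I_n kron (Q0 + exp(-gamma) Q1)``."""
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    q1 = config.q1 if config.q1 is not None else np.eye(p)
    if q1.shape != (p, p):
        raise ValueError(f"Q1 must be {p} x {p}")
    block = config.precision_floor * np.eye(p) + np.exp(-gamma) * q1
    return np.kron(np.eye(n), block)


@dataclass
class PEBResult:
    """Posterior over group effects with free energy and re-estimates."""

    posterior: ParameterDensity          # over theta_2, dimension r * p
    prior: ParameterDensity              # prior over theta_2
    gamma: float
    gamma_sd: float
    free_energy: float
    trajectory: np.ndarray
    design: DesignMatrix
    parameter_names: tuple[str, ...]
    reestimated: list[ParameterDensity] = field(default_factory=list)
    converged: bool = True

    @property
    def p(self) -> int:
        return len(self.parameter_names)

    def effect(self, column: int) -> ParameterDensity:
        """Marginal posterior over one design column's effects."""
        p = self.p
        idx = np.arange(column * p, (column + 1) * p)
        return self.posterior.marginal(idx)

    def to_dict(self) -> dict:
        return {
            "free_energy": float(self.free_energy),
            "gamma": float(self.gamma),
            "design_labels": list(self.design.labels),
            "parameters": list(self.parameter_names),
            "posterior_mean": self.posterior.mean.tolist(),
        }


class _PEBCore:
    """Gaussian second-level model conditional on gamma."""

    def __init__(
        self,
        posteriors: Sequence[ParameterDensity],
        prior: ParameterDensity,
        design: DesignMatrix,
        config: PEBConfig,
    ):
        if design.n != len(posteriors):
            raise ValueError("one design row per first-level posterior required")
        p = prior.size
        for q in posteriors:
            if q.size != p:
                raise ValueError("first-level posteriors do not share the index")
            if q.index is not None and prior.index is not None and q.index != prior.index:
                raise ValueError("parameter indices do not match across subjects")
        self.posteriors = list(posteriors)
        self.prior = prior
        self.design = design
        self.config = config
        self.p = p
        self.P0 = prior.precision()
        self.Q0 = config.precision_floor * np.eye(p)
        self.Q1 = _q1_matrix(config, prior)
        self.Pi = [q.precision() for q in self.posteriors]
        self.r_i = [
            Pi @ q.mean - self.P0 @ self.prior.mean
            for Pi, q in zip(self.Pi, self.posteriors)
        ]
        self.logdet_S0 = _slogdet(prior.cov)
        self.logdet_Si = [_slogdet(q.cov) for q in self.posteriors]
        self.quad_i = [
            float(q.mean @ Pi @ q.mean) for Pi, q in zip(self.Pi, self.posteriors)
        ]
        self.quad_0 = float(prior.mean @ self.P0 @ prior.mean)
        # prior over theta_2: group-mean column inherits the first-level
        # prior; covariate columns are zero-mean with the same covariance
        r = design.r
        self.eta0 = np.concatenate([prior.mean] + [np.zeros(p)] * (r - 1))
        self.S_eta = np.kron(np.eye(r), prior.cov)
        self.P_eta = np.kron(np.eye(r), self.P0)

    def p2_block(self, gamma: float) -> np.ndarray:
        return self.Q0 + np.exp(-gamma) * self.Q1

    def conditional(self, gamma: float):
        """Posterior over theta_2 and free energy terms for fixed gamma."""
        P2 = self.p2_block(gamma)
        logdet_P2 = _slogdet(P2)
        G = np.zeros((self.design.r * self.p,) * 2)
        h = np.zeros(self.design.r * self.p)
        const = 0.0
        for i, (Pi, ri) in enumerate(zip(self.Pi, self.r_i)):
            Pqr = Pi + P2 - self.P0
            Pqr = _ensure_pd(Pqr)
            Sqr = np.linalg.inv(Pqr)
            x = self.design.X[i]
            A = P2 - P2 @ Sqr @ P2
            G += np.kron(np.outer(x, x), A)
            h += np.kron(x, P2 @ Sqr @ ri)
            const += 0.5 * (
                -_slogdet(Pqr) + self.logdet_S0 - self.logdet_Si[i] + logdet_P2
            )
            const -= 0.5 * (
                self.quad_i[i] - self.quad_0 - float(ri @ Sqr @ ri)
            )
        P_post = self.P_eta + G
        S_post = np.linalg.inv(P_post)
        mu_post = S_post @ (self.P_eta @ self.eta0 + h)
        F = (
            const
            - 0.5 * float(self.eta0 @ self.P_eta @ self.eta0)
            + 0.5 * float(mu_post @ P_post @ mu_post)
            + 0.5 * (_slogdet(S_post) - _slogdet(self.S_eta))
        )
        cfg = self.config
        F += (
            -0.5 * (gamma - cfg.gamma_prior_mean) ** 2 / cfg.gamma_prior_var
            - 0.5 * np.log(2 * np.pi * cfg.gamma_prior_var)
        )
        return F, mu_post, (S_post + S_post.T) / 2

    def objective(self, gamma: float) -> float:
        return self.conditional(gamma)[0]

    def fit(self):
        cfg = self.config
        gamma = cfg.gamma_prior_mean
        F = self.objective(gamma)
        trajectory = [F]
        grid = np.linspace(
            cfg.gamma_prior_mean - cfg.gamma_grid_half_width,
            cfg.gamma_prior_mean + cfg.gamma_grid_half_width,
            cfg.gamma_grid_points,
        )
        for g in grid:
            Fg = self.objective(g)
            if Fg > F:
                gamma, F = g, Fg
                trajectory.append(F)
        eps = 1e-3
        converged = False
        for _ in range(cfg.newton_iterations):
            Fp = self.objective(gamma + eps)
            Fm = self.objective(gamma - eps)
            g1 = (Fp - Fm) / (2 * eps)
            g2 = (Fp - 2 * F + Fm) / eps**2
            step = -g1 / g2 if g2 < -1e-12 else np.sign(g1) * 0.5
            step = float(np.clip(step, -1.0, 1.0))
            accepted = False
            for _ in range(6):
                cand = gamma + step
                Fc = self.objective(cand)
                if Fc > F:
                    gamma, F = cand, Fc
                    trajectory.append(F)
                    accepted = True
                    break
                step /= 2
            if not accepted or abs(step) < 1e-4:
                converged = True
                break
        Fp = self.objective(gamma + eps)
        Fm = self.objective(gamma - eps)
        curv = (Fp - 2 * F + Fm) / eps**2
        gamma_var = -1.0 / curv if curv < -1e-12 else cfg.gamma_prior_var
        F_total = F + 0.5 * np.log(2 * np.pi * gamma_var)
        _, mu_post, S_post = self.conditional(gamma)
        return gamma, float(np.sqrt(gamma_var)), F_total, np.asarray(trajectory), mu_post, S_post, converged

    def empirical_priors(
        self, gamma: float, mu_post: np.ndarray, S_post: np.ndarray
    ) -> list[ParameterDensity]:
        """Per-subject empirical priors implied by the group posterior."""
        P2 = self.p2_block(gamma)
        S2 = np.linalg.inv(P2)
        out = []
        for i in range(self.design.n):
            x = self.design.X[i]
            M = np.kron(x, np.eye(self.p)).reshape(self.p, -1)
            mean = M @ mu_post
            cov = S2 + M @ S_post @ M.T
            out.append(ParameterDensity(mean, (cov + cov.T) / 2, self.prior.index))
        return out


def _ensure_pd(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    M = (M + M.T) / 2
    w, V = np.linalg.eigh(M)
    if w.min() > floor:
        return M
    w = np.clip(w, floor, None)
    return V @ np.diag(w) @ V.T


def _slogdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("non positive-definite matrix in PEB")
    return float(ld)


def _as_density(obj) -> ParameterDensity:
    if isinstance(obj, ParameterDensity):
        return obj
    post = getattr(obj, "posterior", None)
    if isinstance(post, ParameterDensity):
        return post
    raise TypeError(f"cannot interpret {type(obj)!r} as a first-level posterior")


def _theta2_names(param_names: Sequence[str], design: DesignMatrix) -> tuple[str, ...]:
    return tuple(
        f"{lab}:{name}" for lab in design.labels for name in param_names
    )


def fit_peb(
    first_level: Sequence,
    prior: ParameterDensity,
    design: DesignMatrix | None = None,
    config: PEBConfig | None = None,
    reestimate: bool = True,
) -> PEBResult:
    """Hierarchical model over first-level posteriors.

    ``first_level`` may contain :class:`ParameterDensity` objects or
    inversion results exposing a ``posterior`` attribute.  Returns the
    Gaussian posterior over group effects, the optimised random-effects
    hyperparameter and (optionally) the BMR re-estimates of every
    first-level posterior under the empirical priors.
    """
    posteriors = [_as_density(x) for x in first_level]
    design = design or build_design(len(posteriors))
    config = config or PEBConfig()
    core = _PEBCore(posteriors, prior, design, config)
    gamma, gamma_sd, F, traj, mu_post, S_post, converged = core.fit()
    names = tuple(
        prior.index.names if prior.index is not None else
        [f"p{i}" for i in range(prior.size)]
    )
    theta2_index = ParameterIndex(
        _theta2_names(names, design),
        tuple(
            prior.index.families[i % prior.size] if prior.index is not None else "J"
            for i in range(design.r * prior.size)
        ),
    )
    posterior2 = ParameterDensity(mu_post, S_post, theta2_index)
    prior2 = ParameterDensity(core.eta0, core.S_eta, theta2_index)
    reest: list[ParameterDensity] = []
    if reestimate:
        for q, emp in zip(
            posteriors, core.empirical_priors(gamma, mu_post, S_post)
        ):
            reest.append(reduce_model(q, prior, emp).reduced_posterior)
    return PEBResult(
        posterior=posterior2,
        prior=prior2,
        gamma=float(gamma),
        gamma_sd=float(gamma_sd),
        free_energy=float(F),
        trajectory=traj,
        design=design,
        parameter_names=names,
        reestimated=reest,
        converged=converged,
    )


def peb_per_family(
    first_level: Sequence,
    prior: ParameterDensity,
    design: DesignMatrix | None = None,
    config: PEBConfig | None = None,
    families: Sequence[str] | None = None,
    reestimate: bool = True,
) -> dict[str, PEBResult]:
    """Independent PEB per parameter family (the pipeline default)."""
    posteriors = [_as_density(x) for x in first_level]
    if prior.index is None:
        raise ValueError("per-family PEB requires an indexed prior")
    families = tuple(families or prior.index.present_families())
    out: dict[str, PEBResult] = {}
    for fam in families:
        idx = prior.index.family_indices(fam)
        if idx.size == 0:
            continue
        sub_prior = prior.marginal(idx)
        sub_post = [q.marginal(idx) for q in posteriors]
        out[fam] = fit_peb(sub_post, sub_prior, design, config, reestimate)
    return out


def peb_of_pebs(
    group_results: Sequence[PEBResult],
    prior: ParameterDensity,
    config: PEBConfig | None = None,
) -> PEBResult:
    """Third-level PEB contrasting cohort-level group means.

    The group-mean posteriors of each cohort enter a ones-plus-indicator
    design; column 2 of the result captures between-cohort differences.
    """
    if len(group_results) != 2:
        raise ValueError("exactly two cohort PEB results are required")
    names0 = group_results[0].parameter_names
    if any(g.parameter_names != names0 for g in group_results):
        raise ValueError("cohort PEBs do not share a parameter index")
    means = []
    for g in group_results:
        eff = g.effect(0)
        means.append(ParameterDensity(eff.mean, eff.cov, prior.index))
    design = build_design(2, covariates=[0.0, 1.0], labels=["difference"])
    return fit_peb(means, prior, design, config, reestimate=False)


def flag_differences(
    peb: PEBResult,
    threshold: float = 0.95,
    column: int = 1,
) -> pd.DataFrame:
    """Parameters with evidence of a non-zero effect in the given column.

    For each parameter the corresponding effect coordinate is switched
    off by BMR; the posterior probability of the model retaining the
    effect is ``1 / (1 + exp(delta_F))``.  Returns every parameter with
    its expectation, central 95% interval, posterior probability and
    flag; filter on ``flagged`` for the reduced table.
    """
    if peb.design.r <= column:
        raise ValueError("the PEB design has no difference/indicator column")
    p = peb.p
    rows = []
    fams = (
        peb.posterior.index.families
        if peb.posterior.index is not None
        else ["?"] * (peb.design.r * p)
    )
    for j in range(p):
        coord = column * p + j
        red_mean = peb.prior.mean.copy()
        red_cov = peb.prior.cov.copy()
        red_mean[coord] = 0.0
        red_cov[coord, :] = 0.0
        red_cov[:, coord] = 0.0
        red_cov[coord, coord] = SWITCHED_OFF_VARIANCE
        reduced = ParameterDensity(red_mean, red_cov, peb.prior.index)
        dF = reduce_model(peb.posterior, peb.prior, reduced).delta_F
        prob = 1.0 / (1.0 + np.exp(np.clip(dF, -700, 700)))
        mean = peb.posterior.mean[coord]
        sd = np.sqrt(peb.posterior.cov[coord, coord])
        rows.append(
            {
                "parameter": peb.parameter_names[j],
                "family": fams[coord],
                "expectation": float(mean),
                "ci_lower": float(mean - 1.959963984540054 * sd),
                "ci_upper": float(mean + 1.959963984540054 * sd),
                "posterior_prob": float(prob),
                "flagged": bool(prob > threshold),
            }
        )
    return pd.DataFrame(rows)
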