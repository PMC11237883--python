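"""Synthetic cohorts with the statistical structure the analyses assume.

Generators are pure functions of (specification, seed): subject-level
parameter vectors are drawn around the group (prior) mean, an optional
session effect is injected into the second session, and observation
noise perturbs the predicted spectra per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import ModelConstants
from .csd import CrossSpectrum, hermitian_psd_project
from .forward import ModelContext, _fixed_point_batch, _jacobian_batch, _predict_batch, _scale_batch, _delay_correct_batch
from .network import NetworkSpec, default_network
from .priors import ParameterDensity, PriorTable
from .reliability import EvidencePair

__all__ = [
    "CohortSpec",
    "Cohort",
    "subject_sd_profile",
    "sample_cohort",
    "stabilise_cohort",
    "simulate_observed_csd",
    "split_epoch_features",
    "generate_evidence_pairs",
]


def subject_sd_profile(scale: float = 0.5) -> dict[str, float]:
    """Between-subject variability per family, in prior-sd units.

    The sensor gain L carries a very diffuse prior (variance 64 on the
    log scale); scaling its between-subject spread by the same factor as
    the physiological families would imply implausible orders-of-
    magnitude gain differences, so L is damped to a fixed 0.5 log-unit
    spread.
    """
    from .priors import FAMILIES

    profile = {fam: scale for fam in FAMILIES}
    profile["L"] = 0.5 / 8.0  # 0.5 log units regardless of scale
    return profile


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort (seed is mandatory)."""

    n_subjects: int
    seed: int
    n_regions: int = 2
    n_sessions: int = 2
    between_subject_sd: float | Mapping[str, float] = 1.0  # prior-sd units
    session_effect: Mapping[str, float] = field(default_factory=dict)
    observation_noise_sd: float = 0.1
    n_epochs: int = 1
    freq_min: float = 4.0
    freq_max: float = 48.0
    freq_step: float = 4.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be >= 0")
        sds = (
            self.between_subject_sd.values()
            if isinstance(self.between_subject_sd, Mapping)
            else [self.between_subject_sd]
        )
        if any(s < 0 for s in sds):
            raise ValueError("between_subject_sd must be >= 0")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.freq_min, self.freq_max + 1e-9, self.freq_step)

    def network(self) -> NetworkSpec:
        return default_network(self.n_regions)


@dataclass
class Cohort:
    """True log-scale deviations per (subject, session)."""

    theta: np.ndarray  # (n_subjects, n_sessions, d)
    spec: CohortSpec
    index: object

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[0]


def _family_sd_units(spec: CohortSpec, families) -> np.ndarray:
    if isinstance(spec.between_subject_sd, Mapping):
        return np.array([spec.between_subject_sd.get(f, 0.0) for f in families])
    return np.full(len(families), float(spec.between_subject_sd))


def sample_cohort(spec: CohortSpec, priors: PriorTable | None = None) -> Cohort:
    """Draw per-subject, per-session true parameter vectors.

    theta(subject, session) = subject deviation (+ session effect on the
    second and later sessions); deviations and effects are expressed in
    units of the prior standard deviation per family.
    """
    priors = priors or PriorTable()
    net = spec.network()
    index = priors.build_index(net)
    prior_sd = np.array([priors.variances[f] for f in index.families]) ** 0.5
    unit = _family_sd_units(spec, index.families)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_subjects, index.size))
    subject_dev = z * unit * prior_sd
    effect = np.zeros(index.size)
    for name, size in spec.session_effect.items():
        effect[index.position(name)] = size
    effect = effect * prior_sd
    theta = np.repeat(subject_dev[:, None, :], spec.n_sessions, axis=1)
    theta[:, 1:, :] += effect
    return Cohort(theta=theta, spec=spec, index=index)


def stabilise_cohort(
    cohort: Cohort,
    priors: PriorTable | None = None,
    constants: ModelConstants | None = None,
    shrink: float = 0.8,
    max_rounds: int = 12,
) -> Cohort:
    """Deterministically shrink unstable draws towards the prior mean.

    Subject deviations whose forward model has no stable equilibrium are
    scaled by ``shrink`` until stability holds; purely a function of the
    input cohort (no randomness).
    """
    priors = priors or PriorTable()
    net = cohort.spec.network()
    ctx = ModelContext(net, priors, constants, cohort.spec.frequencies)
    theta = cohort.theta.copy()
    flat = theta.reshape(-1, theta.shape[-1])
    for _ in range(max_rounds):
        _, valid = _predict_batch(flat, ctx)
        if valid.all():
            break
        flat[~valid] *= shrink
    else:
        raise RuntimeError("cohort could not be stabilised")
    return Cohort(theta=flat.reshape(theta.shape), spec=cohort.spec, index=cohort.index)


def simulate_observed_csd(
    theta_hat: np.ndarray,
    spec: CohortSpec,
    net: NetworkSpec | None = None,
    constants: ModelConstants | None = None,
    priors: PriorTable | None = None,
    rng: np.random.Generator | None = None,
    label: dict | None = None,
) -> list[CrossSpectrum]:
    """Noisy epoch-level observations of the predicted cross-spectrum.

    Adds a Hermitian complex-Gaussian perturbation (scaled per frequency
    by ``observation_noise_sd`` times the mean diagonal power) and
    projects back onto the PSD cone.  With zero noise the prediction is
    returned unchanged for every epoch.
    """
    net = net or spec.network()
    priors = priors or PriorTable()
    ctx = ModelContext(net, priors, constants, spec.frequencies)
    values, valid = _predict_batch(np.asarray(theta_hat, dtype=float)[None], ctx)
    if not valid[0]:
        from .forward import FixedPointError

        raise FixedPointError("unstable parameters in simulate_observed_csd")
    base = values[0]
    rng = rng or np.random.default_rng(spec.seed)
    label = label or {}
    nf, ns = base.shape[0], base.shape[1]
    scale = spec.observation_noise_sd * np.mean(
        np.abs(np.diagonal(base, axis1=1, axis2=2)), axis=1
    )
    epochs = []
    for ep in range(spec.n_epochs):
        if spec.observation_noise_sd == 0:
            noisy = base
        else:
            g = rng.standard_normal((nf, ns, ns)) + 1j * rng.standard_normal(
                (nf, ns, ns)
            )
            herm = (g + np.conj(np.swapaxes(g, 1, 2))) / 2
            noisy = hermitian_psd_project(base + scale[:, None, None] * herm)
        epochs.append(
            CrossSpectrum(
                spec.frequencies,
                noisy,
                region_names=net.region_names,
                subject=str(label.get("subject", "")),
                session=str(label.get("session", "")),
                split=f"epoch{ep:03d}",
            )
        )
    return epochs


def split_epoch_features(
    epochs: list[CrossSpectrum],
) -> tuple[CrossSpectrum, CrossSpectrum]:
    """Average odd-numbered and even-numbered epochs separately.

    Epochs are numbered from 1, so 'odd' collects the 1st, 3rd, ...
    entries; the partition is disjoint and covers every epoch.
    """
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs to split")
    freqs = epochs[0].frequencies
    for e in epochs[1:]:
        if not np.array_equal(e.frequencies, freqs):
            raise ValueError("epochs have mismatched frequency grids")
    odd = [e.values for e in epochs[0::2]]
    even = [e.values for e in epochs[1::2]]
    ref = epochs[0]

    def avg(vals, name):
        return CrossSpectrum(
            freqs,
            np.mean(vals, axis=0),
            region_names=ref.region_names,
            subject=ref.subject,
            session=ref.session,
            split=name,
        )

    return avg(odd, "odd"), avg(even, "even")


def generate_evidence_pairs(
    n: int,
    rho: float,
    sigma2: float = 1.0,
    beta: float = 1.0,
    seed: int = 0,
    loc: float = 0.0,
) -> EvidencePair:
    """Paired vectors with compound-symmetry pair covariance.

    Each subject's pair is drawn from a bivariate Gaussian with common
    variance ``sigma2`` and correlation ``rho``; the first measurement
    is scaled by ``beta``.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"rho={rho} outside the positive-definite range")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    cov = sigma2 * np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2)) @ chol.T
    k2 = loc + z[:, 1]
    k1 = beta * (loc + z[:, 0])
    return EvidencePair(k1, k2)
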