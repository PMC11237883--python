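# dcmrel

Reliability analysis of spectral dynamic causal models (DCM) for
resting-state MEG, built around a conductance-based canonical
microcircuit (CMM-NMDA) forward model. The package provides the full
chain needed to ask "do two measurements support the same model and
parameters?":

- **`dcmrel.forward`** — four-population conductance model per region
  (spiny stellate, superficial/deep pyramidal, inhibitory), NMDA
  magnesium gating, fixed-point search, delay-corrected Jacobians and
  the frequency transfer function mapping endogenous fluctuations to
  predicted source-space cross-spectral densities.
- **`dcmrel.spectra`** — parametric power-law/cosine forms for the
  endogenous input spectrum and common + source-specific observation
  noise.
- **`dcmrel.inversion`** — variational-Laplace (Gauss–Newton with
  Levenberg–Marquardt damping) fitting of the model to an observed
  cross-spectrum, returning a Gaussian posterior and a free-energy
  bound on log evidence.
- **`dcmrel.bmr`** — closed-form Bayesian model reduction: posteriors
  and evidence changes under alternative priors without refitting.
- **`dcmrel.peb`** — parametric empirical Bayes over first-level
  posteriors, per-family by default, with a third-level "PEB of PEBs"
  contrasting cohorts/sessions and BMR-based flagging of parameters
  with evidence of a difference.
- **`dcmrel.reliability`** — evidence reliability of paired per-subject
  free energies via compound-symmetry covariance components (Laplace
  model comparison with vs without the interclass correlation), plus
  classical metrics (pooled-mean modified Pearson, one-way ICC).
- **`dcmrel.synth`** — seeded synthetic cohorts: subject-level
  parameters around group means, optional session effects, spectral
  observation noise, epoch splits and correlated evidence pairs.
- **`dcmrel.pipeline`** — orchestration of the split-sample,
  between-session and between-subject reliability analyses, producing a
  JSON report with flag tables, unflagged fractions and correlation
  counts before/after empirical-Bayes re-estimation.

## Command line

```bash
# simulate a cohort of cross-spectra (HDF5) from a YAML cohort spec
dcmrel simulate --spec cohort.yaml --out data/

# invert one spectrum
dcmrel invert --data data/s00_ses1.h5 --group /epoch000 --regions 2 --out fit.json

# prune parameters post hoc via Bayesian model reduction
dcmrel reduce --posterior fit.json --switch-off "kappa[R1.ampa]" --out reduced.json

# full reliability study (see tests for config examples)
dcmrel reliability --config study.yaml --out report/
```

A cohort YAML contains the `CohortSpec` fields, e.g.

```yaml
n_subjects: 8
seed: 1
n_regions: 2
between_subject_sd: 0.5
observation_noise_sd: 0.1
```

and a study config wraps it: `{cohort: {...}, analyses: [between_session,
evidence_reliability]}`.

## Conventions

Parameters are log-scale deviations with Gaussian priors; natural values
are `theta0 * exp(theta_hat)` with the scaling constants and prior
variances tabulated in `dcmrel.priors.PriorTable`. State layout is
region-major, population-minor with `(V, gAMPA, gGABA, gNMDA)` per
population; potentials in mV, time in seconds, channel time constants
specified in ms. Cross-spectra are serialised to HDF5 as
`/frequencies`, `/csd_real`, `/csd_imag` with subject/session/split
attributes.
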