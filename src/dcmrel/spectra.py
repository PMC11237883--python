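"""Parametric spectra of endogenous fluctuations and observation noise.

The endogenous (neuronal) input spectrum is a power law with a cosine
modulation,

    gu(w) = exp(a1) * w**(-exp(a2)) * max(1 + sum_i d_i cos(i*pi*nu), eps)

where ``nu`` rescales frequency to [0, 1] over the analysis band.  The
observation-noise cross-spectrum is a sum of a common (rank-one, shared
across sources) and a source-specific (diagonal) power law, multiplied
by a smooth frequency-scaling ("filtering") term parameterised by ``f``.

All functions broadcast over arbitrary leading (batch) dimensions of the
parameter arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["input_spectrum", "noise_spectrum", "frequency_scaling"]

#: Floor applied to the cosine modulation of the input spectrum.
MODULATION_FLOOR = 1e-8

#: Base amplitudes of the common and source-specific observation noise
#: (multiples of the unit-amplitude power law); calibrated so that the
#: prior-mean predicted spectrum has roughly 10:1 signal-to-noise at its
#: in-band peak.
NOISE_COMMON_BASE = 6e-6
NOISE_SPECIFIC_BASE = 2.5e-5

#: Width (in rescaled frequency units) of the band-edge taper bumps
#: modulated by the two ``f`` parameters.
EDGE_WIDTH = 0.15


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("freqs must be a non-empty 1-d array")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    return freqs


def _rescaled(freqs: np.ndarray) -> np.ndarray:
    lo, hi = freqs.min(), freqs.max()
    if hi == lo:
        return np.zeros_like(freqs)
    return (freqs - lo) / (hi - lo)


def input_spectrum(a: np.ndarray, d: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Endogenous-input power gu(w), strictly positive.

    Parameters
    ----------
    a : array (..., 2)
        Log amplitude and log-exponent of the power law.
    d : array (..., 4)
        Cosine modulation coefficients (log-scale deviations, used
        additively).
    freqs : array (n_freq,)
        Frequencies in Hz, strictly positive.
    """
    freqs = _check_freqs(freqs)
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape[-1] != 2 or d.shape[-1] != 4:
        raise ValueError("a must have 2 and d 4 trailing elements")
    nu = _rescaled(freqs)
    amp = np.exp(a[..., :1])
    expo = np.exp(a[..., 1:2])
    power = amp * freqs ** (-expo)
    harmonics = np.arange(1, 5)
    basis = np.cos(np.pi * harmonics[:, None] * nu[None, :])  # (4, nf)
    modulation = 1.0 + np.einsum("...i,ij->...j", d, basis)
    return power * np.clip(modulation, MODULATION_FLOOR, None)


def frequency_scaling(f: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Smooth multiplicative scaling s(w) modelling data filtration.

    Two parameters scale log-amplitude bumps at the lower and upper band
    edges; f = 0 gives the identity scaling.
    """
    freqs = _check_freqs(freqs)
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != 2:
        raise ValueError("f must have 2 trailing elements")
    nu = _rescaled(freqs)
    low = np.exp(-(nu**2) / (2 * EDGE_WIDTH**2))
    high = np.exp(-((1 - nu) ** 2) / (2 * EDGE_WIDTH**2))
    return np.exp(f[..., :1] * low + f[..., 1:2] * high)


def noise_spectrum(
    b: np.ndarray,
    c: np.ndarray,
    f: np.ndarray,
    freqs: np.ndarray,
    n_sources: int,
) -> np.ndarray:
    """Observation-noise cross-spectrum go(w), Hermitian PSD per slice.

    Returns an array of shape ``(..., n_freq, n_sources, n_sources)``:
    a common (identical across all source pairs) plus a source-specific
    (diagonal) power-law term, scaled by :func:`frequency_scaling`.
    """
    freqs = _check_freqs(freqs)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if b.shape[-1] != 2 or c.shape[-1] != 2:
        raise ValueError("b and c must have 2 trailing elements")
    common = NOISE_COMMON_BASE * np.exp(b[..., :1]) * freqs ** (-np.exp(b[..., 1:2]))
    specific = NOISE_SPECIFIC_BASE * np.exp(c[..., :1]) * freqs ** (-np.exp(c[..., 1:2]))
    scale = frequency_scaling(f, freqs)
    common = common * scale
    specific = specific * scale
    ones = np.ones((n_sources, n_sources))
    eye = np.eye(n_sources)
    go = (
        common[..., None, None] * ones
        + specific[..., None, None] * eye
    )
    return go.astype(complex)
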