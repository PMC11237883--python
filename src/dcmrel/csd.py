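"""Cross-spectral density container and HDF5 serialisation."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["CrossSpectrum", "hermitian_psd_project"]


def hermitian_psd_project(values: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Project each frequency slice onto the Hermitian PSD cone."""
    values = np.asarray(values, dtype=complex)
    sym = (values + np.conj(np.swapaxes(values, -1, -2))) / 2
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, floor, None)
    return np.einsum("...ik,...k,...jk->...ij", v, w, np.conj(v))


@dataclass
class CrossSpectrum:
    """Complex cross-spectral density: (n_freq, n_sources, n_sources).

    Each frequency slice is Hermitian with a real, non-negative diagonal.
    """

    frequencies: np.ndarray
    values: np.ndarray
    region_names: tuple[str, ...] = ()
    subject: str = ""
    session: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(f"values must be (n_freq, n, n); got {self.values.shape}")
        if self.values.shape[0] != self.frequencies.size:
            raise ValueError("frequency axis mismatch")
        self.region_names = tuple(self.region_names)

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]

    @property
    def label(self) -> str:
        return "/".join(x for x in (self.subject, self.session, self.split) if x)

    def is_hermitian(self, atol: float = 1e-8) -> bool:
        # tolerance scales with the data magnitude (gains can make the
        # absolute scale arbitrarily large)
        tol = atol * max(1.0, float(np.abs(self.values).max()))
        herm = np.allclose(
            self.values, np.conj(np.swapaxes(self.values, 1, 2)), atol=tol
        )
        diag = np.diagonal(self.values, axis1=1, axis2=2)
        return bool(
            herm
            and np.allclose(diag.imag, 0, atol=tol)
            and np.all(diag.real >= -tol)
        )

    def projected(self, floor: float = 0.0) -> "CrossSpectrum":
        return CrossSpectrum(
            self.frequencies,
            hermitian_psd_project(self.values, floor),
            self.region_names,
            self.subject,
            self.session,
            self.split,
        )

    def save(self, path, group: str = "/") -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in ("frequencies", "csd_real", "csd_imag"):
                if name in g:
                    del g[name]
            g.create_dataset("frequencies", data=self.frequencies)
            g.create_dataset("csd_real", data=self.values.real)
            g.create_dataset("csd_imag", data=self.values.imag)
            g.attrs["subject"] = self.subject
            g.attrs["session"] = self.session
            g.attrs["split"] = self.split
            g.attrs["regions"] = ",".join(self.region_names)

    @classmethod
    def load(cls, path, group: str = "/") -> "CrossSpectrum":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            freqs = np.asarray(g["frequencies"])
            values = np.asarray(g["csd_real"]) + 1j * np.asarray(g["csd_imag"])
            regions = tuple(r for r in str(g.attrs.get("regions", "")).split(",") if r)
            return cls(
                freqs,
                values,
                regions,
                subject=str(g.attrs.get("subject", "")),
                session=str(g.attrs.get("session", "")),
                split=str(g.attrs.get("split", "")),
            )
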