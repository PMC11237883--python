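"""Prior scaling constants, parameter indexing and Gaussian densities.

Every unknown parameter is a log-scale deviation ``theta_hat`` with a
Gaussian prior ``N(0, v)``; the natural-scale value is
``theta0 * exp(theta_hat)`` where ``theta0`` is a fixed scaling constant.

Families
--------
``kappa``  channel time constants (AMPA, GABA, NMDA), per region, ms
``C``      membrane capacitance per population, per region
``H``      intrinsic (within-region) connection strengths
``A``      extrinsic AMPA connection strength, per directed edge
``AN``     extrinsic NMDA connection strength, per directed edge
``L``      sensor gain, per region
``J``      contribution of ss and dp populations to the observed signal
``a``      endogenous fluctuation spectrum (amplitude, exponent)
``d``      cosine modulation coefficients of the fluctuation spectrum
``b``      common observation-noise spectrum (amplitude, exponent)
``c``      source-specific observation-noise spectrum
``f``      frequency-scaling (filtering) parameters
``D``      conduction delays (intrinsic, extrinsic), ms
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import POPULATIONS
from .network import NetworkSpec

__all__ = [
    "PriorTable",
    "ParameterIndex",
    "ParameterDensity",
    "FAMILIES",
    "INTRINSIC_TEMPLATE",
    "load_model_config",
    "save_model_config",
]

FAMILIES = ("kappa", "C", "H", "A", "AN", "L", "J", "a", "d", "b", "c", "f", "D")

KAPPA_CHANNELS = ("ampa", "gaba", "nmda")

#: Intrinsic connection template: (target population, source population,
#: strength, channel class).  Excitatory entries drive the AMPA and NMDA
#: conductances of the target; inhibitory entries drive GABA.  The nine
#: magnitudes are configurable; the default follows the canonical
#: microcircuit laminar wiring.
INTRINSIC_TEMPLATE: tuple[tuple[str, str, float, str], ...] = (
    ("sp", "ss", 80.0, "exc"),
    ("inh", "ss", 20.0, "exc"),
    ("dp", "sp", 48.0, "exc"),
    ("inh", "sp", 80.0, "exc"),
    ("inh", "dp", 40.0, "exc"),
    ("ss", "inh", 32.0, "inh"),
    ("sp", "inh", 20.0, "inh"),
    ("dp", "inh", 48.0, "inh"),
    ("inh", "inh", 128.0, "inh"),
)

#: Laminar targets of extrinsic connections: forward sp -> {ss, dp},
#: backward dp -> {sp, inh}; unit mask scaled by 1/8.
EXTRINSIC_MASKS = {
    "forward": {"source": "sp", "targets": ("ss", "dp")},
    "backward": {"source": "dp", "targets": ("sp", "inh")},
}
EXTRINSIC_SCALE = 1.0 / 8.0

#: Fixed population read-out weights (sp fixed, inh silent); ss and dp
#: weights are scaled by the free J parameters.
J_BASE = {"ss": 0.2, "sp": 0.8, "inh": 0.0, "dp": 0.2}


@dataclass(frozen=True)
class PriorTable:
    """Scaling constants theta0 and prior variances per family."""

    kappa_scale: tuple[float, float, float] = (4.0, 16.0, 100.0)
    capacitance_scale: tuple[float, float, float, float] = (0.128, 0.128, 0.256, 0.032)
    intrinsic_template: tuple[tuple[str, str, float, str], ...] = INTRINSIC_TEMPLATE
    extrinsic_scale: float = EXTRINSIC_SCALE
    gain_scale: float = float(np.e)  # log-gain prior N(1, 64) recentred to 0
    j_scale: tuple[float, float] = (J_BASE["ss"], J_BASE["dp"])
    delay_scale: tuple[float, float] = (2.0, 16.0)  # ms: intrinsic, extrinsic
    variances: Mapping[str, float] = field(
        default_factory=lambda: {
            "kappa": 1.0 / 16.0,
            "C": 1.0 / 16.0,
            "H": 1.0 / 32.0,
            "A": 1.0 / 8.0,
            "AN": 1.0 / 8.0,
            "L": 64.0,
            "J": 1.0 / 16.0,
            "a": 1.0 / 128.0,
            "d": 1.0 / 128.0,
            "b": 1.0 / 128.0,
            "c": 1.0 / 128.0,
            "f": 1.0 / 128.0,
            "D": 1.0 / 64.0,
        }
    )

    def __post_init__(self) -> None:
        missing = set(FAMILIES) - set(self.variances)
        extra = set(self.variances) - set(FAMILIES)
        if missing or extra:
            raise ValueError(
                f"variances must cover exactly the families {FAMILIES}; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        if any(v <= 0 for v in self.variances.values()):
            raise ValueError("all prior variances must be > 0")

    def build_index(self, net: NetworkSpec) -> "ParameterIndex":
        return ParameterIndex.build(net, self)

    def prior_density(self, net: NetworkSpec) -> "ParameterDensity":
        """Zero-mean diagonal prior over log-scale deviations."""
        index = self.build_index(net)
        var = np.array([self.variances[f] for f in index.families])
        return ParameterDensity(
            mean=np.zeros(index.size), cov=np.diag(var), index=index
        )


def save_model_config(path, priors: "PriorTable", net: NetworkSpec, constants=None) -> None:
    """Write the prior table, network and constants as YAML."""
    import yaml

    from .constants import ModelConstants

    constants = constants or ModelConstants()
    payload = {
        "priors": {
            "kappa_scale": list(priors.kappa_scale),
            "capacitance_scale": list(priors.capacitance_scale),
            "intrinsic_template": [list(t) for t in priors.intrinsic_template],
            "extrinsic_scale": priors.extrinsic_scale,
            "gain_scale": priors.gain_scale,
            "j_scale": list(priors.j_scale),
            "delay_scale": list(priors.delay_scale),
            "variances": dict(priors.variances),
        },
        "network": {
            "region_names": list(net.region_names),
            "forward_edges": [list(e) for e in net.forward_edges],
            "backward_edges": [list(e) for e in net.backward_edges],
        },
        "constants": {
            "v_leak": constants.v_leak,
            "v_ampa": constants.v_ampa,
            "v_gaba": constants.v_gaba,
            "v_nmda": constants.v_nmda,
            "alpha_nmda": constants.alpha_nmda,
            "sigmoid_threshold": constants.sigmoid_threshold,
            "sigmoid_slope": constants.sigmoid_slope,
        },
    }
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_model_config(path):
    """Read (PriorTable, NetworkSpec, ModelConstants) from YAML/JSON."""
    import yaml

    from .constants import ModelConstants

    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    pr = raw.get("priors", {})
    kwargs = {}
    for key in (
        "kappa_scale",
        "capacitance_scale",
        "j_scale",
        "delay_scale",
    ):
        if key in pr:
            kwargs[key] = tuple(pr[key])
    if "intrinsic_template" in pr:
        kwargs["intrinsic_template"] = tuple(
            (str(t[0]), str(t[1]), float(t[2]), str(t[3]))
            for t in pr["intrinsic_template"]
        )
    for key in ("extrinsic_scale", "gain_scale"):
        if key in pr:
            kwargs[key] = float(pr[key])
    if "variances" in pr:
        kwargs["variances"] = {k: float(v) for k, v in pr["variances"].items()}
    priors = PriorTable(**kwargs)
    nw = raw.get("network", {})
    net = NetworkSpec(
        region_names=tuple(nw["region_names"]),
        forward_edges=tuple(tuple(e) for e in nw.get("forward_edges", [])),
        backward_edges=tuple(tuple(e) for e in nw.get("backward_edges", [])),
    )
    constants = ModelConstants(**raw.get("constants", {}))
    return priors, net, constants


class ParameterIndex:
    """Ordered map from (family, region/edge, element) to coordinates."""

    def __init__(self, names: Sequence[str], families: Sequence[str]):
        if len(names) != len(families):
            raise ValueError("names and families must align")
        self._names = tuple(names)
        self._families = tuple(families)
        self._lookup = {n: i for i, n in enumerate(self._names)}
        if len(self._lookup) != len(self._names):
            raise ValueError("duplicate parameter names")

    @classmethod
    def build(cls, net: NetworkSpec, priors: PriorTable) -> "ParameterIndex":
        names: list[str] = []
        fams: list[str] = []

        def add(family: str, label: str) -> None:
            names.append(f"{family}[{label}]")
            fams.append(family)

        for r in net.region_names:
            for ch in KAPPA_CHANNELS:
                add("kappa", f"{r}.{ch}")
        for r in net.region_names:
            for p in POPULATIONS:
                add("C", f"{r}.{p}")
        for r in net.region_names:
            for tgt, src, _, _ in priors.intrinsic_template:
                add("H", f"{r}.{tgt}<-{src}")
        for kind, fam in (("forward", "A"), ("backward", "A")):
            for s, t in getattr(net, f"{kind}_edges"):
                add(fam, f"{t}<-{s}")
        for kind in ("forward", "backward"):
            for s, t in getattr(net, f"{kind}_edges"):
                add("AN", f"{t}<-{s}")
        for r in net.region_names:
            add("L", r)
        add("J", "ss")
        add("J", "dp")
        for i in (1, 2):
            add("a", str(i))
        for i in (1, 2, 3, 4):
            add("d", str(i))
        for i in (1, 2):
            add("b", str(i))
        for i in (1, 2):
            add("c", str(i))
        for i in (1, 2):
            add("f", str(i))
        add("D", "intrinsic")
        add("D", "extrinsic")
        return cls(names, fams)

    @property
    def size(self) -> int:
        return len(self._names)

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def families(self) -> tuple[str, ...]:
        return self._families

    def position(self, name: str) -> int:
        try:
            return self._lookup[name]
        except KeyError:
            raise KeyError(f"parameter {name!r} is not indexed") from None

    def family_indices(self, family: str) -> np.ndarray:
        if family not in FAMILIES:
            raise KeyError(f"unknown family {family!r}")
        return np.array(
            [i for i, f in enumerate(self._families) if f == family], dtype=int
        )

    def present_families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for f in self._families:
            if f not in seen:
                seen.append(f)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ParameterIndex)
            and self._names == other._names
            and self._families == other._families
        )

    def __repr__(self) -> str:
        return f"ParameterIndex({self.size} parameters)"


class ParameterDensity:
    """Gaussian density over log-scale parameter deviations."""

    __slots__ = ("mean", "cov", "index")

    def __init__(self, mean: np.ndarray, cov: np.ndarray, index: ParameterIndex | None = None):
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise ValueError(
                f"shape mismatch: mean {mean.shape}, cov {cov.shape}"
            )
        if index is not None and index.size != mean.size:
            raise ValueError("index size does not match mean length")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh((cov + cov.T) / 2).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(cov).max())):
            raise ValueError(f"covariance not PSD (min eigenvalue {eigmin:.3e})")
        self.mean = mean
        self.cov = (cov + cov.T) / 2
        self.index = index

    @property
    def size(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    def marginal(self, idx: np.ndarray) -> "ParameterDensity":
        idx = np.asarray(idx, dtype=int)
        sub_index = None
        if self.index is not None:
            sub_index = ParameterIndex(
                [self.index.names[i] for i in idx],
                [self.index.families[i] for i in idx],
            )
        return ParameterDensity(
            self.mean[idx], self.cov[np.ix_(idx, idx)], sub_index
        )

    def with_mean(self, mean: np.ndarray) -> "ParameterDensity":
        return ParameterDensity(mean, self.cov, self.index)

    def copy(self) -> "ParameterDensity":
        return ParameterDensity(self.mean.copy(), self.cov.copy(), self.index)

    def __repr__(self) -> str:
        return f"ParameterDensity(size={self.size})"
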