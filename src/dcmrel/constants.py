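"""Fixed biophysical constants and unit conventions.

Units
-----
- Membrane potential ``V``: millivolts (mV).
- Time: seconds internally.  Channel rate "constants" are expressed as
  time constants in **milliseconds** on the natural scale (so the prior
  scaling ``(4, 16, 100)`` reads as tau_AMPA = 4 ms etc.); the dynamics
  convert to rates via ``1000 / tau_ms``.
- Conductances: dimensionless multiples of the (fixed, unit) leak
  conductance ``G_LEAK``.
- Membrane capacitance ``C``: scaled so that ``G_LEAK / C`` is a rate in
  1/s (prior scaling ``(128, 128, 256, 32) / 1000``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelConstants", "POPULATIONS", "G_LEAK"]

#: Neuronal populations per region, in state order.
POPULATIONS = ("ss", "sp", "inh", "dp")

#: Fixed leak conductance (reference conductance unit).
G_LEAK = 1.0


@dataclass(frozen=True)
class ModelConstants:
    """Reversal potentials, magnesium-block slope and firing sigmoid.

    The firing rate is a logistic squashing function of depolarisation,
    ``sigma(V) = 1 / (1 + exp(-slope * (V - threshold)))``; the voltage
    dependence of the NMDA magnesium block is
    ``m(V) = 1 / (1 + 0.2 * exp(-alpha_nmda * V))``.
    """

    v_leak: float = -70.0
    v_ampa: float = 60.0
    v_gaba: float = -90.0
    v_nmda: float = 60.0
    alpha_nmda: float = 0.06
    sigmoid_threshold: float = -40.0
    sigmoid_slope: float = 0.1

    def __post_init__(self) -> None:
        if not (self.v_gaba < self.v_leak < self.v_ampa <= self.v_nmda):
            raise ValueError(
                "reversal potentials must satisfy "
                "v_gaba < v_leak < v_ampa <= v_nmda; got "
                f"({self.v_gaba}, {self.v_leak}, {self.v_ampa}, {self.v_nmda})"
            )
        if self.alpha_nmda <= 0:
            raise ValueError("alpha_nmda must be > 0")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid_slope must be > 0")
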