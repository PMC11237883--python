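"""Network topology: regions and directed forward/backward edges.

Forward connections originate in superficial pyramidal (sp) cells and
target spiny stellate (ss) and deep pyramidal (dp) cells of the distal
region; backward connections originate in deep pyramidal cells and
target superficial pyramidal and inhibitory (inh) populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NetworkSpec", "default_network", "DMN_REGIONS"]

#: Default-mode-network region labels used by the 4-region configuration.
DMN_REGIONS = ("LAG", "RAG", "MPFC", "PCC")

N_POPULATIONS = 4


@dataclass(frozen=True)
class NetworkSpec:
    """Regions plus directed forward/backward edges (by region name)."""

    region_names: tuple[str, ...]
    forward_edges: tuple[tuple[str, str], ...] = ()
    backward_edges: tuple[tuple[str, str], ...] = ()
    n_populations: int = N_POPULATIONS
    intrinsic_delay_ms: float = 2.0
    extrinsic_delay_ms: float = 16.0

    def __post_init__(self) -> None:
        if self.n_populations != N_POPULATIONS:
            raise ValueError("n_populations is fixed at 4 (ss, sp, inh, dp)")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names")
        for src, dst in self.forward_edges + self.backward_edges:
            if src == dst:
                raise ValueError(f"self-edge {src}->{dst} not allowed")
            for name in (src, dst):
                if name not in self.region_names:
                    raise ValueError(f"edge references undeclared region {name!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_states(self) -> int:
        # V + three ligand-gated conductances per population
        return 4 * self.n_populations * self.n_regions

    def region_index(self, name: str) -> int:
        return self.region_names.index(name)

    @property
    def edges(self) -> tuple[tuple[str, str, str], ...]:
        """All directed edges as ``(kind, source, target)`` tuples."""
        fwd = tuple(("forward", s, t) for s, t in self.forward_edges)
        bwd = tuple(("backward", s, t) for s, t in self.backward_edges)
        return fwd + bwd


def default_network(n_regions: int = 2) -> NetworkSpec:
    """Fully connected default network with 1, 2 or 4 regions.

    For every ordered region pair (i, j) with i < j the edge i->j is
    declared forward and j->i backward, giving a fully connected
    hierarchy-free graph as in the 4-region default-mode configuration.
    """
    if n_regions == 4:
        names = DMN_REGIONS
    elif n_regions in (1, 2, 3):
        names = tuple(f"R{i + 1}" for i in range(n_regions))
    else:
        raise ValueError("n_regions must be in {1, 2, 3, 4}")
    fwd = []
    bwd = []
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            fwd.append((names[i], names[j]))
            bwd.append((names[j], names[i]))
    return NetworkSpec(
        region_names=names,
        forward_edges=tuple(fwd),
        backward_edges=tuple(bwd),
    )
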