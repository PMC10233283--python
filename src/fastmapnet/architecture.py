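"""Cortical area graph and synaptic-topology construction.

Twelve areas, each a 25x25 grid of excitatory cells backed by a matching grid
of graded inhibitory cells.  Excitatory synapses (within- and between-area)
are created once, sparsely and topographically: the probability of a synapse
between cells at Euclidean grid distance d is a clipped Gaussian
``p0 * exp(-d^2 / (2 sigma^2))``, zero outside a square neighborhood window.
Learning later changes weights, never topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .params import ConnectivityParams

__all__ = [
    "AreaSpec",
    "Architecture",
    "AREA_NAMES",
    "HUB_AREAS",
    "PRIMARY_AREAS",
    "AREA_LINKS",
    "build_area_graph",
    "default_architecture",
    "gaussian_connection_probability",
    "init_within_area",
    "init_between_area",
    "init_inhibition",
    "expected_out_degree",
]

#: canonical area order used for all state arrays
AREA_NAMES: tuple[str, ...] = (
    "A1", "AB", "PB", "PF_i", "PM_i", "M1_i",
    "V1", "TO", "AT", "PF_L", "PM_L", "M1_L",
)

HUB_AREAS = frozenset({"PB", "PF_i", "AT", "PF_L"})
PRIMARY_AREAS = frozenset({"A1", "M1_i", "V1", "M1_L"})

_SYSTEMS = {
    "A1": "auditory", "AB": "auditory", "PB": "auditory",
    "PF_i": "articulatory", "PM_i": "articulatory", "M1_i": "articulatory",
    "V1": "visual", "TO": "visual", "AT": "visual",
    "PF_L": "hand-motor", "PM_L": "hand-motor", "M1_L": "hand-motor",
}

#: the 22 reciprocal cortico-cortical links: 10 next-neighbor,
#: 8 second-next-neighbor ("jumping") and 4 long-distance connections
AREA_LINKS: tuple[tuple[str, str], ...] = (
    # next-neighbor
    ("A1", "AB"), ("AB", "PB"), ("PF_i", "PM_i"), ("PM_i", "M1_i"),
    ("V1", "TO"), ("TO", "AT"), ("PF_L", "PM_L"), ("PM_L", "M1_L"),
    ("AT", "PB"), ("PF_i", "PF_L"),
    # second-next-neighbor
    ("A1", "PB"), ("PB", "PM_i"), ("AB", "PF_i"), ("PF_i", "M1_i"),
    ("V1", "AT"), ("AT", "PM_L"), ("TO", "PF_L"), ("PF_L", "M1_L"),
    # long-distance
    ("PF_i", "PB"), ("AT", "PF_L"), ("PB", "PF_L"), ("AT", "PF_i"),
)


@dataclass(frozen=True)
class AreaSpec:
    name: str
    system: str
    rank: str  # primary | secondary | hub

    def __post_init__(self) -> None:
        if self.rank not in ("primary", "secondary", "hub"):
            raise ValueError(f"bad area rank {self.rank!r}")


def _rank(name: str) -> str:
    if name in PRIMARY_AREAS:
        return "primary"
    if name in HUB_AREAS:
        return "hub"
    return "secondary"


@dataclass(frozen=True)
class Architecture:
    """Area list plus reciprocal link set; ``n_side`` is the grid edge length.

    The default is the 12-area / 22-link cortical graph on 25x25 grids; tests
    use smaller custom instances.
    """

    areas: tuple[AreaSpec, ...]
    links: tuple[tuple[str, str], ...]
    n_side: int = 25

    def __post_init__(self) -> None:
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate area names")
        for a, b in self.links:
            if a not in names or b not in names:
                raise ValueError(f"link ({a}, {b}) references unknown area")
            if a == b:
                raise ValueError("self-links are not allowed")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_cells(self) -> int:
        return self.n_side * self.n_side

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.areas)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def has_link(self, a: str, b: str) -> bool:
        return (a, b) in self.links or (b, a) in self.links

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for area in self.areas:
            g.add_node(area.name, system=area.system, rank=area.rank)
        g.add_edges_from(self.links)
        return g

    def directed_projections(self) -> list[tuple[str, str]]:
        """Every reciprocal link realized as two directed projections."""
        out: list[tuple[str, str]] = []
        for a, b in self.links:
            out.append((a, b))
            out.append((b, a))
        return out


def build_area_graph() -> Architecture:
    """The 12-area cortical architecture with the 22 reciprocal links."""
    areas = tuple(AreaSpec(n, _SYSTEMS[n], _rank(n)) for n in AREA_NAMES)
    arch = Architecture(areas=areas, links=AREA_LINKS, n_side=25)
    assert arch.n_cells == 625
    return arch


# kept as a convenience alias used throughout the package
default_architecture = build_area_graph


# ---------------------------------------------------------------------------
# connection kernels
# ---------------------------------------------------------------------------

def _grid_coords(n_side: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.divmod(np.arange(n_side * n_side), n_side)
    return rows, cols


def gaussian_connection_probability(
    d2: np.ndarray | float, p0: float, sigma: float, radius: int,
    chebyshev: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Clipped-Gaussian synapse probability at squared Euclidean distance d2.

    The clip window is the square neighborhood of half-width ``radius``
    (Chebyshev distance); pass ``chebyshev`` when it differs from sqrt(d2).
    """
    d2 = np.asarray(d2, dtype=float)
    if sigma <= 0:
        # degenerate kernel: only distance-0 (between-area) / the four nearest
        # neighbors at d=1 keep a finite limit of exp(-d^2/2s^2) -> [d2 == 0]
        p = np.where(d2 == 0.0, p0, 0.0)
    else:
        p = p0 * np.exp(-d2 / (2.0 * sigma * sigma))
    cheb = np.sqrt(d2) if chebyshev is None else np.asarray(chebyshev, dtype=float)
    return np.where(cheb <= radius, p, 0.0)


def _pairwise_kernel(
    n_side: int, p0: float, sigma: float, radius: int, allow_self: bool
) -> np.ndarray:
    """(n_cells, n_cells) matrix of connection probabilities source -> target."""
    rows, cols = _grid_coords(n_side)
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    d2 = (dr * dr + dc * dc).astype(float)
    cheb = np.maximum(np.abs(dr), np.abs(dc)).astype(float)
    p = gaussian_connection_probability(d2, p0, sigma, radius, chebyshev=cheb)
    if not allow_self:
        np.fill_diagonal(p, 0.0)
    return p


def _realize(p: np.ndarray, lo: float, hi: float, rng: np.random.Generator) -> sp.csr_matrix:
    """Sample synapses from the probability matrix; weights ~ U[lo, hi].

    Rows index the presynaptic (source) cell, columns the postsynaptic
    (target) cell, so a row slice is a cell's out-synapse list.
    """
    mask = rng.random(p.shape) < p
    src, dst = np.nonzero(mask)
    w = rng.uniform(lo, hi, size=src.size)
    m = sp.csr_matrix((w, (src, dst)), shape=p.shape)
    m.sort_indices()
    return m


def init_within_area(
    params: ConnectivityParams, rng: np.random.Generator, n_side: int = 25
) -> sp.csr_matrix:
    """Within-area excitatory synapses (no self-synapse), topographic."""
    p = _pairwise_kernel(
        n_side, params.within_p0, params.within_gaussian_sigma,
        params.within_neighborhood_radius, allow_self=False,
    )
    return _realize(p, params.w_init_lo, params.w_init_hi, rng)


def init_between_area(
    arch: Architecture,
    source: str,
    target: str,
    params: ConnectivityParams,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Topographic projection between two linked areas.

    Cell (i, j) of the source preferentially contacts cells near (i, j) of the
    target (the grids are in register), including the in-register cell itself.
    """
    if not arch.has_link(source, target):
        raise ValueError(f"areas {source!r} and {target!r} are not linked")
    p = _pairwise_kernel(
        arch.n_side, params.between_p0, params.between_gaussian_sigma,
        params.between_neighborhood_radius, allow_self=True,
    )
    return _realize(p, params.w_init_lo, params.w_init_hi, rng)


def init_inhibition(params: ConnectivityParams, n_side: int = 25) -> sp.csr_matrix:
    """Local inhibitory pooling: inhibitory cell x sums excitatory output over
    the square neighborhood of x (truncated at the borders) and feeds back onto
    the excitatory cell at x.  Returned as a (n_cells, n_cells) 0/1 pooling
    matrix: row x selects the excitatory cells pooled by inhibitory cell x.
    """
    r = params.inhib_neighborhood_radius
    rows, cols = _grid_coords(n_side)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    pool = ((dr <= r) & (dc <= r)).astype(float)
    return sp.csr_matrix(pool)


def expected_out_degree(params: ConnectivityParams, n_side: int = 25, kind: str = "within") -> float:
    """Analytic mean out-degree per cell, averaged over grid positions."""
    if kind == "within":
        p = _pairwise_kernel(
            n_side, params.within_p0, params.within_gaussian_sigma,
            params.within_neighborhood_radius, allow_self=False,
        )
    elif kind == "between":
        p = _pairwise_kernel(
            n_side, params.between_p0, params.between_gaussian_sigma,
            params.between_neighborhood_radius, allow_self=True,
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(p.sum(axis=1).mean())
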