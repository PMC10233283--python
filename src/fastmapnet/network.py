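"""Network state: cell-state arrays plus the packed synaptic weight store.

One :class:`NetworkState` represents one simulated "subject": the 12 areas'
excitatory/inhibitory cell states, the area-specific global inhibition levels
and every excitatory-to-excitatory synapse.  Synapses are stored once, packed
into flat arrays indexed two ways (by presynaptic cell for spike propagation,
by postsynaptic cell for plasticity), so the numba kernels in
:mod:`fastmapnet.dynamics` can run over them without per-step conversions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .architecture import Architecture, default_architecture, init_between_area, init_inhibition, init_within_area
from .dynamics import _cells_kernel, _plasticity_kernel, _propagate_kernel
from .params import ExperimentConfig, config_hash, load_config, save_config

__all__ = ["ConnectivityPack", "NetworkState", "build_network", "save_network", "load_network"]

_TRIAL_STREAM = 104729      # stream tags folded into per-network seed sequences
_PATTERN_STREAM = 7919


class ConnectivityPack:
    """All synapse blocks concatenated for the engine kernels.

    A block is one directed projection (within-area blocks have src == dst).
    ``indptr[b, i]:indptr[b, i+1]`` slices the out-synapses of presynaptic
    cell ``i`` of block ``b`` inside ``idx`` (postsynaptic cell) and ``data``
    (weight).  The transpose index (``t_indptr``/``t_pre``/``t_pos``) groups
    the same synapses by postsynaptic cell; ``t_pos`` points back into
    ``data``, which is the single authoritative weight store.
    """

    def __init__(self, blocks: list[tuple[int, int, sp.csr_matrix]], n_cells: int):
        self.n_cells = n_cells
        self.block_pairs = [(s, d) for s, d, _ in blocks]
        n_blocks = len(blocks)
        self.block_src = np.array([s for s, _, _ in blocks], dtype=np.int64)
        self.block_dst = np.array([d for _, d, _ in blocks], dtype=np.int64)
        nnz_tot = sum(int(m.nnz) for _, _, m in blocks)
        self.indptr = np.zeros((n_blocks, n_cells + 1), dtype=np.int64)
        self.idx = np.empty(nnz_tot, dtype=np.int32)
        self.data = np.empty(nnz_tot, dtype=np.float64)
        self.t_indptr = np.zeros((n_blocks, n_cells + 1), dtype=np.int64)
        self.t_pre = np.empty(nnz_tot, dtype=np.int32)
        self.t_pos = np.empty(nnz_tot, dtype=np.int64)
        self._offsets = np.zeros(n_blocks + 1, dtype=np.int64)

        off = 0
        for b, (_, _, m) in enumerate(blocks):
            m = m.tocsr()
            m.sort_indices()
            nnz = int(m.nnz)
            self._offsets[b] = off
            self.indptr[b] = off + m.indptr.astype(np.int64)
            self.idx[off:off + nnz] = m.indices
            self.data[off:off + nnz] = m.data
            # transpose index: group this block's synapses by postsynaptic cell
            coo = m.tocoo()
            order = np.lexsort((coo.row, coo.col))
            self.t_pre[off:off + nnz] = coo.row[order]
            self.t_pos[off:off + nnz] = off + order
            counts = np.bincount(coo.col, minlength=n_cells)
            self.t_indptr[b] = off + np.concatenate(([0], np.cumsum(counts)))
            off += nnz
        self._offsets[-1] = off

    @property
    def nnz(self) -> int:
        return int(self.data.size)

    def block_csr(self, src: int, dst: int) -> sp.csr_matrix:
        """The (pre x post) weight matrix of one projection.

        The returned matrix shares memory with the pack's weight store, so it
        reflects (and edits propagate to) the live weights.
        """
        b = self.block_pairs.index((src, dst))
        lo, hi = int(self._offsets[b]), int(self._offsets[b + 1])
        indptr = (self.indptr[b] - lo).astype(np.int64)
        return sp.csr_matrix(
            (self.data[lo:hi], self.idx[lo:hi], indptr),
            shape=(self.n_cells, self.n_cells),
        )


@dataclass
class NetworkState:
    """Full mutable state of one simulated subject."""

    arch: Architecture
    config: ExperimentConfig
    network_seed: int
    pack: ConnectivityPack
    pool_indptr: np.ndarray
    pool_idx: np.ndarray
    V_e: np.ndarray = field(init=False)
    omega_A: np.ndarray = field(init=False)
    omega_E: np.ndarray = field(init=False)
    O_e: np.ndarray = field(init=False)
    V_i: np.ndarray = field(init=False)
    O_i: np.ndarray = field(init=False)
    glob_inhib: np.ndarray = field(init=False)
    rng_trial: np.random.Generator = field(init=False)
    step_count: int = 0

    def __post_init__(self) -> None:
        a, n = self.arch.n_areas, self.arch.n_cells
        self.V_e = np.zeros((a, n))
        self.omega_A = np.zeros((a, n))
        self.omega_E = np.zeros((a, n))
        self.O_e = np.zeros((a, n))
        self.V_i = np.zeros((a, n))
        self.O_i = np.zeros((a, n))
        self.glob_inhib = np.zeros(a)
        self._X = np.zeros((a, n))
        self._eta = np.zeros((a, n))
        self.rng_trial = np.random.default_rng(
            np.random.SeedSequence([self.network_seed, _TRIAL_STREAM])
        )

    # -- simulation -------------------------------------------------------
    def step(
        self,
        external: np.ndarray | None = None,
        noise_on: bool = True,
        learning: bool = True,
        kG: float | None = None,
    ) -> None:
        """Advance the whole network one simulation step."""
        cfg = self.config
        np_, gp, pp = cfg.neuron, cfg.global_inhibition, cfg.plasticity
        if external is None:
            self._X[:] = 0.0
        else:
            np.copyto(self._X, external)
        _propagate_kernel(
            self.pack.block_src, self.pack.block_dst,
            self.pack.indptr, self.pack.idx, self.pack.data,
            self.O_e, self._X,
        )
        if noise_on:
            self._eta = self.rng_trial.uniform(
                -np_.noise_bound, np_.noise_bound, self._eta.shape
            )
        _cells_kernel(
            self.V_e, self.omega_A, self.omega_E, self.O_e, self.V_i, self.O_i,
            self.glob_inhib, self._X, self._eta, noise_on,
            self.pool_indptr, self.pool_idx,
            np_.tau_exc, np_.tau_inh, np_.k1, np_.k2, np_.thresh, np_.alpha,
            np_.tau_adapt, np_.tau_favg, np_.local_inhibition_strength,
            gp.kG if kG is None else kG, gp.tau_glob, gp.input_scale,
        )
        if learning and pp.learning_enabled:
            _plasticity_kernel(
                self.pack.block_src, self.pack.block_dst,
                self.pack.t_indptr, self.pack.t_pre, self.pack.t_pos,
                self.pack.data, self.V_e, self.omega_E,
                pp.theta_pre, pp.theta_plus, pp.theta_minus, pp.delta, pp.w_max,
            )
        self.step_count += 1

    # -- transient state handling ----------------------------------------
    _TRANSIENT = ("V_e", "omega_A", "omega_E", "O_e", "V_i", "O_i", "glob_inhib")

    def snapshot_transient(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).copy() for k in self._TRANSIENT}

    def restore_transient(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            np.copyto(getattr(self, k), v)

    def reset_transient(self) -> None:
        for k in self._TRANSIENT:
            getattr(self, k)[:] = 0.0

    # -- convenience ------------------------------------------------------
    def weights(self, src: str, dst: str) -> sp.csr_matrix:
        """Live (pre x post) weight matrix of one directed projection."""
        return self.pack.block_csr(self.arch.index(src), self.arch.index(dst))

    def gate_satisfied(self) -> bool:
        gp = self.config.global_inhibition
        gate = [self.arch.index(n) for n in gp.gate_areas if n in self.arch.names]
        return bool(np.all(self.glob_inhib[gate] < gp.baseline_gate_threshold))


def _projection_rng(network_seed: int, src: int, dst: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([network_seed, src, dst]))


def build_network(
    config: ExperimentConfig,
    network_seed: int,
    arch: Architecture | None = None,
) -> NetworkState:
    """Create and randomly initialize one network (one simulated subject).

    Connectivity is a pure function of ``(network_seed, area pair)``: every
    projection gets its own seeded stream, so rebuilding with the same seed
    reproduces the synapse topology and initial weights bit-exactly.
    """
    arch = arch or default_architecture()
    cp = config.connectivity
    blocks: list[tuple[int, int, sp.csr_matrix]] = []
    for a in range(arch.n_areas):
        m = init_within_area(cp, _projection_rng(network_seed, a, a), arch.n_side)
        blocks.append((a, a, m))
    for src_name, dst_name in arch.directed_projections():
        s, d = arch.index(src_name), arch.index(dst_name)
        m = init_between_area(arch, src_name, dst_name, cp, _projection_rng(network_seed, s, d))
        blocks.append((s, d, m))
    pack = ConnectivityPack(blocks, arch.n_cells)
    pool = init_inhibition(cp, arch.n_side)
    return NetworkState(
        arch=arch, config=config, network_seed=network_seed, pack=pack,
        pool_indptr=pool.indptr.astype(np.int64), pool_idx=pool.indices.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# persistence (checkpoint between learning phases)
# ---------------------------------------------------------------------------

def save_network(net: NetworkState, path: str | Path, extra_attrs: dict | None = None) -> None:
    """Persist weights, cell states, RNG stream and config to one HDF5 file."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["network_seed"] = net.network_seed
        f.attrs["step_count"] = net.step_count
        f.attrs["config_hash"] = config_hash(net.config)
        f.attrs["rng_state"] = json.dumps(net.rng_trial.bit_generator.state)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v
        st = f.create_group("state")
        for k in NetworkState._TRANSIENT:
            st.create_dataset(k, data=getattr(net, k))
        f.create_dataset("weights", data=net.pack.data)
    # config stored next to the container so a run is self-describing
    save_config(net.config, path.with_suffix(".config.yaml"))


def load_network(path: str | Path, config: ExperimentConfig | None = None) -> NetworkState:
    """Rebuild a network from a checkpoint; bit-exact resume under fixed seeds."""
    import h5py

    path = Path(path)
    if config is None:
        config = load_config(path.with_suffix(".config.yaml"))
    with h5py.File(path, "r") as f:
        if f.attrs["config_hash"] != config_hash(config):
            raise ValueError("checkpoint was produced with a different configuration")
        net = build_network(config, int(f.attrs["network_seed"]))
        for k in NetworkState._TRANSIENT:
            np.copyto(getattr(net, k), f["state"][k][...])
        np.copyto(net.pack.data, f["weights"][...])
        net.rng_trial.bit_generator.state = json.loads(f.attrs["rng_state"])
        net.step_count = int(f.attrs["step_count"])
    return net
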