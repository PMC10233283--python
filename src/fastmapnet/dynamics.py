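"""Per-time-step neural dynamics.

Excitatory cells are leaky integrate-and-fire units with threshold adaptation
and a running firing-rate estimate; inhibitory cells are graded (rectified
leaky integrators over a local excitatory pool); each area additionally has a
scalar global-inhibition level that tracks its total spike output.

All integrators share the explicit-Euler discretization with a step of one
simulation tick,

    x(t+1) = x(t) + (1/tau) * (-x(t) + drive(t)),

so the leak factor per step is (1 - 1/tau).  For excitatory and inhibitory
membranes the drive is ``k1 * (V_in + k2 * eta)`` where ``V_in`` is the summed
input field and ``eta`` the white noise (zero for inhibitory cells and when
noise is off).  A cell spikes when ``V - alpha * omega_A >= thresh``, i.e.
adaptation acts as threshold elevation.

The module exposes the scalar/one-shot operations (unit-testable contracts)
and the fused numba kernels the simulation engine actually runs; both follow
the identical update order, which is:

    1. synaptic input field X from the previous step's spikes,
       minus local and global inhibition (both lagged one step);
    2. excitatory membrane + spike + adaptation + rate estimate;
    3. inhibitory pool (from the new spikes) and membrane;
    4. global inhibition (from the new spikes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .params import GlobalInhibitionParams, NeuronParams

__all__ = [
    "CellState",
    "step_excitatory",
    "step_inhibitory",
    "step_global_inhibition",
    "total_input",
]


@dataclass(frozen=True)
class CellState:
    """State of a single model cell (excitatory or inhibitory)."""

    V: float = 0.0        # membrane potential
    omega_E: float = 0.0  # estimated firing rate, in [0, 1] (excitatory only)
    omega_A: float = 0.0  # adaptation variable (excitatory only)
    O: float = 0.0        # last output: binary spike (exc) or graded >= 0 (inh)


def step_excitatory(
    cell: CellState, input_: float, params: NeuronParams, eta: float = 0.0
) -> CellState:
    """Advance one excitatory cell a single step.

    ``input_`` is the total input field V_in (synaptic + external - inhibitory
    - global); ``eta`` is the white-noise draw (already in [-bound, bound]; 0
    when noise is off).
    """
    if not np.isfinite(input_):
        raise FloatingPointError(f"non-finite input to excitatory cell: {input_!r}")
    V = cell.V + (1.0 / params.tau_exc) * (
        -cell.V + params.k1 * (input_ + params.k2 * eta)
    )
    O = 1.0 if (V - params.alpha * cell.omega_A) >= params.thresh else 0.0
    omega_A = cell.omega_A + (1.0 / params.tau_adapt) * (-cell.omega_A + O)
    omega_E = cell.omega_E + (1.0 / params.tau_favg) * (-cell.omega_E + O)
    return CellState(V=V, omega_E=omega_E, omega_A=omega_A, O=O)


def step_inhibitory(cell: CellState, input_: float, params: NeuronParams) -> CellState:
    """Advance one graded inhibitory cell a single step (no noise, rectified)."""
    if not np.isfinite(input_):
        raise FloatingPointError(f"non-finite input to inhibitory cell: {input_!r}")
    V = cell.V + (1.0 / params.tau_inh) * (-cell.V + params.k1 * input_)
    O = V if V > 0.0 else 0.0
    return replace(cell, V=V, O=O)


def step_global_inhibition(
    glob_inhib: float, spike_sum: float, params: GlobalInhibitionParams,
    kG: float | None = None,
) -> float:
    """Advance one area's global-inhibition level.

    ``spike_sum`` is the area's total excitatory output this step; ``kG``
    overrides the baseline strength (attention manipulation).
    """
    k = params.kG if kG is None else kG
    drive = k * params.input_scale * spike_sum
    return glob_inhib + (1.0 / params.tau_glob) * (-glob_inhib + drive)


def total_input(
    blocks,
    O_exc: np.ndarray,
    external: np.ndarray | None,
    O_inh: np.ndarray | None,
    glob_inhib: np.ndarray | None,
    params: NeuronParams,
    noise_on: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Total input field V_in for every excitatory cell (one step).

    ``blocks`` is an iterable of ``(src_area, dst_area, csr)`` where the CSR
    rows index presynaptic cells of ``src_area`` and columns postsynaptic
    cells of ``dst_area``.  ``O_exc`` has shape (n_areas, n_cells).  The local
    inhibitory output and global inhibition enter subtractively; white noise
    (uniform, scaled by k2) is added when ``noise_on``.
    """
    O_exc = np.asarray(O_exc, dtype=np.float64)
    n_areas, n_cells = O_exc.shape
    X = np.zeros((n_areas, n_cells))
    for src, dst, w in blocks:
        if w.shape != (n_cells, n_cells):
            raise ValueError(
                f"weight block {src}->{dst} has shape {w.shape}, "
                f"expected {(n_cells, n_cells)}"
            )
        X[dst] += w.T @ O_exc[src]
    if external is not None:
        X += external
    if O_inh is not None:
        X -= params.local_inhibition_strength * np.asarray(O_inh, dtype=np.float64)
    if glob_inhib is not None:
        X -= np.asarray(glob_inhib, dtype=np.float64)[:, None]
    if noise_on:
        if rng is None:
            raise ValueError("noise_on requires an rng")
        X += params.k2 * rng.uniform(-params.noise_bound, params.noise_bound, X.shape)
    return X


# ---------------------------------------------------------------------------
# fused engine kernels (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _propagate_kernel(block_src, block_dst, indptr, idx, data, O_exc, X):
    """Accumulate synaptic drive from last step's spikes into X (in place)."""
    n_blocks = block_src.shape[0]
    n_cells = O_exc.shape[1]
    for b in range(n_blocks):
        s = block_src[b]
        d = block_dst[b]
        for i in range(n_cells):
            if O_exc[s, i] != 0:
                for k in range(indptr[b, i], indptr[b, i + 1]):
                    X[d, idx[k]] += data[k]


@njit(cache=False)
def _cells_kernel(
    V_e, oA, oE, O_e, V_i, O_i, glob,
    X, eta, noise_on,
    pool_indptr, pool_idx,
    tau_exc, tau_inh, k1, k2, thresh, alpha, tau_adapt, tau_favg, kS,
    kG, tau_glob, glob_scale,
):
    """Advance all cell states one step given the input field X."""
    n_areas, n_cells = V_e.shape
    for a in range(n_areas):
        # excitatory layer
        for i in range(n_cells):
            vin = X[a, i] - kS * O_i[a, i] - glob[a]
            if noise_on:
                vin += k2 * eta[a, i]
            v = V_e[a, i] + (1.0 / tau_exc) * (-V_e[a, i] + k1 * vin)
            V_e[a, i] = v
            o = 1.0 if (v - alpha * oA[a, i]) >= thresh else 0.0
            O_e[a, i] = o
            oA[a, i] = oA[a, i] + (1.0 / tau_adapt) * (-oA[a, i] + o)
            oE[a, i] = oE[a, i] + (1.0 / tau_favg) * (-oE[a, i] + o)
        # inhibitory layer: pool the *new* spikes
        for i in range(n_cells):
            c = 0.0
            for k in range(pool_indptr[i], pool_indptr[i + 1]):
                c += O_e[a, pool_idx[k]]
            v = V_i[a, i] + (1.0 / tau_inh) * (-V_i[a, i] + k1 * c)
            V_i[a, i] = v
            O_i[a, i] = v if v > 0.0 else 0.0
        # area-specific global inhibition
        s = 0.0
        for i in range(n_cells):
            s += O_e[a, i]
        glob[a] = glob[a] + (1.0 / tau_glob) * (-glob[a] + kG * glob_scale * s)


@njit(cache=False)
def _plasticity_kernel(
    block_src, block_dst, t_indptr, t_pre, t_pos, data,
    V_e, oE, theta_pre, theta_plus, theta_minus, delta, w_max,
):
    """Apply the Hebbian rule to every synapse whose postsynaptic potential is
    at least theta_minus (all other synapses change by exactly 0)."""
    n_blocks = block_src.shape[0]
    n_cells = V_e.shape[1]
    for b in range(n_blocks):
        s = block_src[b]
        d = block_dst[b]
        for j in range(n_cells):
            v = V_e[d, j]
            if v < theta_minus:
                continue
            up = v >= theta_plus
            for k in range(t_indptr[b, j], t_indptr[b, j + 1]):
                pre_on = oE[s, t_pre[k]] >= theta_pre
                p = t_pos[k]
                if up:
                    if pre_on:
                        w = data[p] + delta   # LTP
                        data[p] = w if w < w_max else w_max
                    else:
                        w = data[p] - delta   # heterosynaptic LTD
                        data[p] = w if w > 0.0 else 0.0
                elif pre_on:
                    w = data[p] - delta       # homosynaptic LTD
                    data[p] = w if w > 0.0 else 0.0
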