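"""Discretized Hebbian plasticity: LTP, homosynaptic and heterosynaptic LTD.

Each existing excitatory-to-excitatory synapse changes by exactly +Delta,
-Delta or 0 per step, selected by the presynaptic rate estimate omega_E
against theta_pre and the postsynaptic membrane potential V against the
theta_minus/theta_plus band:

    +Delta  if omega_E >= theta_pre and V >= theta_plus      (LTP)
    -Delta  if omega_E >= theta_pre and theta_minus <= V < theta_plus
                                                             (homosynaptic LTD)
    -Delta  if omega_E <  theta_pre and V >= theta_plus      (heterosynaptic LTD)
     0      otherwise

The result is clamped to [0, w_max].  Weight changes never alter topology.
"""

from __future__ import annotations

import numpy as np

from .dynamics import _plasticity_kernel
from .params import PlasticityParams

__all__ = ["hebbian_update", "apply_plasticity_step"]


def hebbian_update(
    w: float | np.ndarray,
    pre_rate: float | np.ndarray,
    post_V: float | np.ndarray,
    params: PlasticityParams,
) -> float | np.ndarray:
    """New weight(s) after one plasticity step; scalar or elementwise."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0) or np.any(w > params.w_max):
        raise ValueError("weight outside [0, w_max] on entry")
    pre_on = np.asarray(pre_rate, dtype=float) >= params.theta_pre
    v = np.asarray(post_V, dtype=float)
    up = v >= params.theta_plus
    mid = (v >= params.theta_minus) & ~up
    change = np.where(
        pre_on & up, params.delta,
        np.where((pre_on & mid) | (~pre_on & up), -params.delta, 0.0),
    )
    out = np.clip(w + change, 0.0, params.w_max)
    return float(out) if out.ndim == 0 else out


def apply_plasticity_step(net, params: PlasticityParams | None = None) -> None:
    """Apply one Hebbian step to every synapse of ``net`` (in place).

    Uses the current presynaptic omega_E and postsynaptic V of the network;
    a no-op when learning is disabled.
    """
    params = params or net.config.plasticity
    if not params.learning_enabled:
        return
    _plasticity_kernel(
        net.pack.block_src, net.pack.block_dst,
        net.pack.t_indptr, net.pack.t_pre, net.pack.t_pos, net.pack.data,
        net.V_e, net.omega_E,
        params.theta_pre, params.theta_plus, params.theta_minus,
        params.delta, params.w_max,
    )
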