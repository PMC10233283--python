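"""Independent reference implementations used as oracles in the tests.

Everything here is deliberately written as plain per-cell / per-synapse Python
loops over dictionaries and lists, mirroring the *documented* update order of
the simulator but sharing none of its vectorized code paths.
"""

from __future__ import annotations

import numpy as np


class ScalarNetworkReference:
    """Per-cell scalar re-implementation of the network update.

    Update order (one step):
      1. X = external + synaptic drive from last step's spikes
         - local inhibition (lagged) - global inhibition (lagged)
      2. excitatory membrane, spike, adaptation, rate estimate
      3. inhibitory pool over the new spikes, inhibitory membrane
      4. global inhibition from the new spikes
    """

    def __init__(self, net):
        cfg = net.config
        self.np_ = cfg.neuron
        self.gp = cfg.global_inhibition
        self.pp = cfg.plasticity
        self.n_areas = net.arch.n_areas
        self.n_cells = net.arch.n_cells
        # copy synapses into plain python structures, preserving engine order
        self.blocks = []
        pack = net.pack
        for b, (s, d) in enumerate(pack.block_pairs):
            rows = []
            for i in range(self.n_cells):
                lo, hi = int(pack.indptr[b, i]), int(pack.indptr[b, i + 1])
                rows.append([(int(pack.idx[k]), float(pack.data[k])) for k in range(lo, hi)])
            self.blocks.append((s, d, rows))
        self.pool = []
        for i in range(self.n_cells):
            lo, hi = int(net.pool_indptr[i]), int(net.pool_indptr[i + 1])
            self.pool.append([int(j) for j in net.pool_idx[lo:hi]])
        z = lambda: [[0.0] * self.n_cells for _ in range(self.n_areas)]
        self.V_e, self.oA, self.oE, self.O_e, self.V_i, self.O_i = (
            z(), z(), z(), z(), z(), z()
        )
        self.g = [0.0] * self.n_areas

    def step(self, external=None, kG=None):
        p, gp = self.np_, self.gp
        kG = gp.kG if kG is None else kG
        X = [[0.0] * self.n_cells for _ in range(self.n_areas)]
        if external is not None:
            for a in range(self.n_areas):
                for i in range(self.n_cells):
                    X[a][i] = float(external[a][i])
        for s, d, rows in self.blocks:
            for i in range(self.n_cells):
                if self.O_e[s][i] != 0.0:
                    for j, w in rows[i]:
                        X[d][j] += w
        for a in range(self.n_areas):
            for i in range(self.n_cells):
                vin = X[a][i] - p.local_inhibition_strength * self.O_i[a][i] - self.g[a]
                v = self.V_e[a][i] + (1.0 / p.tau_exc) * (-self.V_e[a][i] + p.k1 * vin)
                self.V_e[a][i] = v
                o = 1.0 if (v - p.alpha * self.oA[a][i]) >= p.thresh else 0.0
                self.O_e[a][i] = o
                self.oA[a][i] += (1.0 / p.tau_adapt) * (-self.oA[a][i] + o)
                self.oE[a][i] += (1.0 / p.tau_favg) * (-self.oE[a][i] + o)
            for i in range(self.n_cells):
                c = 0.0
                for j in self.pool[i]:
                    c += self.O_e[a][j]
                v = self.V_i[a][i] + (1.0 / p.tau_inh) * (-self.V_i[a][i] + p.k1 * c)
                self.V_i[a][i] = v
                self.O_i[a][i] = v if v > 0.0 else 0.0
            ssum = 0.0
            for i in range(self.n_cells):
                ssum += self.O_e[a][i]
            self.g[a] += (1.0 / gp.tau_glob) * (-self.g[a] + kG * gp.input_scale * ssum)

    def plasticity_step(self):
        pp = self.pp
        for s, d, rows in self.blocks:
            for i in range(self.n_cells):
                pre_on = self.oE[s][i] >= pp.theta_pre
                new_row = []
                for j, w in rows[i]:
                    v = self.V_e[d][j]
                    dw = 0.0
                    if v >= pp.theta_plus:
                        dw = pp.delta if pre_on else -pp.delta
                    elif pp.theta_minus <= v and pre_on:
                        dw = -pp.delta
                    new_row.append((j, min(max(w + dw, 0.0), pp.w_max)))
                rows[i][:] = new_row

    def weights_array(self, pack):
        """Flatten weights in the pack's storage order for comparison."""
        out = np.empty(pack.nnz)
        for b, (s, d, rows) in enumerate(self.blocks):
            for i in range(self.n_cells):
                lo = int(pack.indptr[b, i])
                for k, (j, w) in enumerate(rows[i]):
                    out[lo + k] = w
        return out


def hebbian_case_oracle(w, pre_rate, post_v, theta_pre, theta_plus, theta_minus, delta, w_max):
    """Direct transcription of the three-case learning rule."""
    if pre_rate >= theta_pre and post_v >= theta_plus:
        dw = delta
    elif pre_rate >= theta_pre and theta_minus <= post_v < theta_plus:
        dw = -delta
    elif pre_rate < theta_pre and post_v >= theta_plus:
        dw = -delta
    else:
        dw = 0.0
    return min(max(w + dw, 0.0), w_max)


def ca_threshold_oracle(rates, gamma):
    """Exhaustive per-cell scan for the gamma-relative CA threshold."""
    out = []
    for a in range(rates.shape[0]):
        m = 0.0
        for x in rates[a]:
            m = max(m, float(x))
        cells = []
        if m > 0.0:
            for i, x in enumerate(rates[a]):
                if float(x) >= gamma * m:
                    cells.append(i)
        out.append(cells)
    return out


def linking_fraction_oracle(word_cells, ref_cells, areas):
    """Brute-force set-intersection count over the associated areas."""
    hit = tot = 0
    for a in areas:
        ref = set(ref_cells.get(a, ()))
        tot += len(ref)
        for c in word_cells.get(a, ()):
            if c in ref:
                hit += 1
    return hit, tot
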