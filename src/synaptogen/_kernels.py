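"""Compiled inner loops.

Two hot paths are JIT-compiled: without-replacement sampling of the active
lines of every pattern in a block, and the sequential per-pattern
presentation loop (excitation -> fire -> weight update).  Both consume
pre-drawn uniforms from a numpy Generator so the random stream — and hence
every simulation — is reproducible independently of the compiled code.

The elementary operations in :mod:`synaptogen.dynamics` are the readable
reference implementations of the same arithmetic; a test holds the two
routes together.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _partial_shuffle_pick(pool, u, out):
    # partial Fisher-Yates: after k swaps the first k entries are a uniform
    # without-replacement sample of the pool
    k = out.shape[0]
    n = pool.shape[0]
    for j in range(k):
        r = j + int(u[j] * (n - j))
        tmp = pool[j]
        pool[j] = pool[r]
        pool[r] = tmp
        out[j] = pool[j]


@njit(cache=True)
def sample_active_indices(labels, membership, complements, u_keep, u_on):
    """Active line indices for each pattern of a block.

    labels : (n_t,) generating category per pattern
    membership : (n_cat, L) prototype line indices
    complements : (n_cat, n - L) non-prototype line indices
    u_keep, u_on : (n_t, keep) and (n_t, on) uniforms
    returns (n_t, keep + on) int32
    """
    n_t = labels.shape[0]
    keep = u_keep.shape[1]
    on = u_on.shape[1]
    out = np.empty((n_t, keep + on), dtype=np.int32)
    proto_scratch = np.empty(membership.shape[1], dtype=np.int32)
    comp_scratch = np.empty(complements.shape[1], dtype=np.int32)
    for t in range(n_t):
        c = labels[t]
        proto_scratch[:] = membership[c]
        _partial_shuffle_pick(proto_scratch, u_keep[t], out[t, :keep])
        if on > 0:
            comp_scratch[:] = complements[c]
            _partial_shuffle_pick(comp_scratch, u_on[t], out[t, keep:])
    return out


@njit(cache=True)
def present_block(active, w, syn_idx, e_x, eps, theta, x_scratch):
    """Present one block of patterns to one neuron, modifying weights in place.

    active : (n_t, a) active line indices per pattern
    w : (n_inputs,) dense weights (zero where no synapse exists)
    syn_idx : (m,) sorted indices of existing synapses; fixed within a block
    e_x : (n_inputs,) per-line activation expectations
    x_scratch : (n_inputs,) zeroed float64 work array (returned zeroed)

    Per time-step: excitation y = sum of weights on active existing synapses;
    the neuron fires when y strictly exceeds theta; every existing synapse is
    then nudged by eps * (x_i - E[x_i] - w_i) * y, floored at zero.
    Returns the number of firings in the block.
    """
    n_t, a = active.shape
    m = syn_idx.shape[0]
    n_fire = 0
    for t in range(n_t):
        for j in range(a):
            x_scratch[active[t, j]] = 1.0
        y = 0.0
        for j in range(m):
            i = syn_idx[j]
            y += w[i] * x_scratch[i]
        if y > theta:
            n_fire += 1
        if y > 0.0:
            for j in range(m):
                i = syn_idx[j]
                nw = w[i] + eps * (x_scratch[i] - e_x[i] - w[i]) * y
                w[i] = nw if nw > 0.0 else 0.0
        for j in range(a):
            x_scratch[active[t, j]] = 0.0
    return n_fire
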