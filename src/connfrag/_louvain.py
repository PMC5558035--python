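"""Numba kernels: stochastic greedy modularity optimization and Q evaluation.

The optimizer is a multilevel ("Louvain-style") greedy maximizer of weighted
modularity with resolution parameter gamma.  Each run visits nodes in a
freshly shuffled order, moves a node to the neighboring community with the
largest modularity gain (ties broken uniformly at random), and aggregates
communities into super-nodes when no single-node move improves Q, repeating
until the partition is stable under both single-node moves and community
merges.  Dense float64 matrices in, one community label per original node
out.

Conventions: ``m2`` is the sum of the full symmetric matrix (every edge
counted twice); on aggregated matrices the diagonal carries the full
internal weight of a super-node, keeping ``m2`` and row sums invariant, so

    Q = sum_c [ W_in(c)/m2 - gamma * (K_c/m2)^2 ]

matches the classical e_ii - gamma*a_i^2 form at every level.
"""

import numpy as np
from numba import njit

_GAIN_TOL = 1e-12


@njit(cache=True)
def _shuffle(order):
    for t in range(order.shape[0] - 1, 0, -1):
        s = np.random.randint(0, t + 1)
        tmp = order[t]
        order[t] = order[s]
        order[s] = tmp


@njit(cache=True)
def _local_move(A, comm, size, K, k, gamma, m2):
    """Greedy single-node moves until convergence. Mutates comm/size/K.

    Gains are measured relative to the node sitting alone in an empty
    community, which cancels all placement-independent terms.
    """
    n = A.shape[0]
    order = np.arange(n)
    gains = np.empty(n + 1)
    cands = np.empty(n + 1, dtype=np.int64)
    w2c = np.empty(n)
    improved = False
    moved = True
    while moved:
        moved = False
        _shuffle(order)
        for oi in range(n):
            i = order[oi]
            ci = comm[i]
            for c in range(n):
                w2c[c] = 0.0
            for j in range(n):
                if j != i:
                    w = A[i, j]
                    if w != 0.0:
                        w2c[comm[j]] += w
            # detach i from its community
            K[ci] -= k[i]
            size[ci] -= 1
            coef = 2.0 * gamma * k[i] / (m2 * m2)
            # candidate 0: a singleton community (gain 0 by construction)
            cands[0] = -1
            gains[0] = 0.0
            ncand = 1
            stay_gain = 0.0
            best = 0.0
            for c in range(n):
                if w2c[c] > 0.0 or (c == ci and size[c] > 0):
                    g = 2.0 * w2c[c] / m2 - coef * K[c]
                    cands[ncand] = c
                    gains[ncand] = g
                    ncand += 1
                    if c == ci:
                        stay_gain = g
                    if g > best:
                        best = g
            if size[ci] == 0:
                # old community is now empty: staying == singleton
                stay_gain = 0.0
            if best <= stay_gain + _GAIN_TOL:
                # no strict improvement over staying put
                target = ci
            else:
                nbest = 0
                for t in range(ncand):
                    if gains[t] >= best - _GAIN_TOL:
                        cands[nbest] = cands[t]
                        nbest += 1
                pick = cands[np.random.randint(0, nbest)]
                if pick == -1:
                    # find an empty community slot (one always exists:
                    # there are n labels and at most n-1 occupied now)
                    target = ci
                    for c in range(n):
                        if size[c] == 0:
                            target = c
                            break
                else:
                    target = pick
                if target != ci:
                    moved = True
                    improved = True
            comm[i] = target
            K[target] += k[i]
            size[target] += 1
    return improved


@njit(cache=True)
def louvain_labels(W, gamma, seed):
    """One stochastic optimization run; returns a label per original node."""
    np.random.seed(seed)
    n0 = W.shape[0]
    m2 = 0.0
    for i in range(n0):
        for j in range(n0):
            m2 += W[i, j]
    node_comm = np.arange(n0)
    A = W.copy()
    while True:
        n = A.shape[0]
        comm = np.arange(n)
        size = np.ones(n, dtype=np.int64)
        k = np.empty(n)
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += A[i, j]
            k[i] = s
        K = k.copy()
        improved = _local_move(A, comm, size, K, k, gamma, m2)
        # compact labels (order of community index first occurrence)
        remap = np.full(n, -1, dtype=np.int64)
        nc = 0
        for i in range(n):
            if remap[comm[i]] < 0:
                remap[comm[i]] = nc
                nc += 1
        for v in range(n0):
            node_comm[v] = remap[comm[node_comm[v]]]
        if not improved or nc == n:
            return node_comm
        B = np.zeros((nc, nc))
        for i in range(n):
            ri = remap[comm[i]]
            for j in range(n):
                B[ri, remap[comm[j]]] += A[i, j]
        A = B


@njit(cache=True)
def consensus_kernel(W, gamma, seeds):
    """Run one optimization per seed; accumulate co-assignment counts.

    Returns (counts, qs, best_labels) where counts[i, j] is the number of
    runs placing i and j in the same module and best_labels the partition
    of the maximal-Q run (first encountered on ties).
    """
    n = W.shape[0]
    n_runs = seeds.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    qs = np.empty(n_runs)
    best_labels = np.empty(n, dtype=np.int64)
    best_q = -1e300
    for r in range(n_runs):
        labels = louvain_labels(W, gamma, seeds[r])
        q = modularity_value(W, labels, gamma)
        qs[r] = q
        for i in range(n):
            li = labels[i]
            for j in range(n):
                if li == labels[j]:
                    counts[i, j] += 1
        if q > best_q:
            best_q = q
            best_labels[:] = labels
    return counts, qs, best_labels


@njit(cache=True)
def modularity_value(W, labels, gamma):
    """Q of a labelled partition of W (labels need not be compact)."""
    n = W.shape[0]
    nlab = 0
    for i in range(n):
        if labels[i] + 1 > nlab:
            nlab = labels[i] + 1
    w_in = np.zeros(nlab)
    K = np.zeros(nlab)
    m2 = 0.0
    for i in range(n):
        li = labels[i]
        for j in range(n):
            w = W[i, j]
            m2 += w
            K[li] += w
            if li == labels[j]:
                w_in[li] += w
    q = 0.0
    for c in range(nlab):
        q += w_in[c] / m2 - gamma * (K[c] / m2) ** 2
    return q
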