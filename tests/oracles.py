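"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (restricted
growth strings for set partitions, a direct evaluation of the modularity
sum) so that it shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of n items as label vectors (restricted growth)."""
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)
    yield labels.copy()
    while True:
        # increment the rightmost position that can still grow
        i = n - 1
        while i > 0 and labels[i] >= maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxes[j] = maxes[i]
        yield labels.copy()


def q_of_labels(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Modularity by direct summation: Q = sum_c (e_cc - gamma * a_c^2)."""
    m2 = W.sum()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = W[np.ix_(mask, mask)].sum() / m2
        a_c = W[mask].sum() / m2
        q += e_cc - gamma * a_c**2
    return q


def exhaustive_max_q(W: np.ndarray, gamma: float = 1.0) -> float:
    """Global modularity optimum by enumerating every partition (n <= ~10)."""
    n = W.shape[0]
    best = -np.inf
    for labels in set_partitions(n):
        q = q_of_labels(W, labels, gamma)
        if q > best:
            best = q
    return best


def random_weighted_graph(
    rng: np.random.Generator, n: int, p_edge: float = 0.6
) -> np.ndarray:
    """A connected-ish random weighted graph with at least one edge."""
    while True:
        adj = np.triu(rng.random((n, n)) < p_edge, k=1)
        w = np.zeros((n, n))
        w[adj] = rng.uniform(0.2, 2.0, int(adj.sum()))
        w = w + w.T
        if w.sum() > 0:
            return w
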