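"""Modularity, stochastic community detection, consensus affiliation and
fragmentation indices.

The modularity of a partition of a weighted network is

    Q = sum_i (e_ii - gamma * a_i^2)

where e_ii is the fraction of total edge weight internal to module i, a_i
the fraction of edge weight incident to module i, and gamma the resolution
(default 1, at which the expression is the classical Newman form).  Because
the optimizer is stochastic, a single partition is an unstable summary;
repeating the optimization ``n_runs`` times yields a community affiliation
matrix A whose (i, j) entry is the fraction of runs co-assigning regions i
and j.  The mean of A's strict upper triangle is the community affiliation
index C — a stability/integration summary of the hemisphere — and the
fragmentation index contrasts the two hemispheres:

    FI = (RH_C - LH_C) / (RH_C + LH_C)

Positive FI means the left hemisphere's community structure is more
fragmented (less stable) than the right's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._louvain import consensus_kernel, louvain_labels
from .io import Connectome

__all__ = [
    "Partition",
    "ModularityDecomposition",
    "AffiliationResult",
    "FragmentationResult",
    "UndefinedModularityError",
    "modularity_score",
    "detect_communities",
    "consensus_affiliation",
    "affiliation_index",
    "fragmentation_index",
    "module_count",
]


class UndefinedModularityError(ValueError):
    """Modularity is undefined on a network with zero total weight."""


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to 0..m-1 in order of first appearance."""
    raw = np.asarray(raw, dtype=np.int64)
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        key = int(lab)
        if key not in mapping:
            mapping[key] = len(mapping)
        out[i] = mapping[key]
    return out


@dataclass(frozen=True)
class Partition:
    """Community assignment: one nonnegative integer label per region.

    Labels are canonicalized to 0..m-1 in first-appearance order on
    construction, so two partitions are equal iff they group identically.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer array")
        if labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", _canonical_labels(labels))

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, label: int) -> np.ndarray:
        if not 0 <= label < self.n_modules:
            raise KeyError(f"unknown module label {label}")
        return np.flatnonzero(self.labels == label)

    def as_sets(self) -> list[set[int]]:
        return [set(self.members(c).tolist()) for c in range(self.n_modules)]

    @classmethod
    def from_sets(cls, sets, n_regions: int | None = None) -> "Partition":
        sets = [set(s) for s in sets]
        size = max((max(s) for s in sets if s), default=-1) + 1
        if n_regions is not None:
            size = max(size, n_regions)
        labels = np.full(size, -1, dtype=np.int64)
        for lab, s in enumerate(sets):
            for i in s:
                if labels[i] != -1:
                    raise ValueError(f"region {i} assigned to multiple modules")
                labels[i] = lab
        if (labels < 0).any():
            raise ValueError("every region must be assigned to a module")
        return cls(labels)


@dataclass(frozen=True)
class ModularityDecomposition:
    """Q together with the module-level edge-weight fractions behind it.

    ``e_pair[s, t]`` is the fraction of total edge weight running between
    modules s and t (diagonal: internal weight); rows sum to the incident
    fractions a.  All fractions together sum to one.
    """

    e_pair: np.ndarray
    gamma: float
    Q: float

    @property
    def m(self) -> int:
        return int(self.e_pair.shape[0])

    @property
    def e(self) -> dict[int, float]:
        return {c: float(self.e_pair[c, c]) for c in range(self.m)}

    @property
    def a(self) -> dict[int, float]:
        sums = self.e_pair.sum(axis=1)
        return {c: float(sums[c]) for c in range(self.m)}


@dataclass(frozen=True)
class AffiliationResult:
    """Consensus of repeated stochastic partitionings of one network.

    ``A[i, j]`` is the fraction of the ``n_runs`` optimizations placing
    regions i and j in the same module (diagonal fixed at 1).
    ``best_partition`` is the run with maximal Q (first encountered on ties).
    """

    region_ids: tuple[str, ...]
    A: np.ndarray
    n_runs: int
    best_partition: Partition
    Q_best: float
    Q_mean: float
    Q_sd: float

    def index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region_id {region_id!r}") from None


@dataclass(frozen=True)
class FragmentationResult:
    """Right/left contrast of community affiliation indices."""

    rh_c: float
    lh_c: float
    fi: float


def _as_weights(c: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(c, Connectome):
        return c.weights
    return np.ascontiguousarray(np.asarray(c, dtype=np.float64))


def modularity_score(
    c: Connectome | np.ndarray, p: Partition, gamma: float = 1.0
) -> ModularityDecomposition:
    """Evaluate Q (and its module decomposition) for a given partition."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    W = _as_weights(c)
    n = W.shape[0]
    if len(p) != n:
        raise ValueError(
            f"partition covers {len(p)} regions but the network has {n}"
        )
    m2 = W.sum()
    if m2 <= 0:
        raise UndefinedModularityError("total edge weight is zero")
    m = p.n_modules
    onehot = (p.labels[None, :] == np.arange(m)[:, None]).astype(np.float64)
    e_pair = onehot @ W @ onehot.T / m2
    a = e_pair.sum(axis=1)
    Q = float(np.trace(e_pair) - gamma * (a**2).sum())
    return ModularityDecomposition(e_pair=e_pair, gamma=float(gamma), Q=Q)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def detect_communities(
    c: Connectome | np.ndarray, gamma: float = 1.0, rng=None
) -> Partition:
    """One stochastic modularity-maximization run.

    Returns a partition that is a local optimum under single-node moves and
    community merges.  Different random states explore different optima;
    the same seeded generator state reproduces the same partition.
    Zero-strength regions come back as singleton modules.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    W = _as_weights(c)
    if W.sum() <= 0:
        raise UndefinedModularityError("total edge weight is zero")
    rng = _as_rng(rng)
    seed = int(rng.integers(0, 2**31))
    return Partition(louvain_labels(W, float(gamma), seed))


def consensus_affiliation(
    c: Connectome | np.ndarray,
    n_runs: int = 100,
    gamma: float = 1.0,
    rng=None,
) -> AffiliationResult:
    """Repeat detection ``n_runs`` times and build the affiliation matrix."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    W = _as_weights(c)
    if W.sum() <= 0:
        raise UndefinedModularityError("total edge weight is zero")
    rng = _as_rng(rng)
    region_ids = (
        c.region_ids
        if isinstance(c, Connectome)
        else tuple(str(i) for i in range(W.shape[0]))
    )
    n = W.shape[0]
    seeds = rng.integers(0, 2**31, size=n_runs, dtype=np.int64)
    counts, qs, best_labels = consensus_kernel(W, float(gamma), seeds)
    best_q = qs.max()
    A = counts / float(n_runs)
    np.fill_diagonal(A, 1.0)
    return AffiliationResult(
        region_ids=tuple(region_ids),
        A=A,
        n_runs=int(n_runs),
        best_partition=Partition(best_labels),
        Q_best=float(best_q),
        Q_mean=float(qs.mean()),
        Q_sd=float(qs.std(ddof=1)) if n_runs > 1 else 0.0,
    )


def affiliation_index(a: AffiliationResult | np.ndarray) -> float:
    """Community affiliation index C: mean of A's strict upper triangle."""
    A = a.A if isinstance(a, AffiliationResult) else np.asarray(a, dtype=float)
    n = A.shape[0]
    if n < 2:
        raise ValueError("affiliation index needs at least 2 regions")
    iu = np.triu_indices(n, k=1)
    return float(A[iu].mean())


def fragmentation_index(rh_c: float, lh_c: float) -> FragmentationResult:
    """FI = (RH_C - LH_C) / (RH_C + LH_C).

    Positive when the left hemisphere's community structure is the more
    fragmented one (lower affiliation index).
    """
    if rh_c < 0 or lh_c < 0:
        raise ValueError("affiliation indices must be nonnegative")
    if rh_c + lh_c == 0:
        raise ValueError("fragmentation index undefined: both indices are zero")
    fi = (rh_c - lh_c) / (rh_c + lh_c)
    return FragmentationResult(rh_c=float(rh_c), lh_c=float(lh_c), fi=float(fi))


def module_count(p: Partition) -> int:
    """Number of distinct modules (singleton isolates included)."""
    return p.n_modules
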