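"""Node- and module-level network metrics.

Covers the per-region quantities the cohort analysis consumes: node
strength (sum of incident weights), rich-club hub identification against a
degree-preserving randomized null, the Guimera-Amaral participation
coefficient, within-module ("intra-modular") degree, module size, and the
per-region co-membership frequency read off a consensus affiliation matrix.

Hub detection follows the rich-club logic: compute the binary rich-club
coefficient

    phi(k) = 2 * E_k / (N_k * (N_k - 1))

over the subgraph of nodes with degree > k, normalize by the mean phi of
``n_null`` degree-preserving rewirings (Maslov-Sneppen double-edge swaps on
the binarized graph), and call hubs the nodes above the smallest threshold
k* at which the normalized coefficient exceeds 1 with empirical null
exceedance p < 0.05.  Degree here is binary degree on the support of the
weight matrix; weighted strength is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .community import AffiliationResult, Partition
from .io import Connectome

__all__ = [
    "ModuleMetrics",
    "node_strength",
    "identify_hubs",
    "rich_club_profile",
    "participation_coefficient",
    "participation_coefficients",
    "intra_modular_degree",
    "module_size",
    "co_membership_frequency",
    "co_membership_frequencies",
    "node_metrics_table",
]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _rewire_adjacency(edges, n, nswap, seed):
    """Degree-preserving randomization by double-edge swaps.

    ``edges`` is an (m, 2) int array of an undirected simple graph; a copy
    is rewired in place.  Returns the boolean adjacency of the randomized
    graph.  Swaps producing self-loops or multi-edges are rejected.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    adj = np.zeros((n, n), dtype=np.bool_)
    for e in range(m):
        u, v = edges[e, 0], edges[e, 1]
        adj[u, v] = True
        adj[v, u] = True
    swaps = 0
    tries = 0
    max_tries = 100 * nswap + 100
    while swaps < nswap and tries < max_tries:
        tries += 1
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swaps += 1
    return adj


@njit(cache=True)
def _phi_curve(adj, deg):
    """Binary rich-club coefficient phi(k) for k = 0 .. max(deg)-1.

    Entries where the k-threshold subgraph has fewer than 2 nodes are NaN.
    """
    n = adj.shape[0]
    kmax = 0
    for i in range(n):
        if deg[i] > kmax:
            kmax = deg[i]
    order = np.argsort(-deg)
    # prefix[r]: number of edges among the r highest-degree nodes
    prefix = np.zeros(n + 1)
    for r in range(1, n + 1):
        v = order[r - 1]
        add = 0.0
        for t in range(r - 1):
            if adj[v, order[t]]:
                add += 1.0
        prefix[r] = prefix[r - 1] + add
    phi = np.full(kmax, np.nan) if kmax > 0 else np.full(1, np.nan)
    for k in range(kmax):
        nk = 0
        for i in range(n):
            if deg[i] > k:
                nk += 1
        if nk >= 2:
            phi[k] = 2.0 * prefix[nk] / (nk * (nk - 1.0))
    return phi


# ---------------------------------------------------------------------------
# simple node metrics


def _weights_and_ids(c: Connectome | np.ndarray):
    if isinstance(c, Connectome):
        return c.weights, list(c.region_ids)
    W = np.asarray(c, dtype=np.float64)
    return W, [str(i) for i in range(W.shape[0])]


def node_strength(c: Connectome | np.ndarray) -> pd.Series:
    """strength_i = sum_j w_ij, indexed by region id."""
    W, ids = _weights_and_ids(c)
    return pd.Series(W.sum(axis=1), index=ids, name="strength")


def _region_index(c, region) -> int:
    if isinstance(region, (int, np.integer)):
        return int(region)
    if isinstance(c, Connectome):
        return c.index(region)
    raise KeyError(f"region {region!r}: string ids need a Connectome input")


# ---------------------------------------------------------------------------
# rich-club hubs


def rich_club_profile(
    c: Connectome | np.ndarray, n_null: int = 100, rng=None
) -> pd.DataFrame:
    """phi(k), its randomized-null mean, normalized ratio and exceedance p.

    One row per degree threshold k at which phi is defined.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    W, _ = _weights_and_ids(c)
    adj = W > 0
    np.fill_diagonal(adj, False)
    deg = adj.sum(axis=1).astype(np.int64)
    if (deg > 0).sum() < 4:
        raise ValueError("rich-club analysis needs >= 4 connected regions")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    iu, ju = np.where(np.triu(adj, k=1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    m = edges.shape[0]
    phi = _phi_curve(adj, deg)
    null_phi = np.empty((n_null, phi.shape[0]))
    nswap = 10 * m
    for r in range(n_null):
        seed = int(rng.integers(0, 2**31))
        radj = _rewire_adjacency(edges.copy(), adj.shape[0], nswap, seed)
        null_phi[r] = _phi_curve(radj, deg)
    # phi is NaN exactly where fewer than 2 nodes clear the threshold; the
    # null shares the degree sequence, hence the same NaN pattern
    ok = np.isfinite(phi)
    null_mean = np.full_like(phi, np.nan)
    phi_norm = np.full_like(phi, np.nan)
    p_exceed = np.full_like(phi, np.nan)
    if ok.any():
        null_ok = null_phi[:, ok]
        null_mean[ok] = null_ok.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_norm[ok] = phi[ok] / null_mean[ok]
        p_exceed[ok] = (null_ok >= phi[ok][None, :]).mean(axis=0)
    ks = np.arange(phi.shape[0])
    return pd.DataFrame(
        {
            "k": ks[ok],
            "phi": phi[ok],
            "phi_null_mean": null_mean[ok],
            "phi_norm": phi_norm[ok],
            "p_exceed": p_exceed[ok],
        }
    )


def identify_hubs(
    c: Connectome | np.ndarray,
    n_null: int = 100,
    rng=None,
    alpha: float = 0.05,
) -> set:
    """Rich-club hub set: regions with degree above the smallest threshold
    k* whose normalized rich-club coefficient exceeds 1 at null-exceedance
    p < alpha.  Empty set when no threshold qualifies.
    """
    W, ids = _weights_and_ids(c)
    profile = rich_club_profile(c, n_null=n_null, rng=rng)
    hit = profile[(profile["phi_norm"] > 1.0) & (profile["p_exceed"] < alpha)]
    if hit.empty:
        return set()
    k_star = int(hit["k"].iloc[0])
    adj = W > 0
    np.fill_diagonal(adj, False)
    deg = adj.sum(axis=1)
    return {ids[i] for i in np.flatnonzero(deg > k_star)}


# ---------------------------------------------------------------------------
# module-level metrics


def participation_coefficients(
    c: Connectome | np.ndarray, p: Partition
) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s; 0 for isolated nodes."""
    W, _ = _weights_and_ids(c)
    n = W.shape[0]
    if len(p) != n:
        raise ValueError("partition does not cover the network")
    m = p.n_modules
    onehot = (p.labels[None, :] == np.arange(m)[:, None]).astype(np.float64)
    k_is = W @ onehot.T  # (n, m) weight from node i into module s
    k = k_is.sum(axis=1)
    out = np.zeros(n)
    nz = k > 0
    out[nz] = 1.0 - ((k_is[nz] / k[nz, None]) ** 2).sum(axis=1)
    return out


def participation_coefficient(
    c: Connectome | np.ndarray, p: Partition, region
) -> float:
    return float(participation_coefficients(c, p)[_region_index(c, region)])


@dataclass(frozen=True)
class ModuleMetrics:
    """Summary of one module: membership, mean within-module strength, and
    (when damage fractions are supplied) mean member damage."""

    module_label: int
    member_regions: frozenset
    intra_modular_degree_mean: float
    module_damage: float | None = None


def intra_modular_degree(
    c: Connectome | np.ndarray,
    p: Partition,
    module_label: int,
    damage: dict | None = None,
) -> ModuleMetrics:
    """Mean over module members of their within-module strength."""
    W, ids = _weights_and_ids(c)
    if len(p) != W.shape[0]:
        raise ValueError("partition does not cover the network")
    members = p.members(int(module_label))  # raises KeyError if unknown
    sub = W[np.ix_(members, members)]
    mean_within = float(sub.sum(axis=1).mean())
    member_ids = frozenset(ids[int(i)] for i in members)
    module_damage = None
    if damage is not None:
        module_damage = float(
            np.mean([damage.get(rid, 0.0) for rid in sorted(member_ids)])
        )
    return ModuleMetrics(
        module_label=int(module_label),
        member_regions=member_ids,
        intra_modular_degree_mean=mean_within,
        module_damage=module_damage,
    )


def module_size(p: Partition, region: int) -> int:
    """Cardinality of the module containing the region (by index)."""
    region = int(region)
    if not 0 <= region < len(p):
        raise KeyError(f"region index {region} not assigned in partition")
    return int((p.labels == p.labels[region]).sum())


def co_membership_frequencies(a: AffiliationResult) -> np.ndarray:
    """Per region: mean affiliation probability with every other region."""
    A = a.A
    n = A.shape[0]
    return (A.sum(axis=1) - np.diag(A)) / (n - 1)


def co_membership_frequency(a: AffiliationResult, region) -> float:
    idx = a.index(region) if isinstance(region, str) else int(region)
    return float(co_membership_frequencies(a)[idx])


def node_metrics_table(
    c: Connectome,
    affiliation: AffiliationResult,
    hubs: set | None = None,
) -> pd.DataFrame:
    """One row per region: strength, degree, hub flag, participation,
    module size (best partition) and co-membership frequency."""
    W = c.weights
    part = affiliation.best_partition
    adj = W > 0
    np.fill_diagonal(adj, False)
    sizes = np.array([module_size(part, i) for i in range(len(part))])
    return pd.DataFrame(
        {
            "region_id": list(c.region_ids),
            "strength": W.sum(axis=1),
            "degree": adj.sum(axis=1),
            "is_hub": [rid in (hubs or set()) for rid in c.region_ids],
            "participation": participation_coefficients(c, part),
            "module_size": sizes,
            "co_membership_freq": co_membership_frequencies(affiliation),
        }
    )
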