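"""Coupled phase-oscillator simulator emitting time-evolving similarity networks.

Oscillators follow d theta_i/dt = omega_i + kappa sum_j C_ij sin(theta_j -
theta_i) on a designed binary support C, integrated by forward Euler with one
network snapshot per step.  The emitted weights are A_ij(t) =
<|cos(theta_i - theta_j)|>, averaged over independent replicates with random
initial phases.  Natural frequencies omega_i ~ Normal(0, 1) are drawn once
per replicate and held across stable periods; the support matrix switches at
the planted epochs while phases carry over.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from netphase.types import InvalidInputError, TemporalNetwork, Timeline, WeightedNetwork

__all__ = [
    "gen_support",
    "gen_hierarchical_support",
    "integrate",
    "similarity_network",
    "build_kuramoto_scenario",
    "KURAMOTO_PRESETS",
]


def _cross_matching(membership, rng):
    """Random perfect matching with partners in different communities.

    Built by shuffling and pairing consecutively, then repairing same-
    community pairs by swapping members with other pairs.
    """
    membership = np.asarray(membership)
    n = membership.size
    if n % 2:
        raise InvalidInputError("cross-matching requires an even node count")
    counts = np.bincount(membership - membership.min())
    if counts.max() > n // 2:
        raise InvalidInputError("largest community exceeds half the nodes; matching infeasible")
    perm = rng.permutation(n)
    pairs = [[perm[2 * i], perm[2 * i + 1]] for i in range(n // 2)]
    for _ in range(10000):
        bad = [i for i, (u, v) in enumerate(pairs) if membership[u] == membership[v]]
        if not bad:
            return [(int(u), int(v)) for u, v in pairs]
        i = bad[0]
        u, v = pairs[i]
        j = int(rng.integers(len(pairs)))
        if j == i:
            continue
        x, y = pairs[j]
        # swap v <-> y when it fixes pair i without breaking pair j
        if membership[u] != membership[y] and membership[x] != membership[v]:
            pairs[i][1], pairs[j][1] = y, v
    raise RuntimeError("cross-matching repair did not converge")


def _regular_avoiding(n, d, forbidden, rng):
    """Random d-regular simple graph on n nodes avoiding ``forbidden(u, v)``
    edges, via double-edge-swap repair of a random regular graph."""
    if d >= n:
        raise InvalidInputError("degree must be < n")
    G = nx.random_regular_graph(d, n, seed=int(rng.integers(2**31)))
    edges = {tuple(sorted(e)) for e in G.edges()}
    for _ in range(200000):
        bad = [e for e in edges if forbidden(*e)]
        if not bad:
            return edges
        u, v = bad[0]
        others = list(edges)
        x, y = others[int(rng.integers(len(others)))]
        if len({u, v, x, y}) < 4:
            continue
        e1, e2 = tuple(sorted((u, x))), tuple(sorted((v, y)))
        if e1 in edges or e2 in edges or forbidden(*e1) or forbidden(*e2):
            # try the other orientation
            e1, e2 = tuple(sorted((u, y))), tuple(sorted((v, x)))
            if e1 in edges or e2 in edges or forbidden(*e1) or forbidden(*e2):
                continue
            x, y = y, x
        edges.discard((u, v) if u < v else (v, u))
        edges.discard(tuple(sorted((x, y))))
        edges.add(e1)
        edges.add(e2)
    raise RuntimeError("regular-graph repair did not converge")


def gen_support(membership, rng, in_frac_num=14, in_frac_den=16, out_degree=1):
    """Binary symmetric support with exact per-node degree constraints.

    Each node of community k (size N_k) gets exactly ``in_frac_num * N_k /
    in_frac_den`` connections inside its community and ``out_degree``
    connections outside.  Degrees must come out integral and realizable.
    """
    membership = np.asarray(membership, dtype=int)
    n = membership.size
    C = np.zeros((n, n))
    for k in np.unique(membership):
        idx = np.flatnonzero(membership == k)
        nk = len(idx)
        d_num = in_frac_num * nk
        if d_num % in_frac_den:
            raise InvalidInputError(
                f"community {k}: in-degree {in_frac_num}*{nk}/{in_frac_den} is not an integer"
            )
        d = d_num // in_frac_den
        if d >= nk or (d * nk) % 2:
            raise InvalidInputError(f"community {k}: in-degree {d} unrealizable on {nk} nodes")
        if d == nk - 1:
            block = {(i, j) for i in range(nk) for j in range(i + 1, nk)}
        elif d > (nk - 1) // 2:
            # dense regular graphs are pathological for the pairing model:
            # draw the sparse complement and invert it
            G = nx.random_regular_graph(nk - 1 - d, nk, seed=int(rng.integers(2**31)))
            comp = {tuple(sorted(e)) for e in G.edges()}
            block = {
                (i, j)
                for i in range(nk)
                for j in range(i + 1, nk)
                if (i, j) not in comp
            }
        else:
            G = nx.random_regular_graph(d, nk, seed=int(rng.integers(2**31)))
            block = {tuple(sorted(e)) for e in G.edges()}
        for i, j in block:
            C[idx[i], idx[j]] = C[idx[j], idx[i]] = 1.0
    if out_degree == 1:
        for u, v in _cross_matching(membership, rng):
            C[u, v] = C[v, u] = 1.0
    elif out_degree != 0:
        raise InvalidInputError("only out_degree in {0, 1} is supported")
    return C


def gen_hierarchical_support(n=256, n_level1=16, n_level2=4, rng=None):
    """Two-level support: per node, 15 connections inside its 16-node
    first-level community (complete block), 3 inside its second-level group
    but outside the first level, and 1 outside both levels."""
    rng = rng if rng is not None else np.random.default_rng()
    size1 = n // n_level1
    size2 = n // n_level2
    lvl1 = np.repeat(np.arange(n_level1), size1)
    lvl2 = np.repeat(np.arange(n_level2), size2)
    C = np.zeros((n, n))
    # level 1: complete 16-blocks (15-regular)
    for k in range(n_level1):
        idx = np.flatnonzero(lvl1 == k)
        C[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(C, 0.0)
    # level 2: 3-regular inside the 64-group, avoiding own 16-block
    for g in range(n_level2):
        idx = np.flatnonzero(lvl2 == g)
        local_lvl1 = lvl1[idx]
        edges = _regular_avoiding(
            len(idx), 3, lambda u, v: local_lvl1[u] == local_lvl1[v], rng
        )
        for i, j in edges:
            C[idx[i], idx[j]] = C[idx[j], idx[i]] = 1.0
    # 1 connection outside both levels
    for u, v in _cross_matching(lvl2, rng):
        C[u, v] = C[v, u] = 1.0
    return C, lvl1, lvl2


def integrate(C, omega, theta0, kappa, tau, steps):
    """Forward-Euler trajectory; row s holds theta after s+1 steps.

    theta <- theta + tau * (omega + kappa * sum_j C_ij sin(theta_j - theta_i))
    """
    if tau <= 0:
        raise InvalidInputError("step size must be positive")
    theta = np.asarray(theta0, dtype=float).copy()
    omega = np.asarray(omega, dtype=float)
    out = np.empty((steps, theta.size))
    for s in range(steps):
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        coupling = cos_t * (C @ sin_t) - sin_t * (C @ cos_t)
        theta = theta + tau * (omega + kappa * coupling)
        out[s] = theta
    return out


def similarity_network(thetas) -> np.ndarray:
    """A_ij = mean over replicates of |cos(theta_i - theta_j)|.

    ``thetas`` is an (R, N) array of phase vectors, one row per replicate.
    The result is symmetric with unit diagonal and entries in [0, 1].
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    R, n = thetas.shape
    A = np.zeros((n, n))
    for r in range(R):
        c, s = np.cos(thetas[r]), np.sin(thetas[r])
        A += np.abs(np.outer(c, c) + np.outer(s, s))
    A /= R
    return (A + A.T) / 2.0


def _four_period_memberships():
    m1 = np.repeat(np.arange(16), 16)
    merge2 = {1: 0, 2: 0, 3: 0, 5: 4, 6: 4, 8: 7, 9: 7, 11: 10, 13: 12}
    m2 = np.array([merge2.get(c, c) for c in m1])
    merge3 = {14: 0, 15: 0, 10: 4}
    m3 = np.array([merge3.get(c, c) for c in m2])
    merge4 = {12: 0, 7: 4}
    m4 = np.array([merge4.get(c, c) for c in m3])
    return [m1, m2, m3, m4]


KURAMOTO_PRESETS = {
    "four-period": {
        "n": 256,
        "period_steps": [70, 70, 70, 70],
        "taus": [0.1, 0.08, 0.05, 0.02],
        "kappa": 0.25,
        "alpha_ref": 0.72,
    },
    "hierarchical": {
        "n": 256,
        "period_steps": [100],
        "taus": [0.1],
        "kappa": 0.25,
        "alpha_ref": 0.35,
    },
}


def build_kuramoto_scenario(preset: str, seed: int = 0, runs: int = 40):
    """Simulate a preset and emit the full temporal similarity network.

    Returns ``(TemporalNetwork, Timeline, info)``; phases are continuous
    across period boundaries within each replicate while the support matrix
    switches at the epochs.
    """
    if preset not in KURAMOTO_PRESETS:
        raise InvalidInputError(
            f"unknown preset {preset!r}; available: {sorted(KURAMOTO_PRESETS)}"
        )
    if runs < 1:
        raise InvalidInputError("need at least one replicate")
    p = KURAMOTO_PRESETS[preset]
    n = p["n"]
    rng_support = np.random.default_rng([int(seed), 11])
    if preset == "four-period":
        membs = _four_period_memberships()
        supports = [gen_support(m, rng_support) for m in membs]
        info_extra = {}
    else:
        C, lvl1, lvl2 = gen_hierarchical_support(n, rng=rng_support)
        membs = [lvl1]
        supports = [C]
        info_extra = {"level1": lvl1, "level2": lvl2}
    T = int(sum(p["period_steps"]))
    traj = np.empty((runs, T, n))
    for r in range(runs):
        rng_run = np.random.default_rng([int(seed), 12, r])
        omega = rng_run.normal(0.0, 1.0, n)
        theta = rng_run.uniform(0.0, 2.0 * np.pi, n)
        pos = 0
        for C_p, tau, steps in zip(supports, p["taus"], p["period_steps"]):
            # one snapshot per unit of model time; tau is the integrator
            # resolution, so a snapshot covers round(1/tau) Euler substeps
            n_sub = max(1, int(round(1.0 / tau)))
            seg = integrate(C_p, omega, theta, p["kappa"], tau, steps * n_sub)
            traj[r, pos : pos + steps] = seg[n_sub - 1 :: n_sub]
            theta = seg[-1]
            pos += steps
    node_ids = [f"o{i:03d}" for i in range(n)]
    snaps = [
        WeightedNetwork(similarity_network(traj[:, t]), node_ids=node_ids)
        for t in range(T)
    ]
    bounds = np.cumsum([0] + list(p["period_steps"]))
    segments = [
        (int(bounds[i]) + 1, int(bounds[i + 1]), membs[min(i, len(membs) - 1)].copy())
        for i in range(len(p["period_steps"]))
    ]
    epochs = [(int(b), int(b) + 1) for b in bounds[1:-1]]
    timeline = Timeline(T=T, segments=segments, epochs=epochs)
    info = {
        "preset": preset,
        "alpha": p["alpha_ref"],
        "gamma": 1.0 / np.sqrt(n),
        "kappa": p["kappa"],
        "runs": runs,
        **info_extra,
    }
    registry = {nid: i for i, nid in enumerate(node_ids)}
    return TemporalNetwork(snaps, registry=registry), timeline, info
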