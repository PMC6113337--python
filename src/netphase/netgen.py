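"""Seeded temporal-network generators with planted community timelines.

Three formation mechanisms are provided — a statistical factor model
(L = U U^T with community-aligned loadings), a binary stochastic block
model, and a weighted SBM — together with the named presets used for
validation.  Every generator samples the upper triangle (including the
diagonal) and mirrors, so all outputs are exactly symmetric, and all
randomness flows through named substreams of a single seed so that
identical calls are byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from netphase.tuning import alpha_interval
from netphase.types import InvalidInputError, TemporalNetwork, Timeline, WeightedNetwork

__all__ = [
    "FactorSpec",
    "SBMSpec",
    "WSBMSpec",
    "gen_factor_L",
    "gen_sparse_noise",
    "gen_dense_noise",
    "gen_sbm_L",
    "gen_sbm_noise",
    "gen_wsbm_L",
    "project_omega",
    "gen_sbm_A",
    "gen_wsbm_A",
    "build_scenario",
    "PRESETS",
]

# substream tags (stable across platforms: rng seeded with [seed, tag, index])
_LOADINGS, _S_SUPPORT, _S_VALUES, _DENSE, _BLOCK = 1, 2, 3, 4, 5


def _rng(seed: int, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag), int(index)])


@dataclass
class FactorSpec:
    """Factor-model parameters: community loadings in (r_in, 1), background
    in (0, r_out); sparse-noise density p_s and dense-noise amplitude r."""

    r_in: float = 0.6
    r_out: float = 0.4
    p_s: float = 0.1
    r: float = 0.1

    def __post_init__(self):
        if not (0 <= self.r_out < self.r_in <= 1):
            raise InvalidInputError("need 0 <= r_out < r_in <= 1")
        if not (0 <= self.p_s <= 1 and 0 <= self.r <= 1):
            raise InvalidInputError("p_s and r must lie in [0, 1]")


@dataclass
class SBMSpec:
    """Binary SBM: within-community Bernoulli(p_c) edges, zero between, plus
    categorical flip noise (+1/-1 w.p. noise_p each)."""

    p_c: float = 0.3
    noise_p: float = 0.05

    def __post_init__(self):
        if not (0 < self.p_c <= 1):
            raise InvalidInputError("p_c must lie in (0, 1]")
        if not (0 <= self.noise_p <= 0.5):
            raise InvalidInputError("noise_p must lie in [0, 0.5]")


@dataclass
class WSBMSpec:
    """Weighted SBM: within weights Unif(in_low, in_high), between weights
    Unif(out_low, out_high); sparse density p_s, dense amplitude r."""

    in_low: float = 0.4
    in_high: float = 1.0
    out_low: float = 0.0
    out_high: float = 0.6
    p_s: float = 0.1
    r: float = 0.1

    def __post_init__(self):
        if (self.in_low + self.in_high) / 2 <= (self.out_low + self.out_high) / 2:
            raise InvalidInputError("within-weight mean must dominate between-weight mean")

    @classmethod
    def from_ub(cls, ub: float, p_s: float = 0.0, r: float = 0.0) -> "WSBMSpec":
        """Signal-strength parameterization L_in ~ Unif(1-ub, 1), L_out ~ Unif(0, ub)."""
        return cls(in_low=1.0 - ub, in_high=1.0, out_low=0.0, out_high=ub, p_s=p_s, r=r)


def _sym_iid(n: int, draw) -> np.ndarray:
    """Symmetric matrix with iid upper-triangle (incl. diagonal) entries."""
    iu = np.triu_indices(n)
    M = np.zeros((n, n))
    M[iu] = draw(len(iu[0]))
    return M + np.triu(M, 1).T


def gen_factor_L(membership, spec: FactorSpec, rng: np.random.Generator) -> np.ndarray:
    """L = U U^T with one loading column per community.

    Members of community k draw u_ik ~ Unif(r_in, 1); all other nodes
    (including outliers, label -1) draw Unif(0, r_out) in that column.
    """
    membership = np.asarray(membership, dtype=int)
    comms = sorted(c for c in np.unique(membership) if c >= 0)
    if not comms:
        raise InvalidInputError("membership defines no community")
    n = membership.size
    U = rng.uniform(0.0, spec.r_out, size=(n, len(comms)))
    for col, c in enumerate(comms):
        m = membership == c
        U[m, col] = rng.uniform(spec.r_in, 1.0, size=int(m.sum()))
    return U @ U.T


def gen_sparse_noise(n, p_s, rng_support, rng_values=None) -> np.ndarray:
    """S = S1 * S2 elementwise, S1 ~ Bernoulli(p_s), S2 ~ Unif(-1, 1),
    sampled on the upper triangle and mirrored."""
    if rng_values is None:
        rng_values = rng_support
    if p_s == 0:
        return np.zeros((n, n))
    support = _sym_iid(n, lambda m: (rng_support.random(m) < p_s).astype(float))
    values = _sym_iid(n, lambda m: rng_values.uniform(-1.0, 1.0, m))
    return support * values


def gen_dense_noise(n, r, rng) -> np.ndarray:
    """E ~ Unif(-r, r) iid on the upper triangle, mirrored."""
    if r == 0:
        return np.zeros((n, n))
    return _sym_iid(n, lambda m: rng.uniform(-r, r, m))


def gen_sbm_L(membership, p_c, rng) -> np.ndarray:
    """Binary within-community Bernoulli(p_c) block matrix (L_out = 0)."""
    membership = np.asarray(membership, dtype=int)
    n = membership.size
    same = (membership[:, None] == membership[None, :]) & (membership[:, None] >= 0)
    coins = _sym_iid(n, lambda m: (rng.random(m) < p_c).astype(float))
    return coins * same


def gen_sbm_noise(n, noise_p, rng) -> np.ndarray:
    """Categorical flip noise: +1 / -1 w.p. noise_p each, else 0."""
    def draw(m):
        u = rng.random(m)
        return np.where(u < noise_p, 1.0, np.where(u < 2 * noise_p, -1.0, 0.0))

    return _sym_iid(n, draw)


def gen_wsbm_L(membership, spec: WSBMSpec, rng) -> np.ndarray:
    """Weighted blocks: Unif(in_low, in_high) within, Unif(out_low, out_high)
    between (outlier pairs count as between)."""
    membership = np.asarray(membership, dtype=int)
    n = membership.size
    same = (membership[:, None] == membership[None, :]) & (membership[:, None] >= 0)
    w_in = _sym_iid(n, lambda m: rng.uniform(spec.in_low, spec.in_high, m))
    w_out = _sym_iid(n, lambda m: rng.uniform(spec.out_low, spec.out_high, m))
    return np.where(same, w_in, w_out)


def project_omega(X) -> np.ndarray:
    """Euclidean projection onto {X : 0 <= X_ij <= 1, X symmetric}:
    symmetrize by (X + X^T)/2 then clip to [0, 1]."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("projection input must be finite")
    return np.clip((X + X.T) / 2.0, 0.0, 1.0)


def gen_sbm_A(membership, spec: SBMSpec, seed: int, t: int = 0) -> np.ndarray:
    """One binary SBM snapshot A = P_Omega(L + S)."""
    n = np.asarray(membership).size
    L = gen_sbm_L(membership, spec.p_c, _rng(seed, _BLOCK, t))
    S = gen_sbm_noise(n, spec.noise_p, _rng(seed, _S_SUPPORT, t))
    return project_omega(L + S)


def gen_wsbm_A(membership, spec: WSBMSpec, seed: int, t: int = 0, L=None) -> np.ndarray:
    """One weighted-SBM snapshot A = P_Omega(L + S + E); pass L to hold the
    block weights fixed across a stable segment."""
    n = np.asarray(membership).size
    if L is None:
        L = gen_wsbm_L(membership, spec, _rng(seed, _BLOCK, t))
    S = gen_sparse_noise(n, spec.p_s, _rng(seed, _S_SUPPORT, t), _rng(seed, _S_VALUES, t))
    E = gen_dense_noise(n, spec.r, _rng(seed, _DENSE, t))
    return project_omega(L + S + E)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def _scale_sizes(sizes, n_scale, floor=4):
    return [max(floor, int(round(s * n_scale))) for s in sizes]


def _contiguous_membership(sizes, n_total):
    """Labels 0..K-1 over contiguous index ranges, -1 elsewhere."""
    memb = np.full(n_total, -1, dtype=int)
    pos = 0
    for k, s in enumerate(sizes):
        memb[pos : pos + s] = k
        pos += s
    return memb


def _progressive(old, new, old_pres, new_pres, step, n_steps):
    """Interim membership/presence: the first ceil(frac) changed nodes adopt
    the new state, the rest keep the old one."""
    changed = np.flatnonzero((old != new) | (old_pres != new_pres))
    n_switch = int(np.ceil(len(changed) * step / (n_steps + 1)))
    memb = old.copy()
    pres = old_pres.copy()
    sw = changed[:n_switch]
    memb[sw] = new[sw]
    pres[sw] = new_pres[sw]
    return memb, pres


class _ScenarioDef:
    """Per-segment memberships + presence, epochs, and model parameters."""

    def __init__(self, T, seg_bounds, memberships, presences, epochs, n_total):
        self.T = T
        self.seg_bounds = seg_bounds  # [(lo, hi)] closed, one per stable segment
        self.memberships = memberships
        self.presences = presences
        self.epochs = epochs
        self.n_total = n_total

    def state_at(self, t):
        """(membership, presence, segment_index_or_None) at time t."""
        for i, (lo, hi) in enumerate(self.seg_bounds):
            if lo <= t <= hi:
                return self.memberships[i], self.presences[i], i
        # interim: locate enclosing epoch
        for e, (a, b) in enumerate(self.epochs):
            if a < t < b:
                old, new = self.memberships[e], self.memberships[e + 1]
                po, pn = self.presences[e], self.presences[e + 1]
                memb, pres = _progressive(old, new, po, pn, t - a, b - a - 1)
                return memb, pres, None
        raise InvalidInputError(f"time {t} outside scenario horizon")


def _illustrative_def(n_scale=1.0, t_scale=1.0) -> _ScenarioDef:
    sizes = _scale_sizes([100, 100, 90, 90, 80, 80, 70, 70, 60, 60, 50], n_scale)
    n_out = max(4, int(round(50 * n_scale)))
    n_join = max(4, int(round(100 * n_scale)))
    n_base = sum(sizes) + n_out
    n_total = n_base + n_join

    m1 = _contiguous_membership(sizes, n_total)  # joiners absent
    p1 = np.zeros(n_total, bool)
    p1[:n_base] = True
    m2, p2 = m1.copy(), np.ones(n_total, bool)  # joiners present as outliers
    # merge 10->0, 9->1, {7,8}->6; joiners leave
    m3 = m1.copy()
    m3[m1 == 10] = 0
    m3[m1 == 9] = 1
    m3[(m1 == 7) | (m1 == 8)] = 6
    p3 = p1.copy()
    # revert to m2, then community 8 disintegrates and 1, 2 each split in two
    m4 = m2.copy()
    m4[m2 == 8] = -1
    idx1 = np.flatnonzero(m2 == 1)
    m4[idx1[len(idx1) // 2 :]] = 11
    idx2 = np.flatnonzero(m2 == 2)
    m4[idx2[len(idx2) // 2 :]] = 12
    p4 = p2.copy()

    def st(x):
        return max(2, int(round(x * t_scale)))

    T = st(200)
    epochs = [(st(30), st(30) + 1), (st(60), st(65)), (st(130), st(135))]
    seg_bounds = [
        (1, epochs[0][0]),
        (epochs[0][1], epochs[1][0]),
        (epochs[1][1], epochs[2][0]),
        (epochs[2][1], T),
    ]
    return _ScenarioDef(T, seg_bounds, [m1, m2, m3, m4], [p1, p2, p3, p4], epochs, n_total)


def _three_model_def(n_scale=1.0) -> _ScenarioDef:
    sizes = _scale_sizes([120, 100, 100, 100, 80, 80, 70, 70, 70, 60, 60], n_scale)
    n_out = max(4, int(round(90 * n_scale)))
    n_total = sum(sizes) + n_out
    m1 = _contiguous_membership(sizes, n_total)
    m2 = m1.copy()
    m2[m1 == 10] = 0
    m2[m1 == 9] = 1
    m3 = m2.copy()
    m3[(m1 == 7) | (m1 == 8)] = 6
    pres = np.ones(n_total, bool)
    return _ScenarioDef(
        30, [(1, 9), (10, 19), (20, 30)], [m1, m2, m3], [pres] * 3,
        [(9, 10), (19, 20)], n_total,
    )


def _wsbm_split_def(n_scale=1.0) -> _ScenarioDef:
    sizes = _scale_sizes([200, 150, 100, 50], n_scale)
    n_total = sum(sizes)
    m1 = _contiguous_membership(sizes, n_total)
    m2 = m1.copy()
    idx0 = np.flatnonzero(m1 == 0)
    cut = int(round(len(idx0) * 125 / 200))
    m2[idx0[cut:]] = 4  # 200 -> 125 + 75
    pres = np.ones(n_total, bool)
    return _ScenarioDef(40, [(1, 20), (21, 40)], [m1, m2], [pres] * 2, [(20, 21)], n_total)


# (definition builder, default model, reference alpha, reference N,
#  fixed gamma override or None for 1/sqrt(N), default spec)
PRESETS = {
    "illustrative": (_illustrative_def, "factor", 0.10, 1000, None, FactorSpec()),
    "three-model-factor": (_three_model_def, "factor", 0.045, 1000, None, FactorSpec(r=0.3)),
    # the binary model needs a sparsity weight well above 1/sqrt(N) or the
    # Bernoulli blocks drain into S; the tabulated sweeps go up to 0.2
    "three-model-sbm": (_three_model_def, "sbm", 0.30, 1000, 0.2, SBMSpec(p_c=0.3)),
    "three-model-wsbm": (_three_model_def, "wsbm", 0.035, 1000, None, WSBMSpec(p_s=0.1, r=0.5)),
    "wsbm-split": (_wsbm_split_def, "wsbm", 0.10, 500, None, WSBMSpec.from_ub(0.7, p_s=0.0, r=0.1)),
}


def scaled_alpha(alpha_ref: float, n_ref: int, n: int) -> float:
    """Transport a tuned alpha between network sizes along the prescribed
    search interval (both endpoints scale ~ 1/sqrt(N))."""
    return alpha_ref * alpha_interval(n)[0] / alpha_interval(n_ref)[0]


def _snapshot_matrix(model, spec, membership, seed, t, seg_idx, seg_L_cache):
    n = membership.size
    if model == "factor":
        if seg_idx is not None:
            if seg_idx not in seg_L_cache:
                seg_L_cache[seg_idx] = gen_factor_L(
                    membership, spec, _rng(seed, _LOADINGS, seg_idx)
                )
            L = seg_L_cache[seg_idx]
        else:
            L = gen_factor_L(membership, spec, _rng(seed, _LOADINGS, 1000 + t))
        S = gen_sparse_noise(
            n, spec.p_s, _rng(seed, _S_SUPPORT, t), _rng(seed, _S_VALUES, t)
        )
        E = gen_dense_noise(n, spec.r, _rng(seed, _DENSE, t))
        return project_omega(L + S + E)
    if model == "sbm":
        # the Bernoulli block draw is refreshed every t: block membership is
        # what stays fixed within a segment, and window averaging then
        # cancels the Bernoulli fluctuation (mean -> p_c blocks)
        L = gen_sbm_L(membership, spec.p_c, _rng(seed, _BLOCK, t))
        S = gen_sbm_noise(n, spec.noise_p, _rng(seed, _S_SUPPORT, t))
        return project_omega(L + S)
    if model == "wsbm":
        if seg_idx is not None:
            if seg_idx not in seg_L_cache:
                seg_L_cache[seg_idx] = gen_wsbm_L(
                    membership, spec, _rng(seed, _BLOCK, seg_idx)
                )
            L = seg_L_cache[seg_idx]
        else:
            L = gen_wsbm_L(membership, spec, _rng(seed, _BLOCK, 1000 + t))
        return gen_wsbm_A(membership, spec, seed, t, L=L)
    raise InvalidInputError(f"unknown model {model!r}")


def build_scenario(
    name: str,
    seed: int = 0,
    n_scale: float = 1.0,
    t_scale: float = 1.0,
    spec=None,
    model: str = None,
):
    """Build a preset temporal network with its planted ground truth.

    Returns ``(TemporalNetwork, Timeline, info)`` where ``info`` carries the
    suggested solver parameters (alpha transported to the generated size,
    gamma = 1/sqrt(N)) and the resolved generator spec.  Same name + seed
    yields byte-identical output.
    """
    if name not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    def_builder, default_model, alpha_ref, n_ref, gamma_fixed, default_spec = PRESETS[name]
    model = model or default_model
    spec = spec if spec is not None else default_spec
    if n_scale < 1.0:
        # variance-preserving desk-scale replication: noise singular values
        # grow ~ sqrt(N) while block signal grows ~ N, so the dense-noise
        # amplitude shrinks (and the Bernoulli edge density grows) by
        # sqrt(n_scale) to keep the published signal-to-noise ratio
        if hasattr(spec, "r") and spec.r > 0:
            spec = dataclasses.replace(spec, r=spec.r * np.sqrt(n_scale))
        if hasattr(spec, "p_c"):
            spec = dataclasses.replace(
                spec, p_c=min(0.95, spec.p_c / np.sqrt(n_scale))
            )
    if def_builder is _illustrative_def:
        sdef = def_builder(n_scale=n_scale, t_scale=t_scale)
    else:
        sdef = def_builder(n_scale=n_scale)
    node_ids = [f"n{i:04d}" for i in range(sdef.n_total)]
    registry = {nid: i for i, nid in enumerate(node_ids)}
    seg_L_cache = {}
    snaps = []
    for t in range(1, sdef.T + 1):
        memb, pres, seg_idx = sdef.state_at(t)
        idx = np.flatnonzero(pres)
        sub_memb = memb[idx]
        if seg_idx is not None and seg_idx in seg_L_cache:
            pass  # cache is keyed on the segment; presence is constant within it
        A = _snapshot_matrix(model, spec, sub_memb, seed, t, seg_idx, seg_L_cache)
        snaps.append(WeightedNetwork(A, node_ids=[node_ids[i] for i in idx]))
    timeline = Timeline(
        T=sdef.T,
        segments=[
            (lo, hi, sdef.memberships[i].copy())
            for i, (lo, hi) in enumerate(sdef.seg_bounds)
        ],
        epochs=[tuple(e) for e in sdef.epochs],
    )
    n_eff = sdef.n_total
    gamma = 1.0 / np.sqrt(n_eff) if gamma_fixed is None else float(gamma_fixed)
    info = {
        "preset": name,
        "model": model,
        "spec": spec,
        "alpha": scaled_alpha(alpha_ref, n_ref, n_eff),
        "gamma": gamma,
        "n_total": n_eff,
    }
    return TemporalNetwork(snaps, registry=registry), timeline, info
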