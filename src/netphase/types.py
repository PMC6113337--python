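"""Domain types shared across the pipeline.

A :class:`WeightedNetwork` is a single symmetric weighted snapshot; a
:class:`TemporalNetwork` is an ordered sequence of them over a global node
registry.  Node sets may grow or shrink over time; :func:`pad_to_union`
casts every snapshot to the common registry size with zero rows/columns for
absent nodes, retaining a per-time presence mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an input violates a structural precondition."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but numerically degenerate."""


@dataclass
class WeightedNetwork:
    """A symmetric weighted adjacency snapshot.

    Parameters
    ----------
    matrix : ndarray of shape (N, N)
        Symmetric weight matrix (enforced exactly on construction).
    node_ids : sequence of str, optional
        Ordered node identifiers; defaults to stringified row indices.
    """

    matrix: np.ndarray
    node_ids: list = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InvalidInputError("adjacency matrix must be square")
        n = self.matrix.shape[0]
        if n < 2:
            raise InvalidInputError("network must have at least 2 nodes")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidInputError("adjacency matrix must be finite")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise InvalidInputError("adjacency matrix must be exactly symmetric")
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(n)]
        else:
            self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise InvalidInputError("node_ids length must match matrix size")
        if len(set(self.node_ids)) != n:
            raise InvalidInputError("duplicate node ids within a snapshot")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TemporalNetwork:
    """Ordered sequence of snapshots for t = 1..T over a node registry.

    ``registry`` maps global node id -> row index used after padding.  It is
    built in first-appearance order when not supplied.
    """

    snapshots: list
    registry: dict = None
    presence: np.ndarray = None  # (T, n_max) bool, set by pad_to_union

    def __post_init__(self):
        if len(self.snapshots) < 1:
            raise InvalidInputError("temporal network needs at least one snapshot")
        if self.registry is None:
            reg = {}
            for snap in self.snapshots:
                for nid in snap.node_ids:
                    if nid not in reg:
                        reg[nid] = len(reg)
            self.registry = reg
        else:
            for snap in self.snapshots:
                missing = set(snap.node_ids) - set(self.registry)
                if missing:
                    raise InvalidInputError(
                        f"snapshot nodes not in registry: {sorted(missing)[:5]}"
                    )

    @property
    def T(self) -> int:
        return len(self.snapshots)

    @property
    def n_max(self) -> int:
        return len(self.registry)

    @property
    def node_order(self) -> list:
        order = sorted(self.registry, key=self.registry.get)
        return order

    def matrices(self) -> list:
        return [s.matrix for s in self.snapshots]


def pad_to_union(net: TemporalNetwork) -> TemporalNetwork:
    """Cast all snapshots to the registry's common size.

    Rows/columns of nodes absent at time t become all-zero; a boolean
    presence mask of shape (T, n_max) records which nodes were observed at
    each time.  Snapshots already on the full registry are re-ordered to
    registry order if needed.
    """
    n = net.n_max
    order = net.node_order
    padded = []
    presence = np.zeros((net.T, n), dtype=bool)
    for t, snap in enumerate(net.snapshots):
        idx = np.array([net.registry[nid] for nid in snap.node_ids], dtype=int)
        big = np.zeros((n, n))
        big[np.ix_(idx, idx)] = snap.matrix
        presence[t, idx] = True
        padded.append(WeightedNetwork(big, node_ids=order))
    out = TemporalNetwork(padded, registry=dict(net.registry))
    out.presence = presence
    return out


@dataclass
class SolverConfig:
    """Parameters of the per-snapshot decomposition solver.

    ``gamma`` and ``beta`` default to the standard rules 1/sqrt(N) and
    0.15 N^2 / ||A||_1 when left as None; both are resolved against the
    snapshot at solve time.
    """

    alpha: float
    gamma: float = None
    beta: float = None
    eps: float = 1e-6
    max_iter: int = 500

    def __post_init__(self):
        if self.alpha is None or self.alpha <= 0:
            raise InvalidInputError("alpha must be strictly positive")
        if self.gamma is not None and self.gamma <= 0:
            raise InvalidInputError("gamma must be strictly positive")
        if self.beta is not None and self.beta <= 0:
            raise InvalidInputError("beta must be strictly positive")
        if self.eps <= 0:
            raise InvalidInputError("eps must be strictly positive")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")


@dataclass
class Decomposition:
    """Result of decomposing one snapshot into A = L + S + E."""

    L: np.ndarray
    S: np.ndarray
    E: np.ndarray
    Lambda: np.ndarray
    iterations: int
    converged: bool
    residual: float
    singular_values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def rank(self) -> int:
        """Numerical rank of L from its (exactly thresholded) singular values."""
        if self.singular_values.size == 0:
            return 0
        s = self.singular_values
        tol = max(self.L.shape) * np.finfo(float).eps * s[0]
        return int(np.sum(s > tol))


@dataclass
class Timeline:
    """Planted ground truth for a generated scenario.

    ``segments`` is a list of ``(lo, hi, membership)`` triples with closed
    1-based intervals and membership arrays over the registry (-1 marks
    outlier or absent nodes).  ``epochs`` is a list of closed transition
    intervals [tau-, tau+]; time points strictly inside an epoch carry
    interim (mixed) structure.
    """

    T: int
    segments: list
    epochs: list

    def membership_at(self, t: int):
        for lo, hi, memb in self.segments:
            if lo <= t <= hi:
                return memb
        return None

    def segment_of(self, t: int):
        for i, (lo, hi, _) in enumerate(self.segments):
            if lo <= t <= hi:
                return i
        return None
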