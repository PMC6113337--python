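"""Reading and writing temporal networks and decomposition artifacts.

Two snapshot formats are supported: a directory of per-time Matrix Market
files (lexicographic t order, node identity = row index) and a 4-column
temporal edge-list TSV ``t<TAB>i<TAB>j<TAB>w`` with 1-based times and
undirected edges listed once.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io

from netphase.types import InvalidInputError, TemporalNetwork, WeightedNetwork

__all__ = [
    "read_temporal",
    "write_temporal",
    "write_decompositions",
    "read_low_rank",
]


class FormatError(InvalidInputError):
    pass


def _read_tsv(path: Path) -> TemporalNetwork:
    times = {}
    registry = {}
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if cols[:4] != ["t", "i", "j", "w"]:
            raise FormatError(f"{path}: expected header 't\\ti\\tj\\tw', got {cols}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            t, i, j, w = int(parts[0]), parts[1], parts[2], float(parts[3])
            if t < 1:
                raise FormatError(f"{path}:{lineno}: time indices are 1-based")
            edges = times.setdefault(t, {})
            key = (i, j) if i <= j else (j, i)
            if key in edges and edges[key] != w:
                raise FormatError(
                    f"{path}:{lineno}: conflicting weight for edge {key} at t={t}"
                )
            edges[key] = w
            for nid in (i, j):
                if nid not in registry:
                    registry[nid] = len(registry)
    if not times:
        raise FormatError(f"{path}: no edges found")
    t_seen = sorted(times)
    if t_seen != list(range(1, t_seen[-1] + 1)):
        import warnings

        warnings.warn(f"{path}: missing time indices in 1..{t_seen[-1]}", UserWarning)
    snapshots = []
    for t in t_seen:
        nodes = sorted({n for e in times[t] for n in e}, key=registry.get)
        pos = {n: k for k, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for (i, j), w in times[t].items():
            A[pos[i], pos[j]] = w
            A[pos[j], pos[i]] = w
        snapshots.append(WeightedNetwork(A, node_ids=nodes))
    return TemporalNetwork(snapshots, registry=None)


def _read_mtx_dir(path: Path) -> TemporalNetwork:
    files = sorted(path.glob("*.mtx"))
    if not files:
        raise FormatError(f"{path}: no .mtx files")
    snapshots = []
    for f in files:
        M = scipy.io.mmread(str(f))
        if hasattr(M, "toarray"):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
        M = (M + M.T) / 2.0 if not np.array_equal(M, M.T) else M
        snapshots.append(WeightedNetwork(M))
    return TemporalNetwork(snapshots, registry=None)


def read_temporal(path, fmt: str = None) -> TemporalNetwork:
    """Parse a temporal network from an mtx directory or an edge-list TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx-dir" if path.is_dir() else "tsv"
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "mtx-dir":
        return _read_mtx_dir(path)
    raise InvalidInputError(f"unknown format {fmt!r} (expected 'mtx-dir' or 'tsv')")


def write_temporal(net: TemporalNetwork, path, fmt: str = "tsv") -> None:
    """Write snapshots as TSV (upper triangle, nonzero entries once) or as a
    directory of Matrix Market files."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("t\ti\tj\tw\n")
            for t, snap in enumerate(net.snapshots, start=1):
                A = snap.matrix
                iu = np.triu_indices(A.shape[0])
                for r, c in zip(*iu):
                    if A[r, c] != 0.0:
                        fh.write(
                            f"{t}\t{snap.node_ids[r]}\t{snap.node_ids[c]}\t{A[r, c]:.17g}\n"
                        )
    elif fmt == "mtx-dir":
        path.mkdir(parents=True, exist_ok=True)
        for t, snap in enumerate(net.snapshots, start=1):
            scipy.io.mmwrite(str(path / f"A_t{t:04d}.mtx"), snap.matrix, precision=17)
    else:
        raise InvalidInputError(f"unknown format {fmt!r}")


def write_decompositions(decs, out_dir) -> None:
    """Per-time L/S/E Matrix Market files plus a JSON run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = []
    for t, d in enumerate(decs, start=1):
        for name, M in (("L", d.L), ("S", d.S), ("E", d.E)):
            scipy.io.mmwrite(str(out_dir / f"{name}_t{t:04d}.mtx"), M, precision=17)
        log.append(
            {
                "t": t,
                "iterations": d.iterations,
                "converged": bool(d.converged),
                "residual": d.residual,
                "rank": d.rank,
            }
        )
    with open(out_dir / "runlog.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)


def read_low_rank(in_dir):
    """Load the L_t*.mtx files of a decomposition directory, in t order."""
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob("L_t*.mtx"))
    if not files:
        raise FormatError(f"{in_dir}: no L_t*.mtx files")
    out = []
    for f in files:
        M = scipy.io.mmread(str(f))
        if hasattr(M, "toarray"):
            M = M.toarray()
        out.append(np.asarray(M, dtype=float))
    return out
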