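"""Reproducible validation experiments on the built-in generators.

These helpers tie the stages together for the preset scenarios: generate,
decompose, scan for epochs, cluster the detected stable segments, and score
against the planted truth.  They back both the acceptance test suite and
``scripts/acceptance.py``; network sizes can be scaled down to fit a compute
budget without changing the planted design.
"""

from __future__ import annotations

import numpy as np

from netphase import community as comm
from netphase.decompose import decompose_sequence
from netphase.kuramoto import build_kuramoto_scenario
from netphase.netgen import build_scenario
from netphase.phasescan import scan, thresholded_rank
from netphase.types import SolverConfig, pad_to_union

__all__ = [
    "decompose_scenario",
    "detect_epochs",
    "score_clusterings",
    "run_scenario",
    "run_kuramoto",
    "epochs_match",
]


def decompose_scenario(net, info, eps=1e-6, max_iter=500):
    """Pad and decompose a generated scenario with its suggested parameters."""
    padded = pad_to_union(net)
    cfg = SolverConfig(
        alpha=float(info["alpha"]), gamma=float(info["gamma"]), eps=eps, max_iter=max_iter
    )
    decs = decompose_sequence(padded, cfg, warn=False)
    return padded, decs


def detect_epochs(decs, levels=None, h=None):
    """Run the multi-level scan on the recovered low-rank components."""
    Ls = [d.L for d in decs]
    return scan(Ls, levels=levels, h=h)


def _truth_for_times(timeline, times):
    """Per-time planted membership arrays, skipping interim (epoch) times."""
    out = []
    kept = []
    for t in times:
        memb = timeline.membership_at(t)
        if memb is not None:
            out.append(memb)
            kept.append(t)
    return kept, out


def score_clusterings(padded, decs, report, timeline, seed=0):
    """Error rates of three clustering routes against the planted truth.

    Clusters (a) each detected segment's averaged low-rank matrix, (b) each
    individual L(t), (c) each raw A(t), all with k = thresholded rank of the
    segment average at the selected h.  Communities are per-segment
    entities, so each detected segment is evaluated on its own planted
    membership (interim epoch times excluded) and the per-segment results
    are aggregated: error rates are time-weighted means, recovery counts sum
    over (segment, community) pairs.
    """
    Ls = [d.L for d in decs]
    mats = padded.matrices()
    per_segment = []
    for lo, hi in report.segments:
        seg_times, seg_truth = _truth_for_times(timeline, range(lo, hi + 1))
        if not seg_times:
            continue
        L_bar = comm.segment_average(Ls, (lo, hi))
        k = max(1, thresholded_rank(L_bar, report.h_selected))
        bar_labels = comm.spectral_communities(L_bar, k, seed=seed)
        preds = {"L_bar": [], "L_t": [], "A_t": []}
        for t in seg_times:
            preds["L_bar"].append(bar_labels)
            preds["L_t"].append(comm.spectral_communities(Ls[t - 1], k, seed=seed))
            preds["A_t"].append(comm.spectral_communities(mats[t - 1], k, seed=seed))
        per_segment.append(
            {
                "segment": (lo, hi),
                "k": k,
                "n_times": len(seg_times),
                **{
                    route: comm.evaluate_detection(preds[route], seg_truth)
                    for route in preds
                },
            }
        )
    out = {"per_segment": per_segment, "k_per_segment": [s["k"] for s in per_segment]}
    total_t = sum(s["n_times"] for s in per_segment)
    for route in ("L_bar", "L_t", "A_t"):
        n_rec = sum(s[route].n_recovered for s in per_segment)
        n_pl = sum(s[route].n_planted for s in per_segment)
        err = (
            sum(s[route].error_rate * s["n_times"] for s in per_segment) / total_t
            if total_t
            else 0.0
        )
        out[route] = comm.EvaluationResult(
            recovery_rate=(n_rec / n_pl) if n_pl else 1.0,
            error_rate=err,
            per_community_accuracy={},
            n_recovered=n_rec,
            n_planted=n_pl,
        )
    return out


def run_scenario(
    name,
    seed=0,
    n_scale=1.0,
    t_scale=1.0,
    model=None,
    levels=None,
    h=None,
    eps=1e-6,
    max_iter=500,
    cluster=True,
):
    """Generate, decompose, scan and (optionally) score one preset scenario."""
    net, timeline, info = build_scenario(
        name, seed=seed, n_scale=n_scale, t_scale=t_scale, model=model
    )
    padded, decs = decompose_scenario(net, info, eps=eps, max_iter=max_iter)
    report = detect_epochs(decs, levels=levels, h=h)
    result = {
        "timeline": timeline,
        "info": info,
        "report": report,
        "decompositions": decs,
        "padded": padded,
    }
    if cluster:
        result["scores"] = score_clusterings(padded, decs, report, timeline, seed=seed)
    return result


def run_kuramoto(preset="four-period", seed=0, runs=40, levels=None, h=None,
                 eps=1e-6, max_iter=500, cluster=False):
    """Simulate a Kuramoto preset and run detection on it."""
    net, timeline, info = build_kuramoto_scenario(preset, seed=seed, runs=runs)
    padded, decs = decompose_scenario(net, info, eps=eps, max_iter=max_iter)
    report = detect_epochs(decs, levels=levels, h=h)
    result = {
        "timeline": timeline,
        "info": info,
        "report": report,
        "decompositions": decs,
        "padded": padded,
    }
    if cluster:
        result["scores"] = score_clusterings(padded, decs, report, timeline, seed=seed)
    return result


def epochs_match(detected, planted, slack=1):
    """True when detected and planted epoch intervals correspond one-to-one,
    each detected interval lying within the planted one widened by ``slack``."""
    if len(detected) != len(planted):
        return False
    for (dlo, dhi), (plo, phi) in zip(sorted(detected), sorted(planted)):
        if dlo < plo - slack or dhi > phi + slack:
            return False
    return True
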