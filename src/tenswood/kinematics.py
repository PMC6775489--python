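"""Gravibending kinematics from digitized stem traces.

Two per-trace descriptors quantify the uplifting response of a horizontally
inclined stem: the normalized lift, (Y of the primary bending point minus Y
of the base) divided by the stem's traced length, and the curvature, the
summed turning angle between subsequent segment vectors in degrees (180 deg
corresponds to a perfect half circle, a "C" shape).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import StemTrace


def arc_length(trace: StemTrace) -> float:
    seg = np.diff(trace.xy, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def normalized_lift(trace: StemTrace) -> float:
    """(Y_apex - Y_base) / polyline arc length; in [-1, 1] by the chord bound."""
    length = arc_length(trace)
    if length <= 0:
        raise ValueError("trace has zero arc length")
    return float(trace.xy[-1, 1] - trace.xy[0, 1]) / length


def curvature(trace: StemTrace, signed: bool = False) -> float:
    """Total turning angle along the trace, in degrees.

    Sums, over consecutive segment pairs, the signed angle between segment
    vectors (wrapped to (-180, 180]); returns |sum| unless ``signed``.
    """
    seg = np.diff(trace.xy, axis=0)
    if np.any(np.all(seg == 0, axis=1)):
        raise ValueError("repeated points create zero-length segments")
    headings = np.arctan2(seg[:, 1], seg[:, 0])
    turns = np.diff(headings)
    turns = (turns + math.pi) % (2 * math.pi) - math.pi
    turns[turns == -math.pi] = math.pi  # wrap to (-180, 180]
    total = math.degrees(float(np.sum(turns)))
    return total if signed else abs(total)


def series_summary(traces: list[StemTrace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day per-genotype lift/curvature means and the final-day contrast.

    Returns (summary, final_day_contrast). ``summary`` has one row per
    genotype per day with mean, SD and tree count of normalized lift and
    curvature (trees missing a day are simply absent from that day's mean).
    ``final_day_contrast`` lists, for each genotype pair (A, B) ordered by
    descending final-day mean lift, the relative lift reduction
    1 - mean_lift(B) / mean_lift(A) on the final observed day.
    """
    rows = [{
        "tree_id": t.tree_id, "genotype": t.genotype, "day": t.day,
        "lift": normalized_lift(t), "curvature": curvature(t),
    } for t in traces]
    per_tree = pd.DataFrame(rows)
    summary = (per_tree.groupby(["genotype", "day"])
               .agg(lift_mean=("lift", "mean"), lift_sd=("lift", "std"),
                    curvature_mean=("curvature", "mean"),
                    curvature_sd=("curvature", "std"),
                    n_trees=("tree_id", "nunique"))
               .reset_index())
    final_day = int(per_tree["day"].max())
    fin = (summary[summary["day"] == final_day]
           .sort_values("lift_mean", ascending=False)
           .reset_index(drop=True))
    contrasts = []
    for i in range(len(fin)):
        for j in range(len(fin)):
            if i == j:
                continue
            a, b = fin.iloc[i], fin.iloc[j]
            ref = a["lift_mean"]
            red = 1.0 - b["lift_mean"] / ref if ref != 0 else float("nan")
            contrasts.append({
                "day": final_day, "reference": a["genotype"],
                "genotype": b["genotype"],
                "relative_lift_reduction": red,
                "relative_lift_reduction_percent": 100.0 * red,
            })
    return summary, pd.DataFrame(contrasts)
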