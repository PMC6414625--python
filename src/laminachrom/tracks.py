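"""Binned signal tracks, LAD assignment rules and log2 fold changes.

Implements the track-level analysis used for transcription and H3
pan-acetylation: overlap-weighted binning of interval signal, the LAD /
inter-LAD assignment rules (TSS-inside for genes, any-overlap for regions,
with a 1-kb exclusion buffer around LAD edges), per-replicate sum
normalization with a global pseudocount, and class-wise fold-change
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domain_stats import merge_intervals

__all__ = [
    "BinTrack",
    "bin_signal",
    "assign_lad_class",
    "normalize_and_log2fc",
    "lad_vs_interlad_change",
]

LAD = "LAD"
INTERLAD = "interLAD"
UNASSIGNED = "unassigned"


@dataclass
class BinTrack:
    """Per-bin scalar signal aligned to a fixed binning of one arm."""

    values: np.ndarray
    bin_size: int = 20_000
    arm_id: str = "arm"
    log2: bool = False
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for i, v in enumerate(self.values):
                fh.write(
                    f"{self.arm_id}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:.6g}\n"
                )


def bin_signal(
    intervals,
    bin_size: int,
    n_bins: int,
    *,
    log2: bool = False,
    pseudocount: float = 1.0,
    arm_id: str = "arm",
) -> BinTrack:
    """Overlap-weighted binning of weighted intervals into a :class:`BinTrack`.

    Each interval ``(start, end, weight)`` contributes
    ``weight * overlap_bp / interval_bp`` to every bin it overlaps, so total
    weight is conserved (after clipping at the arm end).  With ``log2`` the
    binned values are transformed as ``log2(x + pseudocount)``.
    """
    arr = np.asarray(intervals, dtype=float).reshape(-1, 3)
    out = np.zeros(n_bins)
    arm_end = n_bins * bin_size
    for s, e, w in arr:
        if e <= s:
            continue
        if e > arm_end or s < 0:
            warnings.warn("interval beyond arm end; clipping")
        cs, ce = max(s, 0.0), min(e, arm_end)
        if ce <= cs:
            continue
        b0, b1 = int(cs // bin_size), int(np.ceil(ce / bin_size))
        for b in range(b0, b1):
            lo = max(cs, b * bin_size)
            hi = min(ce, (b + 1) * bin_size)
            out[b] += w * (hi - lo) / (e - s)
    if log2:
        out = np.log2(out + pseudocount)
    return BinTrack(out, bin_size=bin_size, arm_id=arm_id, log2=log2)


# ---------------------------------------------------------------------------
# LAD / inter-LAD assignment
# ---------------------------------------------------------------------------

def _dist_to_lads(point_or_span, lads_m: np.ndarray, *, span: bool) -> float:
    """bp distance to the nearest LAD (0 if inside/overlapping)."""
    if lads_m.size == 0:
        return np.inf
    if span:
        s, e = point_or_span
        left = lads_m[:, 0] - e  # gap if LAD starts after span end
        right = s - lads_m[:, 1]
        gaps = np.maximum(np.maximum(left, right), 0.0)
        overlap = (lads_m[:, 0] < e) & (lads_m[:, 1] > s)
        gaps[overlap] = 0.0
        return float(gaps.min())
    p = float(point_or_span)
    inside = (lads_m[:, 0] <= p) & (p < lads_m[:, 1])
    if inside.any():
        return 0.0
    return float(
        np.minimum(np.abs(lads_m[:, 0] - p), np.abs(p - lads_m[:, 1])).min()
    )


def assign_lad_class(
    features: pd.DataFrame,
    lads,
    *,
    mode: str = "gene",
    min_dist: float = 1_000.0,
) -> pd.DataFrame:
    """Attach a ``lad_class`` column following the TSS / overlap rules.

    Genes (``mode="gene"``, requires ``start``, ``end``, ``strand``): class is
    LAD when the strand-aware TSS lies inside a LAD, inter-LAD when the TSS is
    at least ``min_dist`` bp from every LAD, otherwise unassigned.  Regions
    (``mode="region"``): LAD on any overlap, inter-LAD at >= ``min_dist`` bp,
    otherwise unassigned.  The two classes deliberately do not tile the
    genome: the buffer zone is excluded from both.
    """
    lads_m = merge_intervals(lads)
    out = features.copy()
    classes = []
    for r in out.itertuples():
        if mode == "gene":
            if r.strand not in ("+", "-"):
                raise ValueError(f"feature {r.Index} lacks a strand; TSS undefined")
            tss = r.start if r.strand == "+" else r.end
            d = _dist_to_lads(tss, lads_m, span=False)
        elif mode == "region":
            d = _dist_to_lads((r.start, r.end), lads_m, span=True)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if d == 0:
            classes.append(LAD)
        elif d >= min_dist:
            classes.append(INTERLAD)
        else:
            classes.append(UNASSIGNED)
    out["lad_class"] = classes
    return out


# ---------------------------------------------------------------------------
# Normalization and fold change
# ---------------------------------------------------------------------------

def normalize_and_log2fc(tables: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Sum-normalize replicates, add a global pseudocount, and form log2FC.

    ``tables`` maps ``(condition, replicate)`` to aligned per-feature value
    arrays (conditions ``control`` and ``kd``).  Each replicate is divided by
    its total; features at zero in every replicate are dropped; the
    pseudocount is the minimum nonzero entry of the pooled normalized table
    and is added to every entry; replicates are then averaged per condition
    and ``log2fc = log2(kd / control)`` returned per retained feature.
    """
    keys = sorted(tables)
    mat = np.column_stack([np.asarray(tables[k], dtype=float) for k in keys])
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a replicate has zero total coverage")
    norm = mat / totals
    keep = norm.sum(axis=1) > 0
    norm = norm[keep]
    positive = norm[norm > 0]
    pseudo = float(positive.min()) if positive.size else 0.0
    norm = norm + pseudo
    conds = np.array([c for c, _ in keys])
    mean_kd = norm[:, conds == "kd"].mean(axis=1)
    mean_ctrl = norm[:, conds == "control"].mean(axis=1)
    return pd.DataFrame(
        {
            "feature": np.flatnonzero(keep),
            "mean_control": mean_ctrl,
            "mean_kd": mean_kd,
            "log2fc": np.log2(mean_kd / mean_ctrl),
        }
    )


def lad_vs_interlad_change(log2fc: pd.Series, classes: pd.Series) -> dict:
    """Split per-feature log2FC by LAD class and summarize the two groups.

    Returns the LAD and inter-LAD distributions, their medians/quartiles, and
    a Mann-Whitney U p-value for a location difference (empty classes are
    reported with NaN summaries).
    """
    lfc = np.asarray(log2fc, dtype=float)
    cls = np.asarray(classes)
    dists = {
        LAD: lfc[(cls == LAD) & np.isfinite(lfc)],
        INTERLAD: lfc[(cls == INTERLAD) & np.isfinite(lfc)],
    }
    rows = []
    for name, v in dists.items():
        if v.size:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"class": name, "n": v.size, "median": med, "q1": q1, "q3": q3})
    if dists[LAD].size and dists[INTERLAD].size:
        p = float(stats.mannwhitneyu(dists[LAD], dists[INTERLAD]).pvalue)
    else:
        p = np.nan
    return {"distributions": dists, "summary": pd.DataFrame(rows), "p_between": p}
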