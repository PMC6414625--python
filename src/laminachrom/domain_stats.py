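"""Per-TAD statistics: ACF, replicate concordance, composition and grouping.

The average contact frequency (ACF) of a TAD is the mean balanced contact
value over all pairs of its interior bins (boundary bins dropped from both
sides, diagonal excluded); for an inter-TAD the average runs over the
inter-TAD bins plus the nearest boundary bin of each adjacent TAD.  TADs are
ranked by a Jaccard-style score contrasting LAD coverage against active
("red" + "purple") chromatin content and split into four equal-sized groups
A (active-rich, LAD-poor) through D (LAD-rich, active-poor); knock-down vs
control ACF changes are then summarized per group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .domains import INTER, TAD, DomainAnnotation
from .hic import ContactMap

__all__ = [
    "acf_tad",
    "acf_intertad",
    "concordance_filter",
    "interval_composition",
    "merge_intervals",
    "jaccard_group",
    "build_tad_metrics",
    "group_change_summary",
]

GROUPS = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# ACF
# ---------------------------------------------------------------------------

def _pair_mean(counts: np.ndarray, bins: np.ndarray) -> float:
    """Mean over unordered off-diagonal pairs of ``bins``; NaN entries skipped."""
    sub = counts[np.ix_(bins, bins)]
    iu, ju = np.triu_indices(len(bins), k=1)
    vals = sub[iu, ju]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def acf_tad(cmap: ContactMap, tad: tuple[int, int]) -> float:
    """ACF over interior bins of a TAD ``(start_bin, end_bin)`` (half-open).

    The first and last bin of the TAD are excluded; a TAD with fewer than two
    interior bins has no defined ACF and returns NaN.
    """
    start, end = tad
    interior = np.arange(start + 1, end - 1)
    if interior.size < 2:
        warnings.warn(f"TAD ({start},{end}) has <2 interior bins; ACF undefined")
        return float("nan")
    return _pair_mean(cmap.counts, interior)


def acf_intertad(
    cmap: ContactMap, intertad: tuple[int, int], annotation: DomainAnnotation
) -> float:
    """ACF over inter-TAD bins plus the adjacent TADs' nearest boundary bins."""
    start, end = intertad
    bins = list(range(start, end))
    for s, e, lab in annotation.segments:
        if lab != TAD:
            continue
        if e == start:  # TAD ending where the inter-TAD begins
            bins.append(e - 1)
        if s == end:  # TAD starting where the inter-TAD ends
            bins.append(s)
    if len(bins) == end - start:  # no adjacent TAD on either side
        warnings.warn("isolated inter-TAD: ACF undefined")
        return float("nan")
    return _pair_mean(cmap.counts, np.array(sorted(bins)))


def concordance_filter(
    acf_kd: tuple[float, float],
    acf_ctrl: tuple[float, float],
    *,
    strict: bool = False,
) -> dict:
    """Replicate-concordance test on the four KD/control ACF ratios.

    Forms all four ratios KD_r / Ctrl_s; the sign of each log2 ratio (a ratio
    of exactly 1 counts for neither side) votes for an "up" or "down" change.
    The TAD is kept when at least three ratios agree (all four with
    ``strict=True``); ``direction`` is the winning sign.
    """
    vals = list(acf_kd) + list(acf_ctrl)
    if not all(np.isfinite(v) and v > 0 for v in vals):
        return {"keep": False, "direction": "none"}
    signs = [
        np.sign(np.log2(k / c)) for k in acf_kd for c in acf_ctrl
    ]
    need = 4 if strict else 3
    for direction, sgn in (("up", 1), ("down", -1)):
        if sum(s == sgn for s in signs) >= need:
            return {"keep": True, "direction": direction}
    return {"keep": False, "direction": "none"}


# ---------------------------------------------------------------------------
# Interval composition
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> np.ndarray:
    """Merge overlapping/adjacent half-open bp intervals into a sorted array."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def _covered_bp(span: tuple[float, float], merged: np.ndarray) -> float:
    s0, e0 = span
    if merged.size == 0:
        return 0.0
    lo = np.maximum(merged[:, 0], s0)
    hi = np.minimum(merged[:, 1], e0)
    return float(np.clip(hi - lo, 0, None).sum())


def interval_composition(span: tuple[float, float], intervals) -> float:
    """Fraction of the bp span ``(start, end)`` covered by the intervals."""
    s0, e0 = span
    if e0 <= s0:
        raise ValueError("span must have positive length")
    return _covered_bp(span, merge_intervals(intervals)) / (e0 - s0)


# ---------------------------------------------------------------------------
# Jaccard ranking into groups A-D
# ---------------------------------------------------------------------------

def _jaccard_score(span, lads_m: np.ndarray, union_m: np.ndarray) -> float:
    num = _covered_bp(span, lads_m)
    den = _covered_bp(span, union_m)
    return num / den if den > 0 else 0.0


def jaccard_group(table: pd.DataFrame, lads, active) -> pd.DataFrame:
    """Attach ``jaccard_score`` and quartile ``group`` labels to a TAD table.

    The score of a TAD is |LAD n T| / |(LAD u active) n T| in bp — 0 for a
    fully active LAD-free TAD and 1 for a fully LAD-covered inactive one.
    TADs are ranked ascending by score (ties broken by genomic order) and cut
    into four equal-sized groups A (lowest) to D (highest).
    """
    lads_m = merge_intervals(lads)
    active_m = merge_intervals(active)
    union_m = merge_intervals(np.concatenate([lads_m, active_m], axis=0))
    out = table.copy()
    out["jaccard_score"] = [
        _jaccard_score((r.start_bp, r.end_bp), lads_m, union_m)
        for r in out.itertuples()
    ]
    order = np.argsort(out["jaccard_score"].to_numpy(), kind="stable")
    labels = np.empty(len(out), dtype=object)
    for g, chunk in zip(GROUPS, np.array_split(order, 4)):
        labels[chunk] = g
    out["group"] = labels
    return out


# ---------------------------------------------------------------------------
# Table assembly and group summaries
# ---------------------------------------------------------------------------

def build_tad_metrics(
    annotation: DomainAnnotation,
    maps: dict[tuple[str, str], ContactMap],
    lads,
    active,
    *,
    strict_concordance: bool = False,
) -> pd.DataFrame:
    """Assemble the per-TAD metrics table.

    ``maps`` keys are ``(condition, replicate)`` with conditions ``control``
    and ``kd``; replicate ``"merged"`` holds the re-balanced merged map used
    for headline log2 fold changes, while numbered replicates feed the
    concordance filter.
    """
    bs = annotation.bin_size
    rows = []
    for tid, (s, e) in enumerate(annotation.tads):
        row: dict = {
            "tad_id": tid,
            "start_bin": s,
            "end_bin": e,
            "start_bp": s * bs,
            "end_bp": e * bs,
        }
        for (cond, rep), cmap in maps.items():
            row[f"acf_{cond}_{rep}"] = acf_tad(cmap, (s, e))
        row["lad_coverage"] = interval_composition((s * bs, e * bs), lads)
        row["active_prop"] = interval_composition((s * bs, e * bs), active)
        rows.append(row)
    table = pd.DataFrame(rows)

    reps = sorted({r for (_, r) in maps if r != "merged"})
    if len(reps) >= 2:
        r1, r2 = reps[:2]
        keep, direction = [], []
        for r in table.itertuples():
            res = concordance_filter(
                (getattr(r, f"acf_kd_{r1}"), getattr(r, f"acf_kd_{r2}")),
                (getattr(r, f"acf_control_{r1}"), getattr(r, f"acf_control_{r2}")),
                strict=strict_concordance,
            )
            keep.append(res["keep"])
            direction.append(res["direction"])
        table["keep"] = keep
        table["direction"] = direction
    if ("control", "merged") in maps and ("kd", "merged") in maps:
        with np.errstate(divide="ignore", invalid="ignore"):
            table["acf_log2fc"] = np.log2(
                table["acf_kd_merged"] / table["acf_control_merged"]
            )
    table = jaccard_group(table, lads, active)
    return table


def group_change_summary(
    table: pd.DataFrame, value_col: str = "acf_log2fc", *, filtered: bool = True
) -> pd.DataFrame:
    """Per-group distribution summary of a log2 fold-change column.

    Reports median, quartiles, variance and a one-sample Wilcoxon signed-rank
    p-value (is the group's median shift nonzero) for each group A-D, after
    the replicate-concordance filter when ``filtered`` is set.
    """
    sub = table[table["keep"]] if filtered and "keep" in table else table
    rows = []
    for g in GROUPS:
        vals = sub.loc[sub["group"] == g, value_col].dropna().to_numpy()
        row = {"group": g, "n": len(vals)}
        if len(vals) == 0:
            row.update(median=np.nan, q1=np.nan, q3=np.nan, variance=np.nan, p=np.nan)
        else:
            row["median"] = float(np.median(vals))
            row["q1"], row["q3"] = np.percentile(vals, [25, 75])
            row["variance"] = float(np.var(vals, ddof=1)) if len(vals) > 1 else np.nan
            row["p"] = (
                float(stats.wilcoxon(vals).pvalue)
                if len(vals) > 1 and np.any(vals != 0)
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
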