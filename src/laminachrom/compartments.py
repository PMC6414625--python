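"""A/B compartment annotation, saddle plots and contact-change statistics.

Compartment signal is the first principal component (PC1) of the Pearson
correlation matrix of the observed/expected (O/E) map, oriented so that
positive values correlate with an activity reference track (binned
transcription, or active-chromatin fraction).  Saddle plots aggregate the
O/E map over 20 PC1 quantiles; subtracting a knock-down saddle from the
control saddle (both on the control PC1 ordering) visualizes
compartmentalization changes, and ``ab_contact_changes`` collects per-pair
log2 fold changes within and between the active/inactive fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic import ContactMap, ContactMapError

__all__ = [
    "CompartmentTrack",
    "SaddleMatrix",
    "compute_pc1",
    "saddle",
    "saddle_subtract",
    "ab_contact_changes",
]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values (NaN on masked bins), sign-anchored to a reference."""

    values: np.ndarray
    orientation_reference: str = "transcription"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SaddleMatrix:
    """PC1-quantile aggregated log2 O/E enrichment (n_quantiles x n_quantiles).

    ``quantile_of_bin`` records which quantile each bin fell into (-1 for
    bins excluded from the ordering), so that subtraction can verify both
    saddles used the same ordering.
    """

    matrix: np.ndarray
    quantile_of_bin: np.ndarray

    @property
    def n_quantiles(self) -> int:
        return self.matrix.shape[0]


def compute_pc1(oe: ContactMap, orientation) -> CompartmentTrack:
    """First principal component of the O/E Pearson-correlation matrix.

    Masked bins are excluded from the decomposition and returned as NaN.
    The sign is flipped if PC1 anticorrelates with the orientation track so
    that positive PC1 marks the active compartment.
    """
    live = oe.unmasked
    if live.size < 3:
        raise ContactMapError("too few unmasked bins for PCA")
    sub = oe.counts[np.ix_(live, live)]
    # neutral fill for the rare undefined entries (missing expected distances)
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if np.allclose(sub.std(axis=1), 0):
        raise ContactMapError("degenerate (rank-0) O/E map")
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    corr -= corr.mean(axis=0, keepdims=True)
    # PCA scores of the bins = leading left-singular direction of the
    # column-centred correlation matrix
    u, s, _ = np.linalg.svd(corr, full_matrices=False)
    pc1_live = u[:, 0] * s[0]

    values = np.full(oe.n_bins, np.nan)
    values[live] = pc1_live
    orient = np.asarray(orientation, dtype=float)
    both = np.isfinite(values) & np.isfinite(orient)
    if both.sum() >= 2 and np.std(orient[both]) > 0 and np.std(values[both]) > 0:
        r = np.corrcoef(values[both], orient[both])[0, 1]
        if r < 0:
            values = -values
    return CompartmentTrack(values)


def saddle(
    oe: ContactMap, pc1: CompartmentTrack, n_quantiles: int = 20
) -> SaddleMatrix:
    """Aggregate the O/E map over PC1 quantiles into a saddle plot.

    Bins with defined PC1 are sorted by increasing PC1 (ties broken by bin
    index) and cut into ``n_quantiles`` equal-count groups; cell (p, q) is
    the log2 of the mean O/E over off-diagonal unmasked pairs spanning
    quantiles p and q.
    """
    vals = pc1.values
    eligible = np.flatnonzero(np.isfinite(vals) & ~oe.mask)
    if eligible.size < n_quantiles:
        raise ContactMapError(
            f"need at least {n_quantiles} unmasked bins for a saddle plot"
        )
    order = eligible[np.argsort(vals[eligible], kind="stable")]
    quant = np.full(oe.n_bins, -1, dtype=int)
    for qi, chunk in enumerate(np.array_split(order, n_quantiles)):
        quant[chunk] = qi

    sums = np.zeros((n_quantiles, n_quantiles))
    nums = np.zeros((n_quantiles, n_quantiles))
    C = oe.counts
    n = oe.n_bins
    iu, ju = np.triu_indices(n, k=1)
    qi, qj = quant[iu], quant[ju]
    vv = C[iu, ju]
    ok = (qi >= 0) & (qj >= 0) & np.isfinite(vv)
    qlo = np.minimum(qi[ok], qj[ok])
    qhi = np.maximum(qi[ok], qj[ok])
    np.add.at(sums, (qlo, qhi), vv[ok])
    np.add.at(nums, (qlo, qhi), 1.0)
    sums += np.triu(sums, k=1).T
    nums += np.triu(nums, k=1).T
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.log2(sums / nums)
    return SaddleMatrix(mat, quant)


def saddle_subtract(kd: SaddleMatrix, ctrl: SaddleMatrix) -> SaddleMatrix:
    """Elementwise KD minus control; both must share the PC1 quantile ordering."""
    if kd.matrix.shape != ctrl.matrix.shape or not np.array_equal(
        kd.quantile_of_bin, ctrl.quantile_of_bin
    ):
        raise ValueError("saddles were built on different quantile assignments")
    return SaddleMatrix(kd.matrix - ctrl.matrix, kd.quantile_of_bin.copy())


def ab_contact_changes(
    oe_kd: ContactMap, oe_ctrl: ContactMap, pc1: CompartmentTrack
) -> dict:
    """Per-pair log2(O/E_kd / O/E_ctrl) split by compartment class.

    Classes follow the control PC1 labels: within-active (both bins PC1 > 0),
    within-inactive (both < 0) and between.  Pairs with an undefined O/E in
    either condition, and diagonal pairs, are skipped.  Returns the three
    distributions and a summary table of medians/quartiles.
    """
    if oe_kd.n_bins != oe_ctrl.n_bins:
        raise ValueError("maps must share the binning")
    lab = np.where(pc1.values > 0, 1, np.where(pc1.values < 0, -1, 0))
    n = oe_kd.n_bins
    iu, ju = np.triu_indices(n, k=1)
    a, b = oe_kd.counts[iu, ju], oe_ctrl.counts[iu, ju]
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    ok &= (lab[iu] != 0) & (lab[ju] != 0)
    lfc = np.log2(a[ok] / b[ok])
    li, lj = lab[iu][ok], lab[ju][ok]
    dists = {
        "within_active": lfc[(li == 1) & (lj == 1)],
        "within_inactive": lfc[(li == -1) & (lj == -1)],
        "between": lfc[li != lj],
    }
    rows = []
    for name, v in dists.items():
        if v.size:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"class": name, "n": v.size, "median": med, "q1": q1, "q3": q3})
    return {"distributions": dists, "summary": pd.DataFrame(rows)}
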