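"""Contact-map data model, I/O, ICE balancing and observed/expected transforms.

A :class:`ContactMap` holds one chromosome arm's symmetric cis contact matrix
at a fixed bin size (20 kb in the fly maps this package targets), together
with a per-bin exclusion mask.  Raw count maps are balanced with iterative
correction (ICE), which factors out multiplicative per-bin biases so that
every retained bin has the same total contact sum; distance-decay expected
profiles and observed/expected (O/E) maps are derived from the balanced map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "read_contact_map",
    "write_contact_map",
    "mask_bins",
    "ice_normalize",
    "expected_profile",
    "observed_over_expected",
]


class ContactMapError(ValueError):
    """Raised for malformed or degenerate contact-map inputs."""


@dataclass
class ContactMap:
    """Symmetric binned cis contact matrix for one chromosome arm.

    Parameters
    ----------
    counts
        ``(n_bins, n_bins)`` symmetric non-negative matrix; raw counts or
        ICE-corrected frequencies depending on ``corrected``.
    bin_size
        Bin width in bp; bins are 0-based half-open
        ``[i*bin_size, (i+1)*bin_size)``.
    mask
        Boolean per bin, ``True`` meaning the bin is excluded; masked rows
        and columns are kept all-zero.
    """

    counts: np.ndarray
    bin_size: int = 20_000
    arm_id: str = "arm"
    mask: np.ndarray = None  # type: ignore[assignment]
    corrected: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ContactMapError("counts must be a square matrix")
        if np.isinf(self.counts).any():
            raise ContactMapError("counts must be finite (NaN marks missing)")
        finite = np.isfinite(self.counts)
        if (self.counts[finite] < 0).any():
            raise ContactMapError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ContactMapError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ContactMapError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        """Indices of retained bins."""
        return np.flatnonzero(~self.mask)

    def copy(self) -> "ContactMap":
        return replace(self, counts=self.counts.copy(), mask=self.mask.copy())


@dataclass
class ExpectedProfile:
    """Mean balanced contact frequency per genomic distance (in bins).

    ``values[s]`` is the arm-wide mean over unmasked bin pairs at separation
    ``s``; distances with no unmasked pair are NaN (``missing[s]`` True).
    """

    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_contact_map(
    path,
    format: str = "coo-tsv",
    *,
    n_bins: int | None = None,
    bin_size: int = 20_000,
    arm_id: str = "arm",
    corrected: bool = False,
) -> ContactMap:
    """Read a contact matrix from a dense or sparse (COO triplet) TSV file.

    ``coo-tsv`` rows are ``bin_i<TAB>bin_j<TAB>count``; duplicate and
    transposed triplets are summed, missing entries are zero.  ``dense-tsv``
    is an ``n x n`` float table with a header row of bin start coordinates.
    """
    if format == "dense-tsv":
        df = pd.read_csv(path, sep="\t")
        mat = df.to_numpy(dtype=float)
        mat = 0.5 * (mat + mat.T) if not np.allclose(mat, mat.T) else mat
        return ContactMap(mat, bin_size=bin_size, arm_id=arm_id, corrected=corrected)
    if format != "coo-tsv":
        raise ContactMapError(f"unknown contact-map format: {format!r}")

    ii: list[int] = []
    jj: list[int] = []
    vv: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ContactMapError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ContactMapError(f"{path}:{lineno}: unparsable triplet") from exc
            if v < 0:
                raise ContactMapError(f"{path}:{lineno}: negative count {v}")
            ii.append(i)
            jj.append(j)
            vv.append(v)
    if n_bins is None:
        n_bins = (max(max(ii, default=-1), max(jj, default=-1)) + 1) if ii else 0
    mat = np.zeros((n_bins, n_bins))
    for i, j, v in zip(ii, jj, vv):
        if i >= n_bins or j >= n_bins:
            raise ContactMapError(f"bin index ({i},{j}) outside n_bins={n_bins}")
        mat[i, j] += v
        if i != j:
            mat[j, i] += v
    return ContactMap(mat, bin_size=bin_size, arm_id=arm_id, corrected=corrected)


def write_contact_map(cmap: ContactMap, path, format: str = "coo-tsv") -> None:
    """Write upper-triangle COO triplets or a dense TSV with bin-start header."""
    if format == "coo-tsv":
        iu, ju = np.triu_indices(cmap.n_bins)
        vals = cmap.counts[iu, ju]
        keep = vals != 0
        with open(path, "w") as fh:
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")
    elif format == "dense-tsv":
        header = "\t".join(str(i * cmap.bin_size) for i in range(cmap.n_bins))
        np.savetxt(path, cmap.counts, delimiter="\t", header=header, comments="")
    else:
        raise ContactMapError(f"unknown contact-map format: {format!r}")


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def mask_bins(cmap: ContactMap, min_marginal_frac: float = 0.1) -> ContactMap:
    """Mask under-covered bins before balancing.

    A bin is masked if its marginal (row sum) is zero or below
    ``min_marginal_frac`` times the median nonzero marginal.  Masked rows and
    columns are zeroed.
    """
    marg = cmap.counts.sum(axis=1)
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        raise ContactMapError("empty map after filtering")
    thresh = min_marginal_frac * np.median(nonzero)
    mask = cmap.mask | (marg == 0) | (marg < thresh)
    if mask.all():
        raise ContactMapError("empty map after filtering")
    counts = cmap.counts.copy()
    counts[mask, :] = 0.0
    counts[:, mask] = 0.0
    return replace(cmap, counts=counts, mask=mask)


def ice_normalize(
    cmap: ContactMap, n_iterations: int = 20
) -> tuple[ContactMap, np.ndarray]:
    """Iterative correction: factor out multiplicative per-bin biases.

    Runs a fixed number of balancing iterations (20 by default, matching the
    ICE pipeline convention) with no early stopping, then rescales so the mean
    marginal over unmasked bins is 1.  Returns the corrected map and the bias
    vector ``b`` with ``corrected[i,j] = raw[i,j] / (b_i * b_j)``; masked bins
    get ``b = NaN``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    live = cmap.unmasked
    if live.size < 2:
        raise ContactMapError("need at least 2 unmasked bins to balance")
    W = cmap.counts.copy()
    bias = np.ones(cmap.n_bins)
    prev_cv = np.inf
    warned = False
    for _ in range(n_iterations):
        marg = W.sum(axis=1)
        m_live = marg[live]
        mean_m = m_live.mean()
        if mean_m == 0:
            raise ContactMapError("all-zero marginals during balancing")
        cv = m_live.std() / mean_m
        if cv > prev_cv * (1 + 1e-9) and cv > 1e-10 and not warned:
            warnings.warn("ICE marginal spread increased; result may not be balanced")
            warned = True
        prev_cv = cv
        s = np.ones(cmap.n_bins)
        s[live] = m_live / mean_m
        # guard: a live bin whose marginal hit exact zero cannot be rescaled
        s[s == 0] = 1.0
        W /= np.outer(s, s)
        bias *= s
    # rescale so the mean unmasked marginal equals one
    scale = W.sum(axis=1)[live].mean()
    if scale > 0:
        W /= scale
        bias *= np.sqrt(scale)
    W[cmap.mask, :] = 0.0
    W[:, cmap.mask] = 0.0
    bias_out = bias.copy()
    bias_out[cmap.mask] = np.nan
    return replace(cmap, counts=W, corrected=True), bias_out


# ---------------------------------------------------------------------------
# Expected profile and O/E
# ---------------------------------------------------------------------------

def expected_profile(cmap: ContactMap) -> ExpectedProfile:
    """Per-distance mean contact over unmasked bin pairs.

    ``values[s]`` averages ``counts[i, i+s]`` over all ``i`` with both bins
    unmasked; a distance with no eligible pair is NaN.
    """
    n = cmap.n_bins
    good = ~cmap.mask
    values = np.full(n, np.nan)
    for s in range(n):
        diag = np.diagonal(cmap.counts, offset=s)
        use = good[: n - s] & good[s:] & np.isfinite(diag)
        if use.any():
            values[s] = diag[use].mean()
    return ExpectedProfile(values)


def observed_over_expected(cmap: ContactMap, profile: ExpectedProfile) -> ContactMap:
    """Divide each diagonal by its arm-wide mean; undefined entries become NaN.

    Masked bins and distances with zero or missing expected value are NaN in
    the result (NaN rather than zero so downstream averages can skip them).
    """
    n = cmap.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    exp = profile.values[dist]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, cmap.counts / exp, np.nan)
    oe[cmap.mask, :] = np.nan
    oe[:, cmap.mask] = np.nan
    return replace(cmap, counts=oe, corrected=True)
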