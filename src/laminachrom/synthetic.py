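"""Synthetic inputs with the statistical structure the analysis assumes.

Generates, from a single seeded specification: raw Hi-C contact maps with a
power-law distance decay, planted TADs, planted A/B compartments,
multiplicative per-bin biases and Poisson counting noise; LAD and active
("red"+"purple") chromatin interval sets aligned with the planted TAD
labels; and expression tracks with a planted LAD-specific log2 shift in the
knock-down condition.  Every stage of the pipeline can therefore be tested
as a planted-parameter recovery problem with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import ContactMap

__all__ = [
    "SyntheticSpec",
    "make_hic",
    "make_annotations",
    "make_tracks",
    "make_balanced_matrix",
    "plant_biases",
]

_COND_CODE = {"control": 0, "kd": 1}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults define the standard study conditions: a 500-bin arm of 20-kb
    bins, sequencing depth 2e5 cis contacts, TAD contact boost 3, same-
    compartment boost 1.6, log-normal biases (sigma 0.3), two replicates per
    condition; the knock-down multiplies intra-TAD contacts of active
    (truth group A) TADs by 1.2 and of LAD (truth group D) TADs by 0.8 and
    shifts LAD transcription by +0.5 log2 units.
    """

    n_bins: int = 500
    bin_size: int = 20_000
    decay_exponent: float = 1.0
    tad_boost: float = 3.0
    compartment_strength: float = 1.6
    bias_sigma: float = 0.3
    depth: float = 2e5
    group_a_multiplier: float = 1.2
    group_d_multiplier: float = 0.8
    mixing_multiplier: float = 1.0
    delta_lad: float = 0.5
    replicate_noise: float = 0.1
    n_replicates: int = 2
    n_genes: int = 600
    # log2 expression model: weak LAD background spanning orders of
    # magnitude vs strong inter-LAD genes
    lad_log2_mean: float = 1.0
    lad_log2_sd: float = 1.5
    interlad_log2_mean: float = 6.0
    interlad_log2_sd: float = 1.5
    tad_size_range: tuple[int, int] = (6, 15)
    intertad_size_range: tuple[int, int] = (1, 3)
    seed: int = 0

    # planted structure, generated lazily from the seed
    _tads: list = field(default=None, repr=False)  # type: ignore[assignment]
    _tad_active: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def _plant(self) -> None:
        if self._tads is not None:
            return
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 97]))
        tads: list[tuple[int, int]] = []
        pos = int(rng.integers(*self.intertad_size_range))
        while pos < self.n_bins - self.tad_size_range[1]:
            size = int(rng.integers(self.tad_size_range[0], self.tad_size_range[1] + 1))
            tads.append((pos, pos + size))
            pos += size + int(rng.integers(self.intertad_size_range[0],
                                           self.intertad_size_range[1] + 1))
        # activity labels in runs of 2-5 TADs: compartments are larger than TADs
        labels = []
        state = bool(rng.integers(2))
        while len(labels) < len(tads):
            run = int(rng.integers(2, 6))
            labels.extend([state] * run)
            state = not state
        self._tads = tads
        self._tad_active = np.array(labels[: len(tads)], dtype=bool)

    @property
    def tads(self) -> list[tuple[int, int]]:
        """Planted TAD segments in bin coordinates (half-open)."""
        self._plant()
        return list(self._tads)

    @property
    def tad_active(self) -> np.ndarray:
        """Planted activity label per TAD (True = active / truth group A)."""
        self._plant()
        return self._tad_active.copy()

    @property
    def tad_of_bin(self) -> np.ndarray:
        """TAD index per bin, -1 for inter-TAD bins."""
        out = np.full(self.n_bins, -1, dtype=int)
        for t, (s, e) in enumerate(self.tads):
            out[s:e] = t
        return out

    @property
    def compartment_of_bin(self) -> np.ndarray:
        """Planted compartment sign per bin (+1 active / -1 inactive).

        Inter-TAD bins inherit the label of the nearest planted TAD.
        """
        tob = self.tad_of_bin
        act = self.tad_active
        lab = np.zeros(self.n_bins, dtype=int)
        centers = np.array([(s + e) / 2 for s, e in self.tads])
        for i in range(self.n_bins):
            t = tob[i]
            if t < 0:
                t = int(np.argmin(np.abs(centers - i)))
            lab[i] = 1 if act[t] else -1
        return lab


def _rng_for(spec: SyntheticSpec, *codes: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *codes]))


def make_hic(
    spec: SyntheticSpec, condition: str = "control", replicate: int = 1
) -> ContactMap:
    """Raw Poisson contact map with planted TADs, compartments and biases.

    The expected contact surface is a power-law distance decay boosted
    ``tad_boost``-fold inside planted TADs and ``compartment_strength``-fold
    for same-compartment pairs, modulated in the knock-down by the per-group
    ACF multipliers (intra-TAD) and the between-compartment mixing
    multiplier, then scaled to the target depth, multiplied by log-normal
    per-bin biases and sampled as symmetric Poisson counts.
    """
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = (dist + 1.0) ** (-spec.decay_exponent)

    tob = spec.tad_of_bin
    same_tad = (tob[:, None] == tob[None, :]) & (tob[:, None] >= 0)
    lam = np.where(same_tad, lam * spec.tad_boost, lam)
    comp = spec.compartment_of_bin
    same_comp = comp[:, None] == comp[None, :]
    lam = np.where(same_comp, lam * spec.compartment_strength, lam)

    if condition == "kd":
        act = spec.tad_active
        for t, (s, e) in enumerate(spec.tads):
            mult = spec.group_a_multiplier if act[t] else spec.group_d_multiplier
            lam[s:e, s:e] *= mult
        if spec.mixing_multiplier != 1.0:
            lam = np.where(~same_comp, lam * spec.mixing_multiplier, lam)
    elif condition != "control":
        raise ValueError(f"unknown condition {condition!r}")

    iu, ju = np.triu_indices(n)
    total = lam[iu, ju].sum()
    lam *= spec.depth / total if total > 0 else 0.0

    rng = _rng_for(spec, _COND_CODE[condition], int(replicate), 11)
    bias = rng.lognormal(mean=0.0, sigma=spec.bias_sigma, size=n)
    lam = lam * np.outer(bias, bias)

    counts = np.zeros((n, n))
    draws = rng.poisson(lam[iu, ju])
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMap(counts.astype(float), bin_size=spec.bin_size,
                      arm_id="synthArm", corrected=False)


def make_annotations(spec: SyntheticSpec) -> dict:
    """LAD and active-chromatin interval sets matching the planted labels.

    LADs cover the inactive planted TADs; active ("red"+"purple") intervals
    cover most of each active TAD, trimmed at the edges so the two interval
    sets stay essentially disjoint.  Coordinates are bp, half-open.
    """
    bs = spec.bin_size
    lads, active = [], []
    for t, (s, e) in enumerate(spec.tads):
        if spec.tad_active[t]:
            # active interval: interior of the TAD, ~80% coverage
            pad = max(1, int(0.1 * (e - s)))
            active.append((float((s + pad) * bs), float((e - pad) * bs)))
        else:
            lads.append((float(s * bs), float(e * bs)))
    truth = pd.DataFrame(
        {
            "start_bin": [s for s, _ in spec.tads],
            "end_bin": [e for _, e in spec.tads],
            "active": spec.tad_active,
        }
    )
    return {"lads": lads, "active": active, "tad_truth": truth}


def write_bed(intervals, path, arm_id: str = "synthArm", name: str = ".") -> None:
    """Write bp intervals as a minimal BED file (0-based half-open)."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{arm_id}\t{int(s)}\t{int(e)}\t{name}\n")


def read_bed(path) -> list[tuple[float, float]]:
    """Read start/end bp intervals from a BED file (single arm)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((float(f[1]), float(f[2])))
    return out


def make_tracks(
    spec: SyntheticSpec, condition: str = "control", replicate: int = 1
) -> dict:
    """Synthetic gene table and per-bin transcription values.

    Genes get log-normal expression with a low mean inside LADs (weak
    background transcription) and a high mean outside; the knock-down adds
    ``delta_lad`` log2 units to LAD genes only.  Per-bin values aggregate the
    gene signal by overlap.  Replicate noise is multiplicative log-normal.
    """
    ann = make_annotations(spec)
    lad_arr = np.array(ann["lads"], dtype=float).reshape(-1, 2)
    arm_bp = spec.n_bins * spec.bin_size

    struct_rng = _rng_for(spec, 31)  # gene positions/strands: shared across conditions
    starts = np.sort(struct_rng.uniform(0, arm_bp - 2000, spec.n_genes))
    strands = np.where(struct_rng.random(spec.n_genes) < 0.5, "+", "-")
    ends = starts + 2000.0
    tss = np.where(strands == "+", starts, ends)
    in_lad = np.zeros(spec.n_genes, dtype=bool)
    for s, e in lad_arr:
        in_lad |= (tss >= s) & (tss < e)
    base_log2 = np.where(
        in_lad,
        struct_rng.normal(spec.lad_log2_mean, spec.lad_log2_sd, spec.n_genes),
        struct_rng.normal(spec.interlad_log2_mean, spec.interlad_log2_sd, spec.n_genes),
    )

    rng = _rng_for(spec, _COND_CODE[condition], int(replicate), 37)
    log2_expr = base_log2 + rng.normal(0.0, spec.replicate_noise, spec.n_genes)
    if condition == "kd":
        log2_expr = log2_expr + np.where(in_lad, spec.delta_lad, 0.0)
    values = 2.0**log2_expr

    genes = pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "strand": strands,
            "value": values,
            "in_lad_truth": in_lad,
        }
    )
    from .tracks import bin_signal

    track = bin_signal(
        np.column_stack([starts, ends, values]),
        spec.bin_size,
        spec.n_bins,
        arm_id="synthArm",
    )
    track.condition = condition
    track.replicate = str(replicate)
    return {"genes": genes, "bin_track": track}


# ---------------------------------------------------------------------------
# Balanced matrices for bias-recovery experiments
# ---------------------------------------------------------------------------

def make_balanced_matrix(
    n: int, rng: np.random.Generator, *, sinkhorn_iters: int = 2000
) -> np.ndarray:
    """Random dense symmetric positive matrix with (numerically) equal marginals."""
    M = rng.uniform(0.5, 1.5, size=(n, n))
    M = 0.5 * (M + M.T)
    for _ in range(sinkhorn_iters):
        s = M.sum(axis=1)
        s /= s.mean()
        M /= np.outer(s, s)
        if np.abs(s - 1).max() < 1e-14:
            break
    return M


def plant_biases(M: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Multiply a balanced matrix by per-bin biases: T_ij = b_i * b_j * M_ij."""
    return M * np.outer(biases, biases)
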