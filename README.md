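# laminachrom

Quantitative analysis of how nuclear-lamina (NL) disruption reorganizes
chromatin in *Drosophila*-style Hi-C data, plus a coarse-grained polymer
model of lamina attachment. The package is aimed at chromatin biologists
and modellers who want the full computational chain — from raw binned
contact matrices to TAD-group statistics, compartment saddle plots, LAD
fold-change analysis and a DPD simulation of a sticky copolymer at an
attractive surface — as tested, reusable library code with a synthetic
data generator, so every stage can be exercised without downloading any
dataset.

## What it computes

**Hi-C side.** Contact maps at fixed bin size (20 kb by default) are
balanced by iterative correction (20 iterations, biases factorized as
`T_ij = b_i b_j M_ij`). TADs are called by a gamma-scaled dynamic program
that maximizes Σ max(q, 0) over non-overlapping windows, with

    q(a,b) = S(a,b) / L^γ − μ(L),

followed by the two-step convention: domains > 600 kb re-partitioned at
2γ, domains ≤ 60 kb relabelled inter-TAD. Per TAD the average contact
frequency (ACF) is the mean balanced contact over interior-bin pairs;
knock-down vs control changes are replicate-concordance filtered (≥ 3 of
the 4 cross-replicate ratios sharing a sign) and summarized per TAD group,
where groups A–D are quartiles of the Jaccard-style score
`|LAD∩T| / |(LAD∪active)∩T|`. Compartments come from PC1 of the
O/E correlation matrix; 20×20 saddle plots aggregate log2 mean O/E over
control-PC1 quantiles. The tracks module implements overlap-weighted
binning, the TSS/1-kb LAD assignment rules, per-replicate sum
normalization with a table-minimum pseudocount, and LAD vs inter-LAD
log2 fold-change summaries.

**Polymer side.** A Groot–Warren DPD simulator (a=25, γ=4.5, σ²=2γkT,
r_c=1, dt=0.04) of a block copolymer whose "inactive" beads form
reversible saturating bonds (valence 1) with each other (p=0.001 per
check) and with a wall of immobile surface particles (p=0.007; breakage
p=0.01; checks every 200 steps). Block-level analysis reports surface
contacts, intra-block contacts, gyration-tensor volume and oblateness, and
classifies a block as a LAD when at least one bead touches the surface.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
from laminachrom import *
from laminachrom.synthetic import SyntheticSpec, make_hic, make_annotations

spec = SyntheticSpec(seed=3)                      # 500 bins, 2 conditions
raw = make_hic(spec, "control", 1)
corrected, biases = ice_normalize(mask_bins(raw))
annotation = two_step_annotation(corrected, gamma_scale=0.7)
print(len(annotation.tads), "TADs called,", len(spec.tads), "planted")
acf = acf_tad(corrected, annotation.tads[0])
print(f"ACF of first TAD: {acf:.4f}")
```

prints

```
41 TADs called, 38 planted
ACF of first TAD: 0.0427
```

(the caller recovers the planted boundaries with F1 ≈ 0.99 at ±1 bin; the
ACF is on the balanced scale where the mean bin marginal is 1). The full
pipeline — balancing, TAD groups, saddles, track fold changes — runs as

```bash
laminachrom all --seed 3 --out out/        # writes BED/TSV + summary.json
```

and the simulator as

```bash
laminachrom polymer run --runs 4 --seed 0 --out sim_out/
```

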