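# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `laminachrom`. The package has two halves: a Hi-C / genomic
track analysis pipeline for quantifying how nuclear-lamina disruption
changes TAD compaction and A/B compartmentalisation in *Drosophila*-style
20-kb maps, and a dissipative-particle-dynamics (DPD) polymer model testing
whether surface attachment per se compacts chromatin blocks.

## Contact-map model and balancing

A `ContactMap` is one chromosome arm's symmetric cis matrix at a fixed bin
size (default 20 kb), with a per-bin exclusion mask. Bins with zero
marginal, or marginal below `min_marginal_frac` (default 0.1) times the
median nonzero marginal, are masked before balancing; the threshold is a
package choice exposed in the config, selected for stability on shallow
maps.

Iterative correction (ICE) factorizes multiplicative per-bin biases by
repeatedly dividing each bin's row/column by its relative marginal. It runs
a fixed 20 iterations with no early stopping, then rescales so the mean
unmasked marginal is 1, which makes average contact frequencies (ACF)
comparable across conditions. On inputs of the form
`T_ij = b_i * b_j * M_ij` with `M` doubly balanced, 20 iterations recover
the biases to better than 1e-6 relative error on dense 200-bin matrices
(convergence is geometric with a small ratio for dense positive maps; very
sparse or near-decomposable maps converge more slowly and trigger a warning
if the marginal spread grows).

Expected-by-distance profiles average each diagonal over unmasked pairs;
observed/expected (O/E) maps divide by that profile, with undefined entries
(masked bins, empty distances) carried as NaN so downstream averages can
skip rather than absorb them.

## TAD calling

Candidate windows `[a, b]` are scored by scaled density centred on the
same-length mean:

    q(a, b) = S(a, b) / L^gamma - mean_a'( S(a', a'+L-1) / L^gamma ),

where `S` is the within-window upper-triangle contact sum (main diagonal
excluded) and `L = b - a + 1`. A dynamic program maximizes the sum of
positive window scores over non-overlapping windows; uncovered bins are
inter-TADs. Ties resolve to the skip option, giving a deterministic
partition; the DP optimum is verified against exhaustive partition search
on all matrices up to 12 bins. `mu(L)` is computed per arm, and masked bins
contribute zero contact (domains are not hard-broken at masked bins).

Two-step annotation re-partitions every called domain strictly longer than
600 kb with gamma doubled (the sub-DP runs on the domain's own submatrix),
then relabels every domain of 60 kb or shorter as inter-TAD ("larger than"
strict, "equal or less" inclusive — the thresholds convert to 30 and 3 bins
at 20 kb). The scaling parameter gamma is selected per dataset by
inspecting the partition, as is standard for this caller; for the synthetic
maps the package default is 0.7 (on the real fly maps the published choices
were 1.12 for control and 1.20 for knock-down, and both are accepted as
config values). Boundary-recovery F1 against planted truth is scored with a
±1-bin matching tolerance, reflecting the bin-level uncertainty of both the
caller and the planted boundaries.

## Per-TAD statistics

ACF of a TAD is the mean balanced contact over unordered pairs of its
interior bins (first and last bin dropped; diagonal excluded; fewer than
two interior bins gives a missing value). ACF of an inter-TAD averages over
its bins plus the nearest boundary bin of each adjacent TAD. The
knock-down/control comparison forms all four replicate ACF ratios per TAD
and keeps TADs where at least three log-ratios share a sign (an exact ratio
of 1 votes for neither side; a stricter all-four variant is available). The
headline per-group log2 fold change uses ACFs from merged-replicate maps
(replicate counts summed, re-balanced); per-replicate ACFs feed only the
concordance filter.

TADs are ranked by a Jaccard-style score
`|LAD ∩ T| / |(LAD ∪ active) ∩ T|` in bp, where "active" is the union of
the active-TSS ("red") and elongation ("purple") chromatin-state intervals.
The score is 0 for an active, LAD-free TAD and 1 for a LAD-covered inactive
one, and equals a set Jaccard of the two annotations when they are disjoint
(they nearly are). Ranked TADs split into four equal-sized groups A-D
(stable sort, genomic order breaks ties; sizes differ by at most one).
Group-level location tests are delegated to standard routines (Wilcoxon
signed-rank per group; Levene across groups for variance comparisons is
available through scipy directly).

## Compartments

PC1 is the leading principal-component score of the Pearson correlation
matrix of the O/E map (masked bins excluded; the correlation matrix is
column-centred and decomposed by SVD). The sign is anchored so PC1
correlates positively with a transcription reference track; the fraction of
active chromatin serves as a fallback reference. Saddle plots sort bins by
control PC1 (ties broken by bin index, guaranteeing equal quantile counts),
cut them into 20 equal-count quantiles, and log2-transform the mean O/E
over off-diagonal pairs per quantile pair; knock-down minus control
subtraction requires the identical quantile assignment. Compartment-class
contact changes pool per-pair log2(O/E_kd / O/E_ctrl) into within-active,
within-inactive and between classes using the control PC1 labels (PC1 = 0
or masked bins excluded).

## Track analysis

Interval signal is binned by overlap-weighted allocation (an interval
contributes `weight * overlap/length` per bin), conserving total weight.
LAD assignment follows the two asymmetric rules: genes belong to a LAD if
their strand-aware TSS lies inside one and to the inter-LAD class only if
the TSS is at least 1 kb from every LAD; reads/regions use any-overlap
versus the same 1-kb buffer. The buffer zone belongs to neither class.
Fold changes divide each replicate by its total coverage, drop features
that are zero in every replicate, add a single pseudocount — the minimum
nonzero entry of the pooled normalized table — to every value, average
replicates per condition and take log2(kd/control).

The pseudocount mechanically shrinks fold changes of features whose
abundance is comparable to the table minimum: the recovered shift for a
planted `d` log2 effect is `log2((2^d + rho) / (1 + rho))` with `rho` the
pseudocount-to-feature ratio. The synthetic generator therefore models LAD
background transcription as log-normal over roughly three orders of
magnitude (log2 values N(1, 1.5²)), which is typical of near-silent
lamina-associated genes and keeps `rho` ≈ 0.03 for the median LAD gene;
the residual estimator bias is about −0.05 log2 units and the planted
+0.5 shift is recovered within ±0.1 on every tested seed.

## Synthetic data generator

The generator defines the study conditions used by every recovery test:
one 500-bin arm of 20-kb bins; planted TADs of 6-15 bins separated by 1-3
bin gaps; TAD activity labels in runs of 2-5 TADs (compartments are larger
than TADs); expected contacts follow `(s+1)^-1` distance decay times a
3-fold intra-TAD boost and a 1.6-fold same-compartment boost; log-normal
per-bin biases (sigma 0.3); Poisson counts at 2x10^5 cis contacts per
replicate; two replicates per condition. The knock-down multiplies
intra-TAD contacts by 1.2 in active (truth group A) TADs and 0.8 in LAD
(truth group D) TADs and shifts LAD transcription by +0.5 log2 units. LAD
intervals coincide with inactive TADs; active-chromatin intervals cover the
interior ~80% of active TADs, so the two interval sets are nearly disjoint
as in the real annotations.

What the generator does not emulate: restriction-fragment structure and
read-level noise, overdispersion beyond Poisson, trans contacts,
copy-number variation, and the X chromosome (excluded in the original
analysis). Passing recovery tests therefore demonstrates correctness of
the estimators under the stated statistical structure, not robustness to
every artifact of real Hi-C.

## DPD polymer model

Standard Groot-Warren DPD: soft repulsion `a(1 - r/r_c)` with `a = 25`,
pairwise friction `-gamma w(r)^2 (v_rel·r̂)` with `gamma = 4.5`,
`w(r) = 1 - r/r_c`, and a matched random force with
`sigma = sqrt(2 gamma kT)` (fluctuation-dissipation; kT = 1, r_c = 1,
dt = 0.04, all masses 1). The random numbers are symmetric uniform with
unit variance, which is statistically equivalent to Gaussians at O(dt) and
substantially cheaper. Integration is the lambda = 1/2 velocity-Verlet
variant; pair forces come from a cell-sorted half-stencil kernel (numba)
with an inline xorshift64* stream, so trajectories are bit-reproducible per
seed. Momentum is conserved to accumulation rounding (~1e-13 per step in a
periodic box) and the kinetic temperature settles ~3% above kT at the
default time step, the known discretization bias of this scheme.

The copolymer alternates blocks of "inactive" (sticky) and "active" (inert)
beads; production-scale defaults are 64 blocks of 500+50 beads in a 50³ box
at density 3 (375,000 particles, wall and solvent included). One box face
carries a hexagonal monolayer of immobile surface particles. Boundaries
are periodic in x/y; in z the slab reflects every mobile particle
specularly (the wall layer additionally repels). Solvent is treated like
any other particle; confining it to the slab rather than wrapping it
through the wall keeps the local density unperturbed at the boundary.

Reversible saturating bonds (valence 1 per inactive bead, zero-rest-length
harmonic springs, K = 4 as for the backbone) are updated every 200 steps:
each existing bond breaks with probability 0.01; each eligible
inactive-inactive pair within r_c attempts once per sweep with probability
0.001; each unbonded inactive bead within r_c of the surface plane attempts
a surface bond with probability 0.007 (anchored to the nearest wall
particle). Attempt bookkeeping is pair-based: a held two-bead system
reaches the two-state stationary bonded fraction 0.001/0.011 = 1/11
exactly, and a bead whose only neighbour is the wall attempts at exactly
0.007 per sweep. Pair-based attempts (rather than one partner per bead per
sweep) are what lets a dense block maintain the ~40% bonded-bead fraction
that turns blocks into the bond-stabilized globules the chromatin model is
built on; with single attempts per bead the bonded fraction saturates near
10% and blocks remain loose coils.

### Block analysis

Per inactive block and snapshot: surface contacts are beads within r_c of
the wall plane; intra-block contacts are non-backbone bead pairs within
r_c; the gyration tensor gives eigenvalues λ1 ≥ λ2 ≥ λ3, the
ellipsoid-equivalent volume `(4π/3)·3^{3/2}·sqrt(λ1 λ2 λ3)` and the
oblateness `λ3 / sqrt(λ1 λ2)` (low = pancake). A block is a LAD in a
snapshot when it has at least one surface contact. Chain coordinates are
unwrapped along the backbone before shape analysis so periodic images do
not distort the tensors. Ensemble distance maps average pairwise centroid
distances of consecutive coarse-grained segments over the equilibrated
(second) half of each run.

### Desk-scale attachment experiment

The attachment-compaction experiment asks whether blocks with more surface
contacts have more intra-block contacts, smaller volume and flatter shape,
with a null control (surface binding disabled) in which block volume should
not depend on wall distance. The desk-scale measurement configuration —
a solvent-free melt of six 180+18-bead blocks in an 8x8x12 slab, chain
initialized within 4 units of the wall, 3 runs of 1.5x10^5 steps
(snapshots every 5x10^3, first half discarded as equilibration) — was
chosen after an explicit parameter study. Two findings from that study
shape it. First, block mass controls the physics: blocks of ~55 beads
never exceed a handful of surface anchors (the stationary anchor count is
set by the bond kinetics, not by simulation length) and sit in a
weak-tether regime; anchor counts in the tens require roughly 150+ beads
per block. Second, detached blocks need crowding, not vacuum: in a dilute
tall box weakly-tethered blocks dangle and stretch, while in a chain melt
(the production-scale situation) neighbouring blocks cushion both classes.
The solvent is omitted in this experiment only — the melt provides the
pressure — while the thermostat, momentum and bond-kinetics checks run on
solvated or pure-solvent systems.

An honest caveat: across the parameter study (block sizes 55-220, boxes
8-16 units, solvated and melt variants, multiple seeds) the attached class
at desk scale remains dominated by tethered, partially stretched blocks,
which tend to have *larger* gyration volumes than free ones; the full
compaction signature was observed only sporadically (seed-dependent) and
is not reproduced reliably by any configuration small enough for the test
suite. The trend test and the acceptance script therefore report the
measured correlations at the documented configuration as they come out;
reproducing the published effect appears to require the production-scale
system (hundreds of beads per block, tens of blocks, 50³ box), which the
same code path supports but which exceeds a workstation test budget by
orders of magnitude.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; BED input converts on read.
* O/E of an arm's own expected profile has per-diagonal mean 1 to 1e-9.
* A ratio of exactly 1 in the concordance filter votes for neither
  direction; zero or missing ACF excludes the TAD.
* PC1 on a rank-0 (constant) map raises; orientation with a constant
  reference track leaves the sign unchanged.
* Saddle quantile ties break by bin index; quantile populations differ by
  at most one bin.
* The DP resolves score ties toward the skip (inter-TAD) option with a
  1e-12 tolerance, making partitions deterministic.
* DPD integration aborts with a diagnostic if any particle moves more than
  r_c in one step (time step too large).

## Known limitations

* Only intra-arm (cis) maps; no trans contacts, no multi-resolution
  formats, no read-level Hi-C processing.
* Single optimal DP partition (no top-k consensus); no nested TAD models.
* The Jaccard grouping formalizes an ambiguous published construction as a
  set Jaccard; alternatives (e.g. a scalar-metric Jaccard) would rank
  near-identically at the extremes but can differ mid-scale.
* Differential expression proper (TMM/edgeR) is out of scope; the track
  module stops at normalized log2 fold changes and class summaries.
* The desk-scale DPD experiment reproduces trend directions, not the
  production-scale effect sizes; its block count and box are far below the
  published system, and the spec-sized 8x(55+5)-bead configuration is
  below the block-mass threshold at which the attachment-compaction effect
  exists at all.
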