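# Methods

This note documents the models, conventions and numerical choices behind
gmsimnet, in the order the pipeline applies them.

## Input model

The pipeline consumes already-segmented, spatially normalized gray-matter
intensity maps (NIfTI-1/2). It is agnostic to whether the values are
modulated volumes or tissue probabilities — both are treated as generic
"gray-matter intensity", since the network construction only uses ranks and
within-mask comparisons. Acquisition, segmentation and normalization are out
of scope; the smoothing step (Gaussian, default FWHM 8 mm, converted per
axis with FWHM = σ·√(8 ln 2) so anisotropic voxels get anisotropic σ) is
provided for inputs that arrive unsmoothed. Smoothing is applied to the raw
grid before masking and the mask is re-derived afterwards. All grids are
0-based index-addressed; world coordinates are never used because every
operation is mask/atlas-relative.

## Cube-level network

Nodes are 3×3×3-voxel cubes from a non-overlapping tiling anchored at the
grid origin; a cube survives only if all 27 voxels are inside the
gray-matter mask (a deliberate, deterministic containment rule — no partial
cubes). Each cube's ROI is the majority atlas label of its 27 voxels, ties
resolved to the lowest label and background-majority cubes labeled 0.

Edges compare the 27 *positionally corresponding* values of a cube pair by
Spearman correlation (rank transform within cube, then Pearson; ties get
average ranks). No search over cube rotations or reflections is performed —
the correspondence is fixed by within-cube position. Constant-intensity
cubes have undefined rank correlations; they are flagged and their
similarities set to 0 rather than dropped, so node indexing stays stable.
All cube pairs are compared (a whole-gray-matter similarity network), not
only spatially adjacent ones.

**Permutation threshold.** The null distribution draws random cube pairs
and permutes the within-cube value order of one member, which destroys the
positional correspondence while preserving each cube's marginal intensity
distribution. The threshold is the empirical (1−α) quantile of the null
taken with the *next-order-statistic-up* convention, so the expected
fraction of null pairs exceeding it is ≤ α; with the default α = 0.05 and
n ≥ 200 permutations the expected spurious-edge rate is (slightly below)
5%. Edges use strict inequality (ρ > threshold), breaking ties at the
quantile conservatively. With a finite permutation count the realized rate
fluctuates around its expectation from subject to subject; acceptance
checks therefore bound the mean over subjects with a one-sided sampling
allowance rather than each subject individually. Thresholds are
per-subject; seeds and permutation counts are recorded in the network's
provenance so any run can be reproduced exactly.

## ROI-level network

ROI pairs have unequal voxel counts, so "corresponding voxels" needs a
pairing rule. Each ROI's masked intensities are sorted and linearly
resampled to a common quantile profile of length L = 100. Two profiles are
then rank-transformed **jointly over their pooled 2L values** and the two
rank vectors Pearson-correlated. This pooled-rank statistic is a Spearman-
style measure of distributional similarity: it equals 1 exactly when the
two intensity multisets coincide and decreases as the distributions
diverge. (Ranking each sorted profile separately would be degenerate — any
two increasing sequences are perfectly rank-correlated — which is why the
ranking must be joint.)

Per-pair p-values come from a permutation null that pools the two ROIs'
masked voxels and randomly re-assigns them to the two parcels before
profile construction, p = (1 + #{null ≥ observed})/(n_perm + 1).
Benjamini–Hochberg across all unordered pairs at q = 0.05 defines the
edges. Note the BH floor: with m pairs, a discovery requires
p ≤ q/m at worst, so n_perm must exceed m/q for a lone true edge to be
detectable (the permutation p-value floor is 1/(n_perm+1)).

## Graph metrics

All metrics operate on the binary adjacency. Distances are unweighted
shortest paths (Dijkstra on the sparse adjacency); unreachable pairs are
infinite. Efficiency-family metrics use 1/∞ = 0, so they are well defined
on disconnected graphs; characteristic path length instead averages over
reachable ordered pairs and returns NaN when none exist.

Nodal local efficiency uses the subgraph induced by the *neighbors only*
of node i (i excluded), normalized by N_i(N_i−1); nodes with fewer than two
neighbors contribute 0. A variant that includes node i is available via
`include_self=True`, since both conventions appear in the literature.
Betweenness is Brandes' algorithm (via networkx), reported unnormalized
with a normalized column alongside. Small-worldness is
σ = (C/C_rand)/(L/L_rand) with null statistics averaged over
degree-preserving double-edge-swap rewirings (10× the edge count in swap
attempts per null, 100 nulls by default); σ is undefined at density 0 or 1,
where no rewiring exists. Every metric is validated in the test suite
against independent brute-force implementations (Floyd–Warshall distances,
explicit shortest-path enumeration) on the complete atlas of connected
graphs with n ≤ 6 and on random graphs with n ≤ 10.

ROI aggregation is the arithmetic mean of cube-level nodal metrics over the
member cubes of each of the 90 parcels; parcels without member cubes are
reported missing (NaN), never zero.

## Synthetic cohort

The generator emulates the *structure* of an ADNI-like three-group study
(HC/MCI/AD), not any particular cohort's moments. Per subject, each of 6
ROI modules draws a 27-component template (one value per within-cube voxel
position) and each ROI mixes its module template with an ROI-private one:
S_r = √c·T_m + √(1−c)·U_r, giving exact exchangeable inter-ROI latent
correlation c = coupling[group] within modules (defaults HC 0.2, MCI 0.5,
AD 0.8) and 0 across. Voxel intensity is offset + amplitude·S_r[v mod 3] +
noise (σ = 1), so the positional cube similarity provably recovers the
coupling; setting the signal amplitude to 0 yields pure iid-noise subjects
for null checks. The per-subject amplitude scales with a latent
(1 + 0.3·latent), which makes network density and mean degree increase with
the latent; cognitive scores (MMSE-like group means 29/27/22) and CSF
columns (Aβ, t-tau, p-tau at ADNI-like pg/mL scales) are linear in the same
latent (default t-tau slope −80 pg/mL per latent SD, i.e. denser networks
carry lower tau), which is what association analyses recover. Demographics
(age ≈ N(73, 6) years, sex Bernoulli(1/2), education ≈ 16 ± 2.6 years)
deliberately overlap across groups. A configurable fraction of subjects
(default 20%) has missing CSF values, exercising listwise handling.

Randomness fans out from one master seed to per-subject substreams
(`default_rng([seed, group_index, subject_index])`), so inserting or
removing a subject never perturbs the others, and identical config + seed
reproduce byte-identical volumes and tables.

What the generator does **not** emulate: cortical geometry (ROIs are
axis-aligned blocks so cube/ROI containment is exact and capacity is
checkable), partial-volume or segmentation artifacts, spatial
autocorrelation beyond the module structure, scanner effects, and
longitudinal drift. Passing tests therefore demonstrate that the pipeline
recovers known similarity structure and controls its error rates under its
own assumptions — not that those assumptions hold for any real scanner's
data.

## Statistics

"Adjusting for age, sex and education" is implemented uniformly as linear
residualization: group terms enter a linear model with the covariates
(ANCOVA F-test for the group factor; adjusted t for two-group contrasts),
and associations are Spearman correlations of the residuals of both
variables after regressing each on the covariates — reconciling the
regression formulation with rank-based reporting. Associations are run
within each diagnostic group (pooling groups would confound within-subject
slopes with group-level shifts) and left uncorrected by default, with
`bh_fdr` available as an opt-in. FDR families mirror the analysis
structure: nodal/global metrics form one family per ANCOVA call; edges form
one family per group-pair comparison; post hoc contrasts are emitted with
both raw and BH-corrected p-values. Kruskal–Wallis uses tie correction
(neuropsychological scales are discrete). Sex is a single binary covariate.
Every result row carries the n actually used after listwise deletion;
strata with fewer than 10 complete cases yield NaN rather than a silent
estimate.

## Pipeline and reproducibility

A single YAML config drives simulate → extract → metrics → compare. Stage
seeds derive from the master seed by hashing the stage name (CRC-32), so
adding a stage never shifts another's stream; per-subject extraction seeds
are offsets of the stage seed in sorted-subject order. The manifest records
the config snapshot, tool version, stage seeds and elapsed times, and a
SHA-256 digest of every output file; re-running a config reproduces
identical digests. Config validation is exhaustive and runs before any
stage executes.

## Default problem sizes

Desk-scale defaults — a 24³ grid (512 cube nodes), 90 ROIs, 20 subjects per
group, 200 permutations for the cube threshold — were chosen so that a full
three-group run completes in minutes on one CPU while every planted effect
in the test suite remains comfortably detectable; the module structure
(6 modules of 15 ROIs) keeps roughly 1/6 of cube pairs "truly" coupled.
Production-scale inputs (e.g. 1–2 mm whole-brain grids, 1000+ permutations)
use the same code paths; only the loops over ROI pairs in the FDR edge test
grow quadratically.

## Known limitations

- The ROI-level edge test measures *distributional* similarity of parcel
  intensities; under the synthetic model all parcels share the same
  marginal distribution, so module coupling is recovered at the cube level,
  not the ROI-profile level.
- Negative-similarity edges are effectively excluded whenever the
  permutation threshold is positive; the threshold applies to signed ρ.
- Weighted-network analysis is limited to nodal strength on the
  pre-threshold similarity matrix (opt-in); path-based weighted metrics are
  not implemented.
- Cross-subject covariance networks (one network per group) are out of
  scope; all networks are single-subject.
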