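# Methods

`sadnet` analyzes signed functional-connectivity networks built from
ROI BOLD time series recorded under two back-to-back paradigms — a
neutral epoch followed by a spatial working-memory block, and a sadness
provocation followed by an identical block — and asks which network
nodes mediate the interaction between the dorsal (cognitive) and
ventral (emotional) subnetworks, and how that interaction depends on
the intensity of the sadness a subject reports.  Because the recordings
the design presumes are not publicly deposited, the package ships a
synthetic cohort generator whose defaults encode the study conditions;
everything downstream is tested against what the generator plants.

## Network model

**Nodes.** Twenty bilateral ROIs (packaged table with MNI peak
coordinates): a dorsal set — dlPFC, iFG, mSFG, IPS, PCG — and a ventral
set — sACC, mFP, mOFG, amygdala, hippocampus.  Each ROI is conceptually
a 5×5×5-voxel cube around the peak; `extract_roi_signal` implements the
detrend-then-average extraction for volume input.

**Edges.** Pearson correlation between the two ROIs' conditioned
signals over all 160 volumes of a paradigm (no epoch splitting: the
band-pass removes the slow paradigm structure instead).  Group-level
analyses use the plain entrywise mean of subject matrices (a Fisher-z
variant sits behind a flag).

**Communities.** Partitions maximize the signed-modularity quality

    Q = (1/v⁺) Σᵢⱼ (w⁺ᵢⱼ − γ⁺ e⁺ᵢⱼ) δ(cᵢ,cⱼ)
        − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − γ⁻ e⁻ᵢⱼ) δ(cᵢ,cⱼ)

with w⁺/w⁻ the positive/negative weight parts, s±ᵢ their node
strengths, v± their totals and e±ᵢⱼ = s±ᵢ s±ⱼ / v±.  With nonnegative
weights and γ⁺ = 1 this is classical Newman–Girvan modularity (tested
against networkx).  Defaults γ⁺ = 1, γ⁻ = 0.45; `scan_gamma_neg`
sweeps γ⁻, reports the Q contrast between paradigms and flags
partitions that keep a caller-supplied anatomical grouping (cortical
vs subcortical) separate.

Since Q = Σᵢⱼ Bᵢⱼ δ(cᵢ,cⱼ) for a fixed pairwise gain matrix B, the
optimizer evaluates moves exactly: greedy local moves
(first-improvement over a seeded random node and candidate order)
alternate with best-gain community merges until a full cycle leaves the
partition unchanged, best of `n_restarts` seeded restarts.  For graphs
of ≤ 12 nodes `exhaustive_best_partition` enumerates all set partitions
as an independent oracle; on random signed 5–8-node matrices the greedy
optimizer matches it (acceptance check, 50+ instances).  Supplying
known candidate partitions guarantees the result is never worse than a
candidate.

**Node roles.** Per subject, the matrix is binarized by keeping edge
(i,j) iff |wᵢⱼ| ≥ (t/100) · max|w| of that subject's own matrix
(negative edges count; sign matters only for modularity and edge
statistics).  The threshold t is the grid value (default 5–95 % step 5)
maximizing the across-node variance of subject-averaged degree, ties
toward the smaller value.  Degree is binary; the participation
coefficient is Pᵢ = 1 − Σₛ (k_is/kᵢ)², 0 for isolated nodes, with the
group-level partition (detected on the mean matrix) applied to every
subject's graph.  A **connector hub** has node-mean degree above the
across-node mean + 1 SD (SD with ddof = 1 across the 20 node means)
*and* node-mean participation above the across-node mean.  A
permutation check (degree values shuffled across nodes within each
subject, add-one p) accompanies every hub flag.

## Preprocessing

Order: per-ROI linear detrend → common-signal regression → band-pass.
All three steps are recorded in the output metadata, and the regression
can be disabled for sensitivity analyses.

* **Detrend** and **common-signal regression** are least-squares
  projections; both are idempotent, and residuals are exactly
  orthogonal to the regressors.  The common signal is the per-time-point
  mean over the analysis ROIs (not a whole-brain global signal); its
  removal is known to push correlation distributions negative, which is
  visible throughout the synthetic results (planted between-module
  r = −0.15 measures near −0.3 after regression).
* **Band-pass** 0.018 Hz to the nominal upper edge 0.26 Hz.  At TR = 2 s
  the Nyquist frequency is 0.25 Hz, so the upper edge is capped at
  0.99 × Nyquist and the filter effectively acts as a high-pass above
  0.018 Hz; `bandpass` itself refuses bands at or beyond Nyquist.  The
  default implementation is an exact orthogonal projection: the
  out-of-band Fourier modes plus an intercept and a linear ramp are
  removed by least squares.  This choice is zero-phase, has unit
  passband gain, and — crucial for only 160 samples — is exactly
  idempotent, so reapplying the pipeline is a no-op; a 4th-order
  forward-backward Butterworth (`design="butterworth"`) is available,
  but its transition bands erode 3–6 % RMS per reapplication.
  Contract: gain ≥ 0.9 at 0.1 Hz, ≤ 0.2 at 0.005 Hz (measured: ≈ 1.0
  and ≈ 0.04).

## Statistics

* **Interaction ANOVA.** Balanced two-paradigm repeated measures with
  subject as a blocking random factor nested in a two-level group:
  group is tested against between-subject variation, paradigm and the
  paradigm × group interaction against the within-subject residual.
  On this design the Type I/III distinction is immaterial for the
  interaction; F values match pingouin's mixed ANOVA to machine
  precision.  A permutation variant flips each subject's paradigm
  labels (sign-flips of the per-subject difference).
* **Hub-edge tests.** For each connector hub, the 19 incident edges'
  correlations enter the interaction ANOVA; Benjamini–Hochberg FDR at
  α = 0.05 across the 19 tests; FDR-significant edges get follow-up
  two-tailed paired t-tests across paradigms within each group.
* **Permutation machinery.** All permutation p-values use the add-one
  rule p = (b+1)/(n_perm+1), default n_perm = 1000, fully reproducible
  by seed.  `compare_group_correlations` contrasts an x–y Pearson
  correlation between groups with a label-shuffling null and a
  configurable tail.
* Calibration: under the null, both the interaction ANOVA and the
  permutation test reject at 3.9–5.4 % at α = 0.05 over 1000 replicates
  (recomputed by `scripts/acceptance.py`).

## Synthetic cohort: what it emulates, and what not

Defaults are the study conditions: 22 subjects (12 high- / 10
low-sadness), two paradigms of 160 volumes at TR = 2 s, 20 ROIs,
20-trial WM blocks with exactly 5 catch trials (25 %, round half up,
positions drawn without replacement from a 16-position grid), and
bimodal ratings (components 6.14 ± 0.35 and 4.85 ± 0.45 on the 0–7
scale, weight 12/22; the cohort draws each subject's rating from their
group's component and redraws the vector until the above-the-mean split
reproduces the intended labels).  Error probabilities (p_error = 0.12,
p_inhibition = 0.27) put block scores near 3 errors / 1.3 inhibition
errors; reaction times are truncated-normal around a per-subject mean
(≈ 1.33 s).

Time series are correlated Gaussian innovations with the cell's target
correlation, AR(1)-colored (coefficient 0.3, identical across ROIs so
zero-lag correlations are preserved), plus a shared AR(1) nuisance
(amplitude 1.0, added identically to all ROIs — exactly what
common-signal regression removes) and per-ROI linear drifts (slope SD
0.01/volume).  A single master seed spawns per-subject substreams.

Target matrices: within r = +0.30, between r = −0.15 on the
dorsal/ventral split; hubs dlPFCl and mFPl get 0.40 within / 0.35
cross couplings so their degree clears the mean + 1 SD rule under |w|
thresholding.  Condition effects: in the sadness paradigm, both groups'
within-module couplings weaken by 0.06 and between-module
anticorrelations strengthen by 0.02 (a net decrease in integration),
and the high-sadness group additionally shifts sACCl–dlPFCl by −0.30
and sACCl–mFPl by +0.20.  Matrices are repaired to the nearest
unit-diagonal PSD matrix by eigenvalue clipping and rescaling, with the
repair magnitude logged (zero for the defaults).

The segregation shift is planted as within-module weakening rather
than as a purely between-module strengthening for a measured reason:
after common-signal regression the total negative correlation mass is
pinned (the residual mean is zero), and a *stronger planted*
anticorrelation shrinks the common signal, hence *less*
regression-induced anticorrelation — the planted contrast inverts.
Weakened within-module coupling survives the regression and yields a
consistently positive Q contrast (sadness > neutral) at γ⁻ = 0.45,
of order +0.003 at a baseline Q ≈ 0.63.  Note the synthetic regime is
cleaner than real recordings (Q here ≈ 0.63 vs ≈ 0.26 on real data),
so contrast magnitudes are not comparable across regimes.

What the generator does *not* emulate: hemodynamic-response dynamics,
task-locked activations, motion or physiological artifacts beyond one
shared AR(1) nuisance, spatial voxel structure (except the constant
cubes used by extraction tests), or heavy-tailed/heteroscedastic BOLD
noise.  Passing recovery tests therefore demonstrates the analysis
chain is correct and calibrated under its own assumptions, not that it
would recover structure from arbitrary real data.

## Numerical choices and degenerate inputs

* Modularity needs v⁺ > 0 (all-negative graphs are rejected); the
  matrix diagonal must be zero — connectivity matrices drop their unit
  diagonal before graph analysis.
* Tie-breaks: optimizer moves require a strict gain (> 1e−12); threshold
  selection ties go to the smaller threshold; ratings exactly at the
  group mean go to the low group, values at the median to "low" in
  median splits.
* All-equal |w| spectra make degree variance flat: the smallest grid
  value is returned with a warning.  Zero-variance ROI signals are an
  error naming the ROI; a zero-variance common signal skips regression
  with a warning (relative guard so numerically-zero residual means do
  not re-fire).
* Missing WM responses count as errors and are excluded from mean RT.
* Recovery simulations in tests and the acceptance script use 20 cohort
  replicates, hub permutation checks at n_perm = 200 and calibration at
  1000 replicates with n_perm = 199 — sizes chosen to keep the whole
  suite fast while leaving the binomial noise on the reported rates
  well inside the asserted margins.

## Known limitations

* Louvain-style greedy optimization is exact on the tested small-graph
  ensemble and recovers planted 20-node structure, but carries no
  global-optimality guarantee on adversarial instances.
* The split-plot ANOVA assumes homoscedastic within-subject residuals;
  the permutation interaction test is the distribution-free fallback.
* Group-specific shifts on sACC edges leak slightly into other edges
  through the common-signal regression (the spillover shows up as an
  occasional extra FDR rejection); measured null-edge rejection stays
  below α on average.
* `compare_group_correlations` expects per-subject scalar pairs
  supplied by the caller; the package does not compute GLM activation
  contrasts (voxelwise modeling is out of scope).
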