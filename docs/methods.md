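# Methods

`connectoscope` reimplements a complete resting-state fMRI group-analysis
chain — voxelwise amplitude and homogeneity metrics, a 90-node functional
connectome with graph-theoretic topology, covariate-adjusted group
statistics, and multi-kernel SVM classification — and exercises it
entirely on synthetic BOLD cohorts with planted, recoverable group
effects. This note documents the models, the numerical conventions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic cohorts

Real resting-state cohorts of this kind are rarely shareable, so the
generator is a first-class, tested component rather than a fixture.

**Node signals.** Each subject's 90 node signals are white Gaussian noise
masked to the analysis band (0.01–0.08 Hz) in the frequency domain,
standardized, and mixed by the symmetric matrix square root of a target
correlation matrix. The expected covariance is then exactly the target
and all spectral power lies in the band by construction. The default
group-level target is block structured (8 communities, within-block
r ≈ 0.35, background ≈ 0.08, eigenvalue-repaired to a valid correlation
matrix), which gives thresholded graphs realistic clustering, modularity
and small-world topology (σ > 1 across the sparsity grid).

**Between-subject variability.** Each subject's target is
C_i = C_group + B_i B_i′ − E[B B′] with B_i a 90×2 Gaussian factor matrix
(then diagonal-renormalized), i.e. a centered rank-2 Wishart
perturbation. This keeps E[C_i] = C_group — planted group effects survive
in expectation — produces a per-edge Fisher-z dispersion of about
`subject_z_sd` (default 0.2, the order reported for test–retest FC
variability), and stays positive definite. Unstructured i.i.d. edge
noise of comparable size is not representable by any valid 90-node
correlation matrix: its spectral radius (≈ 2·0.2·√90 ≈ 3.8) dwarfs the
smallest eigenvalue of any realistic target, and projecting back to the
positive-definite cone destroys planted effects (we measured a planted
Δz of 0.5 shrinking to ≈ 0.2). Empirical between-subject FC variability
is itself dominated by a few global modes, which the low-rank model
mimics.

**Voxel rendering.** Parcels are Voronoi cells of farthest-point-sampled
seeds on the interior of the voxel box (convex, hence contiguous). Each
voxel in parcel l carries amp(l)·s_l plus independent Gaussian noise
scaled so the node signal explains exactly the parcel's coherence
fraction (default 0.6; coherence 1 means identical voxels, 0 means pure
noise at `noise_sd`). Group 1 ("patients") receives multiplicative
amplitude factors, coherence deltas, and additive Fisher-z connectivity
deltas (applied to the group target in z-space and back-transformed;
values pushing |r| ≥ 0.999 are rejected). Linear drift (per-voxel random
slopes), two band-limited confound series ("white matter", "CSF") added
globally, and smoothed-random-walk motion traces give the preprocessing
stage real work and make motion-QC paths exercisable.

**Covariates** are drawn per group from truncated-normal/Bernoulli models
whose defaults match a typical middle-aged endocrine-clinic cohort
(age ≈ N(41–42, 11–14²) on 18–60, education ≈ N(13–15, 2–3²),
BMI ≈ N(24–25, 3²), patient group more female). Calibration simulations
that require exchangeable groups use a variant with identical group
distributions, since systematic covariate differences are themselves a
group effect.

**What the generator does not model:** hemodynamic-response convolution,
scanner artifacts, physiological (cardiac/respiratory) noise, spatial
normalization geometry, site effects. Passing tests therefore show the
*analysis machinery* is correct and calibrated for band-limited
correlated Gaussian signals; they do not certify performance on real
scanner data.

## Preprocessing

Per run: drop the first 10 volumes; voxelwise least-squares removal of
intercept + linear trend; ideal FFT-mask bandpass (0.01–0.08 Hz) —
idempotent and exactly testable, matching the convention of the usual
resting-state toolchains; regression of six motion parameters, the WM
and CSF confound series, and the whole-brain mean signal (regressors
filtered like the data). Motion QC excludes a run iff any translation
exceeds 3 mm or any rotation exceeds 3° — *strictly* exceeds, and
either-limit suffices. Excluded runs are reported in the QC table, never
silently dropped.

ALFF and fALFF are computed on the detrended, nuisance-regressed but
**not** bandpassed branch: fALFF's denominator is the full spectrum, and
on bandpassed data the ratio degenerates to ≈ 1. ReHo and connectivity
use the bandpassed branch.

## Voxel metrics

The one-sided sqrt-periodogram amplitude at bin k is |X_k|/√T; the DC bin
never counts. ALFF is the mean in-band amplitude; fALFF the in-band sum
over the full-spectrum (DC-excluded) sum, in [0, 1]. ReHo is Kendall's
coefficient of concordance W = 12·Σ(R_t − R̄)²/(m²(n³−n)) over a voxel
and its in-mask neighbors (default 27-neighborhood; 7/19 configurable;
midranks for ties), computed fully vectorized from time ranks. Ordering
follows the standard convention: ALFF/fALFF smooth the 4D data *before*
the spectrum; ReHo computes first and smooths the *map*. Smoothing is a
separable Gaussian with σ = FWHM/(voxel·2√(2 ln 2)) per axis, truncated
at 4σ and renormalized (constant fields are fixed points; FWHM 6 mm, 3 mm
voxels by default). "Z-standardization" of a finished map is within-mask
(x − μ)/σ — an amplitude map is unbounded, so a variance-stabilizing
atanh is undefined; this matches the convention of the standard
toolchains.

## Connectome and graph topology

Node series are parcel means of cleaned BOLD; their Pearson matrix is
thresholded by sparsity S (fraction of the 4005 possible edges retained,
ranked by |r| with lexicographic tie-breaks) over the grid
0.05 ≤ S ≤ 0.50, step 0.01 (46 nested graphs, floor(S·4005) edges each).
Ranking by absolute correlation retains strong anticorrelations; the
Fisher-z copy clips |r| at 1 − 1e-7 to keep classifier features finite.

Per graph: modularity Q (greedy CNM agglomeration, deterministic),
global efficiency (mean 1/d, 1/∞ = 0), local efficiency (mean over nodes
of the neighbor-subgraph global efficiency), clustering Cp (mean nodal
clustering; degree < 2 contributes 0), characteristic path length Lp
(mean over *reachable* pairs — low-sparsity graphs are routinely
disconnected), and the nodal set: unnormalized betweenness (fractional
credit over tied shortest paths), degree, nodal clustering, nodal
efficiency, nodal local efficiency, nodal shortest path (mean finite
distance). γ and λ normalize Cp and Lp by their means over
degree-preserving Maslov–Sneppen double-edge-swap null networks
(defaults: 100 nulls, 10×edge-count swaps, bounded attempts, never
introducing self-loops or multi-edges); σ = γ/λ exactly. Each metric
curve is summarized by its trapezoidal AUC over the grid.

BFS distances, neighbor-subgraph efficiencies and the swap loop are
numba-compiled; betweenness and CNM modularity use igraph's C core.
All metrics except Q/γ/λ/σ are verified exactly against a brute-force
Floyd–Warshall/path-counting oracle on every connected graph with ≤ 6
nodes.

## Group statistics

Voxelwise model: value ~ intercept + group + age + sex + education + BMI,
two-sided t on the group coefficient (df = n − K − 2). Cluster
correction permutes group labels (covariates stay attached to subjects),
recomputes the adjusted t-map per permutation through the exact
Frisch–Waugh residualization identity, thresholds |t| at the two-tailed
voxel p, labels 6-connected (faces-only) components, and keeps observed
clusters exceeding the (1 − cluster_p) quantile of the permutation
max-cluster-size null (defaults voxel p 0.01, cluster p 0.01;
permutation count configurable, 1000 by default against the study-scale
10,000). Positive and negative suprathreshold voxels are clustered as
one mask; adjacent opposite-signed clusters can merge (rare, noted as a
convention). Two caveats established by simulation and reflected in the
calibration tests: cluster-size inference presumes smooth maps
(unsmoothed independent-voxel fields make the max-cluster statistic
degenerate), and naive label permutation becomes conservative when
covariate distributions differ between groups — the calibration null
therefore uses smoothed maps and exchangeable covariates. Network-metric
AUCs are compared by two-sample t-tests (covariates optional, off by
default) with Benjamini–Hochberg control within each metric family (the
8 global metrics; each nodal metric's 90 nodes).

## Classification

Three feature blocks per subject: C (4005 Fisher-z edge weights, upper
triangle, fixed lexicographic order), G (8 global AUCs), N (540 nodal
AUCs, metric-major). All seven combinations C, G, N, C+G, C+N, G+N,
C+G+N run through one engine. Within each outer leave-one-out fold:
two-sample t-test selection at p < 0.05 for C and N (G always passes
whole), feature z-scoring by training statistics, per-block linear
kernels trace-normalized to the training count, and a soft-margin SVM on
the convex kernel combination Σβ_m K_m. An inner LOOCV over the training
subjects picks (cost C, weights β) from C ∈ {2⁻⁵…2⁵} and a simplex
lattice of step 0.1 by default (tests use reduced grids). Consensus
connections are the C features selected in every outer fold. Sensitivity
treats patients as positive; the ROC area is the rank statistic of the
decision values.

Three design choices here deserve explanation, all motivated by
small-sample LOOCV pathologies that surfaced in null simulations:

1. **Selection is refit inside every inner fold.** If the outer fold's
   selection is reused inside the inner loop, every kernel built from
   t-selected features separates the training subjects almost perfectly
   (the selection saw them), the inner criterion saturates, and
   hyperparameter choice degenerates to tie-breaking.
2. **Every training set is balanced** by dropping the highest-index
   surplus subjects of the over-represented class. LOOCV training sets
   of a balanced cohort are imbalanced by exactly one subject — always
   against the held-out subject's class — and margin classifiers plus
   tuning exploit that composition signal; in simulations the
   permutation-null accuracy reached 0.6–0.9 without this control. The
   drop rule is deterministic and label-blind. The SVM additionally uses
   balanced class weights for genuinely unbalanced cohorts.
3. **One-standard-error rule** for the inner choice: among
   configurations within one binomial standard error of the best inner
   accuracy, the smallest cost and then the lexicographically smallest
   weights win. A per-fold argmax over near-tied noisy inner scores
   couples the chosen configuration to the fold (folds share all but two
   subjects) and biases the outer estimate.

Even so, leave-one-out fold outcomes remain strongly correlated through
the shared training data: the per-cohort accuracy of a *null* cohort has
a standard deviation near 0.13 however many folds are pooled. Chance-
level checks therefore compare the mean over independent label
permutations against 0.5 using the empirical spread of the permutation
accuracies; a plain binomial interval on pooled fold counts would be
anticonservative at any number of repeats.

## Pipeline and reproducibility

`connectoscope run --config run.yaml --out DIR --seed N` executes
simulate → preprocess → voxel-metrics → connectome → graph → stats →
classify; stages communicate only through files (uncompressed NIfTI,
TSV, JSON), so any stage can be re-run in isolation via its subcommand.
Every stage draws its seed deterministically from the master seed; the
manifest records the package version, per-stage seeds, a full parameter
echo, and SHA-256 checksums of every output. Identical configs reproduce
byte-identical manifests. Configuration defaults equal the analysis
defaults (drop 10, band 0.01–0.08 Hz, FWHM 6 mm, sparsity 0.05:0.01:0.50,
α 0.05, voxel/cluster p 0.01, motion limits 3 mm/3°); validation
aggregates all problems into one report before any stage runs. The
pipeline always begins from the simulate stage — the package analyses
synthetic cohorts; ingestion of externally acquired data is out of
scope.

## Problem sizes used by the test suite

Chosen so the whole suite runs on one core in well under half an hour:
null-model count 1–3 and C-grid {0.125, 1, 8} / β-step 0.5 in
simulation-heavy tests (package defaults are 100 nulls, 11 costs, β-step
0.1); statistical calibration over 200 null cohorts (8×8×8 grid, 12
parcels, 60 volumes, 26/26 subjects) plus 100 cohorts at 12×12×12 with
500 permutations for the cluster family-wise-error check; classification
recovery over 10 cohorts at the full 12×12×12 / 240-volume / 26-26
geometry with 12 label permutations for the chance check; end-to-end
determinism on the 12×12×12, 52-subject default cohort run twice.
`scripts/acceptance.py` re-runs the planted-effect classification and a
40-cohort null calibration from scratch at the same geometry.

## Known limitations

* Cluster-level calibration degrades for unsmoothed maps and for
  covariates correlated with group (see above); the pipeline applies
  smoothing by default and reports covariate balance in the QC table.
* Greedy (CNM) modularity is deterministic but not optimal; Q values are
  lower bounds on the best partition quality.
* γ/λ/σ at very low sparsity can be noisy when null networks have few
  triangles; the default 100 nulls keep this manageable, the reduced
  counts used in tests do not.
* The packaged node→network lookup is a hand-made approximate assignment
  of the 90 standard anatomical parcels to the 7 canonical cortical
  networks plus a subcortical network; it stands in for an
  overlap-derived template assignment and should be replaced for real
  atlas work.
* Nested LOOCV accuracy estimates on ~50 subjects have large variance
  (correlated folds); confidence statements should come from label
  permutations, not binomial counts.
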