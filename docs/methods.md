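# Methods

This note documents the models and numerical conventions behind `funcgrad`:
what the synthetic generator emulates, the free parameters of each pipeline
stage and their defaults, and the design choices made where the underlying
method leaves them open.

## The synthetic study

### Latent geometry

The generator's ground truth is a set of node coordinates in a
low-dimensional *gradient space*. Seven network centroids (VN, SMN, DAN,
VAN, LN, FPN, DMN) sit at fixed, distinct positions — evenly spaced on the
unit circle in the first two gradient dimensions, zero elsewhere — and each
node is drawn isotropically around its centroid with a per-network spread
(default 0.4 gradient units, giving substantially overlapping networks; a
smaller spread produces a connectome so modular that its top-10 % graph can
disconnect, which real cortical connectomes do not do).

### Factor-model time series

Each scan is generated by a linear factor model: node *n*'s signal is
Σ_g coords[n, g] · F_g(t) + ε, with independent Gaussian noise ε of standard
deviation `noise_sd` (default 1.0, i.e. comparable to the typical signal
power of a node at unit radius — peak pairwise correlations around 0.5,
realistic for cleaned ROI data). The latent factors F are white Gaussian
series band-limited to 0.01–0.1 Hz (so the pipeline's own band-pass does
not destroy the planted structure) and then **sample-orthonormalised** by a
QR decomposition: in-sample the factors have exactly zero mean, unit
variance and zero cross-correlation. Consequences:

- with `noise_sd = 0` the empirical correlation matrix equals the analytic
  factor-model correlation r_ij = cᵢ·cⱼ / (|cᵢ| |cⱼ|) to machine precision;
- with noise, r_ij = cᵢ·cⱼ / √((|cᵢ|²+σ²)(|cⱼ|²+σ²)) holds up to noise
  sampling error only (`analytic_correlation` implements the closed form,
  and the tests verify a 240-point scan against it).

Note the model's one structural blind spot: Pearson correlation is
amplitude-invariant, so the purely *radial* component of a node's position
is invisible to the pipeline — only angular structure in latent space is
recoverable. Planted spread changes are therefore recovered through their
angular component, which is why effect transmission varies somewhat across
networks for any one geometry realisation.

### Condition effect

The EC-vs-EO contrast is planted as per-network spread multipliers and
centroid displacements applied to the EO (reference) geometry. The shipped
default compresses VN and SMN by ×0.85 and displaces the FPN centroid 0.3
units outward from the grand centroid — the *direction* of the reported
eyes-closed findings. The magnitudes have no published values in gradient
units; 0.85 was chosen by a design-stage power analysis so that a
21-subject study detects the compression at the Bonferroni threshold in the
majority of replicate studies, i.e. the planted study is adequately powered
rather than marginal.

### Subject heterogeneity, confounds, retest

Each subject carries a log-normal global spread scale (sd 0.1) shared by
both conditions, so the paired design has realistic between-subject
variance. Confound tables contain three tissue/global regressors (smooth
unit-variance series), six motion parameters (smoothed random walks) and
the Power frame-wise displacement FD computed from them (50 mm rotation
radius; FD[1] = 0 by convention). The subject's scan-mean FD is
mean + z·sd with a per-subject motion propensity z shared by the two
conditions; defaults 0.053 (0.024) mm under EC and 0.044 (0.014) mm under
EO, a typical eyes-closed/eyes-open motion contrast. Motion increments are
rescaled so the realised scan-mean FD (frames 2..T) equals the drawn target
exactly. Confounds leak into the node signals with small random loadings
(sd 0.2) so nuisance regression has something real to remove; because the
same regressors enter the regression, the leak is removed exactly and does
not bias the condition contrast.

Retest designs draw a dispersion-controlling parameter θ_ij = b_i + w_ij
(log spread scale) with σ_b and σ_w chosen so the planted intraclass
correlation σ_b²/(σ_b²+σ_w²) defaults to 0.4 — the boundary between "fair"
and "moderate" reliability. The pipeline-estimated ICC of dispersion values
is attenuated below the planted value by scan-level measurement noise,
exactly as real test-retest ICCs of derived measures are.

### What the generator does *not* emulate

No volumetric artefacts (motion interpolation, susceptibility, smoothing),
no spatial autocorrelation between neighbouring parcels, no heavy-tailed or
non-stationary noise, no genuine neural non-Gaussianity. Passing tests
demonstrate that the pipeline recovers what it claims from data satisfying
its own model; they do not certify performance on real scans.

## Pipeline conventions

- **Band-pass**: ideal DFT filter, inclusive edges (bins with
  low ≤ |f| ≤ high kept, all others zeroed). Exactly idempotent and
  parameter-free; the DC bin is outside any positive band so output is
  mean-free. On the 240-point, 2 s grid the highest passing frequency is
  exactly 0.1 Hz (bin 48 of 480 s).
- **Nuisance regression**: ordinary least squares with an intercept (the
  intercept is required for residuals to be mean-zero, which downstream
  correlation assumes); rank-deficient designs are rejected with the
  collinear columns named.
- **Connectome states**: raw Pearson (symmetric, unit diagonal) →
  z-scored off-diagonal (individual level, to absorb site differences) or
  averaged + Fisher z (template level). The template path averages *raw*
  correlations and applies atanh afterwards; applying atanh to z-scored
  values would be invalid since they exceed ±1. A mean correlation of
  exactly ±1 is clipped to ±(1−1e-7) with a logged warning.
- **Sparsification**: per column, keep the ceil(fraction·N) largest values
  (default fraction 0.1). Ties spanning the cutoff are all kept and logged;
  the output may be asymmetric. Individual matrices destined for embedding
  receive the same sparsification as the template so both embeddings come
  from the same operator family and are alignable.
- **Affinity**: cosine similarity between sparsified connectivity columns;
  negative cosines are clipped to 0 so the Markov operator stays
  non-negative (a global shift was rejected because it densifies the
  graph); diagonal 1. A disconnected affinity graph is an explicit error.
- **Diffusion embedding**: α = 0.5 (Fokker–Planck normalisation) and
  diffusion time 0, i.e. multiscale λ/(1−λ) eigenvector scaling — the
  customary defaults of gradient toolboxes. Eigenvectors are computed via
  the symmetric conjugate of the Markov operator and normalised so the
  trivial eigenvector is the constant 1 (unit norm under the stationary
  distribution). Sign convention: each gradient's largest-magnitude loading
  is positive, making repeated runs bit-identical. Variance explained is
  defined as λᵢ/Σλ over the retained non-trivial eigenvalues (the ratio has
  no universal convention; this one is simple and sums to 1).
- **Procrustes**: column-mean centring, orthogonal rotation/reflection (no
  scaling) minimising the Frobenius distance, template means re-attached.
  Never increases the distance to the template and is idempotent.
- **Dispersion**: computed on the first 2 gradients by default
  (configurable); the within-network aggregator is the sum of squared
  distances to the centroid (a mean-of-squares option is available and the
  choice is recorded in output metadata). Between-network dispersion is the
  mean centroid-to-centroid distance and equals the row mean of the
  pairwise matrix by construction. Network gradient summaries are
  member-node means per gradient.
- **Statistics**: the two-condition repeated-measures F equals the squared
  paired t; the FD covariate enters as an ANCOVA on the paired differences
  with a centred covariate, testing the intercept on (1, n−2) degrees of
  freedom — with 145 subjects this yields the (1, 143) design. The primary
  Bonferroni family is the 14 dispersion comparisons (0.05/14 displays as
  .0036); the pairwise centroid-distance follow-up corrects over its own
  family of 21 network pairs. Negative ANOVA ICCs are reported as computed;
  truncation at zero happens only in the ReML path, where the balanced
  closed form (σ̂e² = EMS, σ̂b² = max(0,(BMS−EMS)/K)) makes iterative
  fitting unnecessary and the ANOVA/ReML identity exactly testable.

## Cross-talk of planted effects

The embedding is a global spectral function of the whole connectome, so a
planted change to one network moves the operator's spectrum and thereby
every network's coordinates: replicate studies with the default effect
reliably show secondary within-network shifts in unmanipulated networks
(e.g. LN, DMN) and broad between-network differences across all seven
networks, alongside the planted VN/SMN compression and FPN displacement.
This is a property of the method, not a bug of the generator — condition
contrasts of gradient dispersion are not localised measurements. The null
configuration (no planted effect) shows no such shifts: the 14 primary
comparisons hold the nominal type-I error (verified by a 200-replicate
Monte Carlo).

## Compact parcellation

The mask partitioner uses randomised region growing: k ≈ size/(1.5·min)
seed voxels per 6-connected mask component, smallest-parcel-first growth
over 6-neighbours, then a repair loop that merges parcels below the minimum
size into their smallest neighbour and splits parcels above 2×min by
farthest-point bisection (balanced two-seed regrowth from a BFS-farthest
pair). This satisfies the two constraints the approach is defined by —
contiguity and max ≤ 2×min — with bounded iteration; pathological masks
(components thinner than the minimum size allows) raise explicit errors.
6-connectivity was chosen over 26 for compactness. The parcel count is
emergent from the minimum size, not fixed. Parcels are mapped to networks
by majority vote over a voxel-wise network label image, ties breaking to
the lowest network index; a parcel entirely outside the labels is an error.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| subjects | 21 | typical single-site sample for this design |
| nodes | 280 (40/network) | smallest connectome whose top-10 % graph is stable; scan-level dispersion noise small relative to the planted effect |
| volumes × TR | 240 × 2 s | an 8-minute resting-state scan |
| band | 0.01–0.1 Hz | resting-state fluctuation band |
| threshold fraction | 0.1 | top 10 % of each column |
| α, t | 0.5, 0 | toolbox-customary diffusion parameters |
| dispersion dims | 2 | the two interpretable macroscale gradients |
| planted ICC | 0.4 | fair/moderate reliability boundary |

The Monte-Carlo suites scale the study down where calibration does not
depend on size: the null type-I study uses 140-node connectomes (200
replicates), and the ICC recovery study uses the scalar one-way model
directly (1000 replicates at n = 21, K = 2). All simulations are pure
functions of (parameters, seed).

## Known limitations

- Dispersion contrasts inherit the global-operator cross-talk described
  above; interpreting a single network's change as localised is unsafe.
- The multiscale λ/(1−λ) scaling makes absolute dispersion values sensitive
  to the leading eigenvalue; comparisons are meaningful within a study, not
  across operators of different sizes or sparsities.
- The ReML ICC closed form assumes complete balanced data; missing cells
  are rejected rather than imputed.
- Only the one-way random-effects ICC family is implemented (no ICC(2,1)
  or ICC(3,1) variants), matching the reliability model used here.
- Surface (vertex-wise) analysis, joint-embedding alignment and subcortical
  structures are out of scope.
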