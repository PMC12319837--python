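# Methods

## The pipeline in brief

`axisflux` estimates, per scanning session, the principal axis of a
subject's functional connectome — the sensorimotor-association (S-A) axis —
and then treats the session-by-session fluctuation of that axis as the
object of study: its per-parcel variability, its relation to day-by-day
hormone and perceived-stress covariates, and the reorganization of
functional networks along it.

### Coherence connectomes

Connectivity is magnitude-squared coherence rather than correlation because
coherence is insensitive to regional differences in hemodynamic response
shape.  Each parcel series is first reduced to the 0.01–0.17 Hz band by
summing MODWT multiresolution detail components over dyadic scales 3–6
(detail scale j covers `[fs/2^(j+1), fs/2^j]`; at TR = 0.72 s the union is
0.0109–0.1736 Hz).  The transform uses the least-asymmetric length-8
wavelet (`sym4` in PyWavelets' naming) with reflection padding to a
multiple of 2^6.

The coherence estimator is Welch-style: Hann-windowed segments of 128
samples with 50% overlap, cross-spectra averaged over segments, coherence
averaged over the passband bins.  Under independence, Welch MSC with `d`
independent averages has `P(C > c) = (1−c)^(d−1)`; we use the
overlap-corrected effective count `d = 1 + (K−1)/2` for K segments at 50%
overlap.  These edge p-values feed a Benjamini–Hochberg step across the
P(P−1)/2 edges at q = 0.05; non-surviving edges are zeroed and the
diagonal is fixed at 0 (self-coherence would otherwise dominate row-wise
thresholding).  The estimator and its null are our documented choices —
any coherence workflow must pick some smoothing, and this one has a
closed-form edge null.

### Diffusion-map S-A axis

Each connectome is sparsified to the top 10% of entries per row (stable
ties toward lower column index; the result is deliberately asymmetric),
converted to a normalized-angle affinity `a_ij = 1 − arccos(ρ_ij)/π` of row
cosine similarities, and embedded by anisotropic diffusion maps: density
normalization `Ã = A / (d^α d^α)` with α = 0.5, row-normalization to a
Markov operator, eigendecomposition via the symmetric conjugate, the
trivial constant eigenvector dropped, and components scaled by
`λ/(1−λ)` at diffusion time t = 0 (by `λ^t` otherwise).  Variance explained
is reported as `λ_k / Σ λ` over the retained components — a toolbox
convention, which is why published variance-explained percentages are not
used as numeric targets here.

The subject's mean connectome is embedded the same way to give a reference;
session embeddings (10 components) are aligned to it by orthogonal
Procrustes **without scaling** — scaling would corrupt the dispersion
statistics computed downstream from loading spread.  The first aligned
component is the session's S-A axis.  Orientation is anchored on network
labels (flip so default-mode mean loading exceeds somatomotor mean loading)
rather than an external template, so synthetic parcellations work; the flip
is applied consistently to the reference and all sessions.

Session QC mirrors how dense-sampling studies exclude corrupted days:
sessions are flagged when their Spearman correlation with the mean axis
falls below a threshold (default 0.5) or their first-component variance
explained sits more than 3 robust SDs (median/MAD) below the session
median.

### Local effects

Per parcel, session loadings are regressed on z-scored covariates (joint
model per covariate set, intercept included), with experimental session as
a random-intercept group and REML estimation.  With exactly one observation
per session — the typical dense-sampling layout — the random-intercept
variance is confounded with the residual variance; attempting the REML fit
there yields ridge-dependent standard errors.  The fitting ladder is
therefore explicit and deterministic: singleton groups → OLS
(`ols_fallback` flag); REML fit whose random-effect variance collapses to
the zero boundary → `boundary_fit` (t equals the OLS t); REML failure →
OLS.  An `ols_ar1` alternative (iterated feasible GLS with AR(1) errors
across consecutive sessions) is available for users who want serial
dependence modelled directly.  Covariates are z-scored within subject so t
statistics are comparable across hormones with different units; two-sided
p-values are BH-FDR corrected across parcels per covariate.

Model presets mirror the standard covariate sets: estradiol + progesterone
(female-predominant), testosterone + cortisol (male-predominant),
estradiol + testosterone (common), and perceived stress alone — stress is
modelled separately by default because its shared variance with hormones
differs by hormone.

### Variability, comparison, decoding

Intra-individual variability is the sample SD (denominator S−1) of each
parcel's loading across sessions.  Between-subject variance comparison uses
classic Levene (absolute deviations from the group **mean**; a config flag
gives the Brown–Forsythe median variant), with the SD difference carrying
direction and BH-FDR across parcels.  Decoding correlates a variability map
with user-supplied parcel-wise feature maps by Spearman rank; inference
spins the subject's map (one shared null serves all features) and BH-FDR
runs across features.

### Dispersion

Within-network dispersion of a session is `D_w(n) = Σ_p (g_p − median_n)²`
over the parcels of network n; between-network dispersion is
`D_b(n,m) = |median_n − median_m|`.  The axis is one-dimensional, so
Euclidean distances reduce to absolute differences; medians of even-sized
groups are the midpoint of the central pair.  Pairs follow the canonical
network order (visual, somatomotor, dorsal attention, ventral attention,
limbic, frontoparietal, default mode), 21 pairs for 7 networks.  Covariate
effects on each measure use the same fitting ladder as local effects, at
Bonferroni thresholds 0.025/7 ≈ 0.004 (within) and 0.025/21 ≈ 0.001
(between); positive t means the covariate accompanies segregation, negative
t integration.

Spatial specificity of a surviving effect is assessed by network-label
spinning: each permutation relabels parcels' networks through the spin
index while loadings stay fixed, the dispersion series is recomputed and
the model refit, giving a null t distribution.  Permutations whose rotation
happens to eliminate a network entirely are skipped (the measure is
undefined there).  A genuinely network-specific effect yields a small p; a
cortex-wide scaling survives relabeling and does not.

### Spin permutations

Spins operate at the parcel-centroid level: per permutation a uniform
random rotation (QR of a Gaussian matrix, determinant corrected to +1) is
applied to left-hemisphere centroids and its sagittal mirror to
right-hemisphere centroids, and each rotated centroid is reassigned to the
nearest original centroid in its hemisphere.  Assignments may be
many-to-one, as is standard for centroid-based spin tests; on coarse
parcellations a small rotation can reproduce the identity assignment, so
the minimum attainable p is occasionally above 1/(n_perm+1).  Permutation
p-values use the +1 correction and are never zero.

## The synthetic-data generator

The generator emulates a dense-sampling study's statistical structure:

- **Parcellation** — each hemisphere is its own unit sphere (as in
  spherical surface registration); left-hemisphere parcels sit on a
  Fibonacci lattice, the right hemisphere mirrors it, and networks are
  contiguous nearest-seed patches, bilateral by construction.
- **Covariates** — the cycle design spans one menstrual cycle across the
  session count: estradiol has a dominant ovulatory peak just before
  mid-series (argmax around day 13 of 29) plus a luteal shoulder, at serum
  levels around 40–250 pg/mL; progesterone is near zero through the
  follicular half and rises to ~5–15 ng/mL in the luteal half.  The diurnal
  design gives morning-level AR(1) testosterone (~100 pg/mL salivary) and
  cortisol (~0.5 µg/dL).  Both designs add integer perceived-stress scores
  in 0–40 with design-specific means (≈8 cycle, ≈10 diurnal).  These levels
  match typical dense-sampling endocrine panels.
- **Latent axis** — a smooth field on the sphere plus network offsets
  (default-mode high, somatomotor low), rank-uniformized to [−1, 1].  The
  uniformization matters: with a clumpy loading distribution the leading
  diffusion eigenvalues become near-degenerate and the first component
  tracks cluster splits rather than the axis.  An even parcel density along
  the axis makes it the single dominant gradient — the property the
  pipeline assumes of real connectomes.
- **Session loadings** — `g_s = g0 + Σ_h β_h z(h_s)`, then per planted
  network a scaling of deviations about the network **median** by
  `1 + γ z(h_s)` (mirroring the dispersion definition), then isotropic
  Gaussian noise.  β is in loading units per covariate SD because
  covariates are z-scored both here and in the fitting code.  The default
  effect sizes (β ≈ 0.05, γ ≈ 0.6, noise SD 0.05 against a loading range of
  ~2) are chosen for test power, not biological realism — no published
  effect-size scale exists for hormone effects on axis loadings.
- **Time series** — a factor model: 12 band-limited (0.01–0.17 Hz) latent
  sources at centers spread along the axis, mixed into parcels with
  Gaussian weights of width 0.25 × the axis range, plus white noise (SD
  0.3 against unit-variance signal).  Parcels with similar loadings share
  sources, so band coherence decays with axis distance and the leading
  embedding of the resulting connectome recovers the planted axis.
- **Smooth null maps** — for spin-test calibration, random directional
  harmonics evaluated at mirrored coordinates for the right hemisphere, so
  mirror-partner parcels get near-identical values (plus 10%
  hemisphere-specific noise).  Bilateral symmetry is essential: the
  mirrored-rotation null spans only a 3-degree-of-freedom orbit, and for
  maps with strong cross-hemisphere asymmetry it is too narrow (we measured
  ~0.24 rejection at α = 0.05).  Real cortical feature maps are strongly
  bilaterally symmetric, which is the regime the generator emulates and in
  which the test calibrates (measured 0.03–0.085 across seeds at 200
  replicates).

What the generator does **not** emulate: hemodynamic response functions,
realistic fMRI noise spectra (scanner drift, motion, physiological noise),
voxel-level structure, and spatial autocorrelation of the *noise* on
loadings.  Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that preprocessing
artifacts in real data are handled.

## Reproducibility and numerics

One global seed is split into named substreams (CRC-32 of the component
name into a SeedSequence), so adding a generator never perturbs the draws
of another.  All generators are bit-reproducible for a fixed seed.
Eigendecompositions use the symmetric conjugate of the Markov operator
(`eigh`), eigenvector signs are absorbed by Procrustes alignment plus the
orientation anchor, and graph connectivity is checked on the symmetrized
support of the thresholded matrix.  Ties in row thresholding break toward
lower column indices so results are permutation-stable.  Degenerate inputs
(all-zero affinity rows, empty networks, constant covariates, < 2 Welch
segments, < 128 timepoints) raise structured validation errors before any
computation.

Simulation sizes: the end-to-end recovery study runs 100 parcels ×
20 sessions × 512 timepoints; spin calibration uses 200 replicates × 200
rotations at 100 parcels; the local-effects null uses 30 seeds × 60
parcels × 29 sessions; the within-family FWER check uses 80 seeds.  These
are the package's chosen problem sizes for its test suite and acceptance
script; larger runs only sharpen the same estimates.

## Known limitations

- The mixed-effects "random session intercept" is structurally unidentified
  in the one-observation-per-session design and resolves to OLS; the flags
  make this auditable rather than hiding it.  Users with repeated sessions
  per day get a genuine REML fit.
- Variance-explained percentages depend on the `λ/Σλ` convention and are
  not comparable across toolboxes.
- Centroid-level spins permit many-to-one assignment; extremely coarse
  parcellations inflate the identity-assignment probability and raise the
  attainable minimum p.
- The Levene comparison assumes sessions are exchangeable within subject;
  serial correlation across consecutive days is not modelled there.
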