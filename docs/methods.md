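# Methods

`tenswood` implements the quantitative analyses used to characterize the
tension-wood response of woody stems and its dependence on ethylene
signaling: Raman microspectroscopic chemotyping of fiber cell walls,
kinematic quantification of stem uplifting, microfibril-angle (MFA)
estimation from azimuthal X-ray diffraction profiles, and
differential-expression set logic with cis-element enrichment. Because the
raw measurements (hyperspectral maps, time-lapse images, diffraction
patterns, RNA-seq reads) are instrument-bound, every input has a synthetic
generator with recorded ground truth; the test suite scores each stage
against that truth.

## Synthetic data: what it emulates, and what it does not

**Spectral maps.** A map is a line/grid scan across three fiber cells
(lumen → wall → lumen), 60–80 voxels at 1 µm steps, each voxel a Raman
spectrum on a ~1 cm⁻¹ grid over 510–1,800 cm⁻¹. Voxel spectra are
non-negative mixtures of four Gaussian-band component spectra — cellulose
(1,096 / 1,120 / 1,376 cm⁻¹), lignin (1,600 / 1,660 / 1,270 cm⁻¹), a
carbonyl-bearing extractives component (1,730 cm⁻¹), and a residual
component of unassigned broad contributions — plus polynomial baseline
drift, noise, and optional single-channel cosmic spikes (10–50× local
amplitude). Layer mixing weights give each component a linearly
independent spatial pattern: the gelatinous (G) layer is cellulose-rich
with matrix-gel residual signal, the middle lamella + S layer (ML+S) is
lignin-rich, and lumina carry only extractive deposits and residual
signal. This independence is what makes the four-component factorization
identifiable; a residual spread uniformly across layers would be
absorbable by the other components and unrecoverable in principle.
Within-layer compositional variability is modeled as ±15% multiplicative
uniform jitter on the mixing weights; the jittered concentrations are the
stored truth, so a noiseless map factorizes exactly (machine precision).

Noise is signal-dependent: the per-voxel standard deviation is
`noise_sd` × that voxel's peak amplitude (floored at 5% of the map
maximum), approximating the shot-noise character of CCD Raman detection.
No instrument lineshape, wavenumber miscalibration, detector etaloning or
fluorescence photobleaching dynamics are modeled; passing tests therefore
demonstrate algorithmic correctness on band-structured mixtures, not
robustness to every instrumental artifact of real spectra.

**Stem traces.** A digitized stem is a constant-arc-length circular-arc
polyline. Segment headings are spread uniformly from 0 to the day's total
turn so the summed turning angle equals the nominal curvature *exactly* at
any point count, and the polyline length equals the stem length exactly —
this makes lift and curvature analytically checkable. Per-genotype
curvature trajectories follow a lagged saturating exponential
`a·(1 − e^(−r(t − lag)))`. Defaults give the ethylene-insensitive (ETI)
genotype a delayed, attenuated response whose final-day lift is ≈48% of
the wild type's. Limitation: for a circular arc, normalized lift is a
fixed function of total curvature, so a ~52% lift reduction implies a
larger curvature reduction — real stems bend non-uniformly and can
decouple the two descriptors in the opposite direction.

**Azimuthal profiles.** The (200)-reflection azimuthal intensity on
φ ∈ [−90°, 90°] (1° steps) is a mirror-symmetric mixture of ±μ Gaussian
pairs: a near-axial G-layer population (μ_G ~ 0–5°) and an inclined
S2-layer population (μ_S ~ 20–40°), plus constant background and noise.
No fiber-geometry or beam-path diffraction physics is simulated.

**DE tables and promoters.** Paired differential-expression tables plant
four gene classes — ethylene-dependent (significant in wild type only),
shared, insensitive-only, and null — with signed log2 fold-changes bounded
away from the cut for passing genes. Promoters are i.i.d. background
sequence (≤2,000 bp) with motif literals planted at recorded positions.

## Spectral preprocessing

The Raman chain is despike → crop (510–1,800 cm⁻¹) → asymmetric
least-squares (ALS) baseline (λ = 5,000, p = 0.001) → total-area
normalization → Savitzky–Golay smoothing (first-order, frame 3). The FT-IR
chain is crop → two-point linear baseline (anchors 812 and 1,809 cm⁻¹) →
area normalization.

* **Despike** (the vendor's cosmic-ray filter is proprietary; this is a
  behavioral stand-in): channels are flagged when the residual against a
  running median (window 5) exceeds 8 robust SDs *and* 3× the local median
  amplitude, then replaced by the local median. The noise scale comes from
  the MAD of first differences — the running-median residual itself is
  zero-inflated and underestimates spread by ~2×. The amplitude guard
  keeps genuine narrow bands intact on low-noise spectra while still
  catching spikes, which tower 10–50× over their local amplitude.
* **ALS baseline** is a Whittaker smoother with second-difference penalty
  and iteratively reweighted asymmetry (w = p above the baseline, 1 − p
  below), iterated to weight convergence (tolerance 1e−8, max 50 sweeps).
  Constants and straight lines lie in the penalty null space and are
  removed exactly. At λ = 5,000 the baseline's stiffness scale is roughly
  λ^(1/4) ≈ 8 channels, so it bulges ~1–2% of peak height under narrow
  bands and more near the unconstrained grid ends; a repeated application
  of the full chain consequently shifts channels by a few percent of the
  output scale. This bias is identical across samples processed with the
  same settings and does not affect between-class comparisons.
* **Area normalization** uses the trapezoid rule on the native grid
  (region configurable; default the full cropped range), interpreting
  "total area" and "total sum" normalization uniformly as unit area.
* **Savitzky–Golay** with order 1 / frame 3 equals the centered three-point
  mean on interior channels; edges use a polynomial fit to the terminal
  window rather than padding.

## MCR-ALS unmixing

`D ≈ C·S` with `C ≥ 0` (n voxels × k) and `S ≥ 0` (k × m), k = 4 chosen by
singular-value screening. Both half-updates are solved as exact
non-negative least-squares subproblems (Lawson–Hanson active set), never
by clipping, so the lack of fit `100·√(Σ(D − CS)²/ΣD²)` is non-increasing
by construction — an asserted invariant. Resolved spectra are
re-normalized to unit area each cycle with the scale moved into C (the
product is unchanged). Iteration stops when the relative lack-of-fit
change drops below 1e−8 (or below 1e−9% absolute); the default cap is 500
iterations. Only non-negativity constraints are applied — no closure or
unimodality.

Initialization is either "purest" (successive-projection selection of the
k most mutually independent voxel spectra — exact when pure voxels exist)
or a matrix of initial spectral estimates. The four-component study fixture
uses initialization transfer — components resolved from one tissue seed
the fit of another — mirroring how the tension-wood solution seeds the
normal-wood fit in practice; with purest initialization a fully mixed
four-component map is subject to rotational ambiguity, and no algorithm
can guarantee recovery of the planted profiles.

The rank screen combines two criteria: the smallest k reaching 99%
cumulative squared-singular-value fraction, extended while consecutive
singular values remain separated by a factor > 1.5 — a minor component can
carry well-structured signal (clearly above the flat noise floor) while
adding < 1% of variance.

## Layer segmentation

Hard k-means (k-means++, n_init = 10, fixed seed) with three clusters on
the MCR concentration rows. Cluster → layer assignment is content-based,
so cluster index permutations cannot change labels: the cluster with the
lowest mean *polymer* (cellulose + lignin) concentration is the lumen —
total signal cannot distinguish empty lumina once spectra are
area-normalized — and of the remaining two, the higher cellulose:lignin
ratio is the inner wall layer (G in tension wood, S in normal wood), the
lower is ML+S. Map-level QC drops maps when any zone has < 5 voxels, fewer
than three clusters are populated, or the minimum between-centroid
distance is below 2.0× the pooled within-cluster RMS spread; k-means
centroids on pure isotropic noise already separate by ~1.2–1.5× the
within-spread, so a threshold of 1 would never drop a structureless map.
Boundary voxels between S and G layers are assigned to whichever cluster
their mixed chemistry favors; no boundary class or spatial regularization
is modeled.

## Chemometrics

PCA is the SVD of the column-centered matrix; R²X per component is the
squared-singular-value fraction (checked against an eigendecomposition
oracle at 1e−10). OPLS-DA (two classes, y coded 0/1 and centered,
mean-centering only — standard for area-normalized spectra) separates the
predictive component from `n_orth` orthogonal components: the predictive
weight is the normalized X–y covariance; each orthogonal component is the
part of the X loading orthogonal to that weight, deflated from X before
the final predictive fit. R²Y is the fitted-y variance fraction; Q² is the
cross-validated counterpart over deterministic interleaved ("venetian
blind") 7-fold splits assigned by row index, with the full model refit on
each training split. With `n_orth = 0` the predictive component reduces to
the first PLS1 component (verified against a NIPALS oracle). If X carries
no class-correlated variation the model degenerates explicitly to zero
scores with R²Y = Q² = 0 rather than dividing by zero. Correlation-scaled
loadings p(corr) are the Pearson correlations between the predictive score
and each channel. Hotelling's T² ellipse uses
`T²crit = 2(n−1)/(n−2)·F(1−α; 2, n−2)` on the score covariance
eigenframe; n = 3 is computed but flagged unstable. The study's original
software-specific R²/Q² values require the study's raw spectra and are
treated as behavioral, not numeric, targets.

## Kinematics

Normalized lift is `(Y_apex − Y_base) / L` with `L` the polyline arc
length — the traced stem's length, not the chord — so |lift| ≤ 1 always.
Curvature is the sum of signed turning angles between consecutive segment
vectors, wrapped to (−180°, 180°], reported as the absolute value of the
sum (180° is a perfect half-circle "C"); consecutive duplicate points are
collapsed at validation. Curvature is rigid-motion invariant; lift is
translation- and scale-invariant and transforms as sin(θ) under rotation
of a straight stem. The trace reader exposes `flip_y` because image pixel
coordinates grow downward while stem height grows upward.

## MFA fitting

`I(φ) = a_G·½[g(φ;μ_G,σ_G) + g(φ;−μ_G,σ_G)] + a_S·½[g(φ;μ_S,σ_S) +
g(φ;−μ_S,σ_S)] + b` is fit by bounded trust-region least squares,
multi-started over μ_S ∈ {15°, 25°, 35°, 45°}; the best residual wins and
near-ties go to the smaller μ_S. Gaussians (not wrapped von Mises) are
adequate because the angles sit well inside (−90°, 90°). The fit is
flagged weakly identified when |μ_S − μ_G| < 2·max(σ) — and note that a
±μ pair with μ < σ merges into a single central maximum, so near-axial
G-layer angles are resolvable only when the G population is narrow
(σ_G ≲ μ_G). The fitted μ values are layer-mean angles of this simplified
symmetric model, not the output of a full fiber-diffraction forward
simulation; correspondence with physically modeled mean MFA is
approximate. Group summaries report mean ± SD per layer per genotype,
excluding fits whose S population weight is < 0.05.

## Regulatory analysis

A differentially regulated gene (DRG) satisfies |log2FC| ≥ 0.5 (inclusive)
and adjusted p < 0.05 (strict). Ethylene-dependent genes are wild-type
DRGs absent from the insensitive line's DRG set; the full Venn partition
is returned and its sizes always sum to the union. IUPAC motifs (TEIL
AYGWAYCT, GCC-box AGCCGCC, ERE ATTTCAAA) are scanned as overlapping
regex character-class matches, 1-based forward coordinates; sequence `N`
never satisfies a concrete motif symbol. Scanning defaults to the forward
strand (the original screen's strand handling is unstated); a both-strands
mode reports reverse-complement hits at forward coordinates. Enrichment of
gene-level motif presence (≥1 hit) in a set against a universe uses the
exact one-sided hypergeometric tail P(X ≥ x), summed from log-domain
binomial coefficients and verified against exhaustive draw enumeration.
No multiple-testing correction is applied across the three motifs by
default. Promoters shorter than 2,000 bp are scanned over their full
length.

## Orchestration and determinism

`run_pipeline` executes chemotype (simulate → preprocess → MCR → segment →
OPLS-DA), kinematics, and regulatory stages, staging outputs in a
temporary directory that is renamed into place only on success. Every
randomized stage derives its stream from the single run seed; the manifest
records a SHA-256 per artifact plus seed, config hash and version, and two
runs with identical seed and configuration are byte-identical. Default
problem sizes — one 70-voxel × 1,291-channel map per genotype, 28-day ×
6-tree trace sets at 1,000 points, 400-gene DE tables, 120 promoters —
keep a full run around a minute on one CPU while preserving the study's
map geometry and spectral range.
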