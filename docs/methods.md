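# Methods

## Pipeline model

The detector treats rhythm classification as image classification of
interval dynamics. A 60-beat window is mapped to the point cloud
(ΔRR[k], ΔRR[k−1]) — 58 points from 59 consecutive differences — and
the cloud, after de-correlation, is summarized by the low-pass band of
a wavelet decomposition. The geometry of the cloud is what carries the
diagnosis: AF gives a diffuse, roughly isotropic cloud; sinus rhythm a
tight cluster at the origin; bigeminy a few discrete clusters far from
the origin; heart block a cross-shaped pattern from interval doubling.

### De-correlation

For consecutive differences of a weakly autocorrelated interval series,
cov(ΔRR[k], ΔRR[k−1]) ≈ −var(RR), so corr ≈ −0.5 regardless of scale.
The transform Y′ = Y + α·sign(X)·|X|^β with α = 0.5, β = 0.75 adds a
monotone odd function of X to Y, rotating the sheared cloud toward
axis alignment. Working in milliseconds matters: the correction term
0.5·|X|^0.75 is ≈ 21 ms at |X| = 150 ms, i.e. comparable to the ΔRR
scale it corrects; in seconds the same exponent would produce a
negligible correction. The signed power is the odd extension of X^0.75
(undefined over the reals for X < 0); it preserves the point symmetry
of the Lorenz cloud, and the transform's odd symmetry
T(−P) = −T(P) is asserted in tests. The lag-correlation magnitude on
i.i.d. intervals drops from ≈ 0.50 to ≈ 0.38–0.42 for ΔRR SDs of
50–200 ms (measured at n = 10⁴); the transform reduces, not
eliminates, the intrinsic correlation.

### Raster and wavelet feature

The (X, Y′) points are histogrammed on a 64×64 grid over ±600 ms per
axis with `floor((c + 600)/1200 · 64)` binning and edge clamping, so
every window contributes exactly 58 counts and no per-image
normalization is needed. 64×64 is the smallest power-of-two raster
that reaches an 8×8 approximation band in three clean dyadic levels
while still resolving bigeminy's cluster separation (bins are 18.75 ms
wide; bigeminy clusters sit hundreds of ms apart).

The 8×8 feature image is the level-3 LL band of a separable 2D
CDF 9/7 decomposition, computed by the standard lifting factorization
(α = −1.586134342, β = −0.05298011854, γ = 0.8829110762,
δ = 0.4435068522, K = 1.149604398) with whole-sample symmetric
extension — the non-expansive irreversible transform of JPEG 2000.
No quantization or entropy coding is applied; compression here is only
dimensionality reduction (4096 → 64). A Haar mode (orthonormal,
periodized) exists solely as a test oracle: its 3-level LL band equals
8×8 block sums divided by 8, which a brute-force block computation
verifies exactly, and its full transform conserves energy to 1e-9.
The lifting implementation is cross-checked against the PyWavelets
`bior4.4` filter bank on interior coefficients.

### Classifier

RBF-SVM with per-feature standardization, both fitted on training data
only (inside each CV fold). Defaults: C = 1, γ = 1/(64 · mean feature
variance) (scikit-learn's "scale"). AF is predicted iff the decision
function is positive; no threshold is tuned, matching a single
operating point. Cross-validation assigns windows to k = 5 folds by a
seeded uniform permutation over all windows; an optional grouped mode
assigns whole records to folds for leakage-aware evaluation, but is
not the default because the reference evaluation splits randomly
across the pooled windows. Class imbalance is not reweighted by
default (`class_weight` is exposed).

Confidence intervals are Clopper–Pearson exact bounds via beta
quantiles: lower = BetaInv(a/2; k, n−k+1), upper =
BetaInv(1−a/2; k+1, n−k). This method reproduces the published bounds
for 79/79 (lower 95.4%) and 328/336 (upper 99.0%); tests verify the
beta formulation against direct bisection of binomial tail
probabilities to 1e-6 for all n ≤ 50.

## Synthetic rhythm generator

The generator exists so the full pipeline is exercisable and its
discrimination claims testable without clinical recordings. The models
are statistical stand-ins for the interval dynamics of each rhythm
class — they are not derived from any recorded dataset:

* **Sinus** — mean RR (default 800 ms) plus two sinusoidal
  modulations: a respiratory component (10-beat period, i.e. slow
  resting respiration ≈ 7.5 breaths/min at 75 bpm) and a dominant
  low-frequency baroreflex component (20-beat period ≈ 0.06 Hz), with
  variance fractions 0.25 / 0.73 plus 0.02 white jitter, total SD
  40 ms by default. The LF-dominated spectrum reflects a resting
  elderly profile in which respiratory sinus arrhythmia is attenuated
  (RMSSD well below SDNN): it produces the strong lag-1
  autocorrelation (ρ ≈ 0.9) and tight Lorenz cluster characteristic
  of real sinus windows.
* **AF** — i.i.d. draws from a shifted lognormal (σ = 0.5) scaled to
  SD 120 ms and shifted to the target mean; lag-1 |ρ| < 0.05.
  Independence across beats is the modeling claim: AF's RR sequence
  is nearly memoryless at this timescale.
* **Bigeminy** — strict 2-periodic alternation of a coupled interval
  (0.7 × mean) and a compensatory interval (1.3 × mean) with small
  jitter (default SD 10 ms): large swings, but at most a handful of
  distinct Lorenz locations.
* **Heart block** — the sinus stream with each beat dropped with
  probability 0.1, merging the two adjacent intervals (interval
  doubling).
* **Sinus arrhythmia** — the sinus model with respiratory-scale
  variability forced ≥ 80 ms (default 100 ms).

Intervals are clipped to (250, 2500) ms. Each spec draws from a
substream keyed by (seed, rhythm), so a dataset is bit-reproducible
and adding a spec never perturbs another's draws.

What the generator does **not** emulate: ectopy within sinus windows,
atrial flutter (no interval-statistics morphology is defined for it
here), gradual rate drift, measurement dropouts/artifacts, or
inter-patient diversity of AF interval distributions. Consequently the
synthetic cross-validation results (sensitivity and specificity ≈ 1.0
on 500 AF + 500 sinus + 200 bigeminy windows) demonstrate that the
feature pipeline separates the *archetypal* rhythm geometries; they do
not estimate clinical performance, which must come from annotated
Holter databases and prospective recordings read through `rr_io`.

## Numerical and design choices

* **Units**: milliseconds end to end; a `--seconds` flag converts on
  read. The de-correlation exponent makes the transform
  scale-sensitive, so unit discipline is part of the contract.
* **Window purity**: a labeled window is emitted only if all 60
  intervals map to one binary label; windows spanning rhythm
  transitions are discarded rather than majority-voted — the
  reproducible reading of "consecutive sequences" of one rhythm.
* **Label mapping**: only the tag `AFIB` maps to AF; atrial flutter
  (`AFL`) and all other tags are non-AF by default, since flutter is
  annotated as a distinct rhythm in the source databases. The mapping
  is a config table (`af_tags`) so flutter-as-AF variants can be run.
* **Edge clamping** in the raster keeps the point count invariant (58
  per window) at the cost of conflating extreme outliers with ±600 ms
  points; at physiological ΔRR this affects essentially nothing.
* **Degenerate inputs**: a constant window produces 58 points at the
  origin, one occupied bin, and a valid feature vector; zero-variance
  features receive unit scale in standardization.
* **Ties/boundaries**: bin index uses floor with the half-open
  convention, so a coordinate exactly at +extent clamps into the last
  bin; x = 0 contributes no de-correlation shift.
* **Problem sizes**: the shipped checks use 1200-window datasets,
  n = 10⁴ interval streams and 100 random oracle images — sizes at
  which every reported statistic is stable to well inside its asserted
  tolerance while the whole suite runs in seconds.

## Known limitations

* The classifier's clinical operating point depends on training data
  this repository does not ship; models trained on synthetic rhythms
  will misclassify rhythms absent from their training set (e.g.
  bigeminy windows read as AF when trained on AF-vs-sinus only).
* Windows are fixed at 60 beats; no sub-window AF onset localization.
* Binary output only (AF / non-AF); flutter detection is out of scope.
* The annotation reader ingests text beat-annotation tables; binary
  Holter formats must be converted externally.
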