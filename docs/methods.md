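# Methods

This note documents the models behind `isletmt`: what the simulator
emulates, how each pipeline stage is parameterized, which choices were
genuinely open and how they were settled, and what passing the test suite
does and does not establish about real data.

## Coordinate and unit conventions

Arrays are ordered `(z, y, x)`, 0-based, with voxel centers at
`(i + 0.5) × voxel_size` per axis. All physical parameters are in
micrometres and converted to voxels per axis, so every operation respects
the anisotropy of confocal sampling (default 3.0 µm Z-step vs 0.5 µm XY
pixels; the XY pixel size is instrument-dependent and configurable, the
Z-step matches whole-spheroid confocal acquisition). Ground-truth cell
centers and nucleus centroids are reported as `(x, y, z)` µm.

## The synthetic microtissue

**Geometry.** `generate_spheroid_geometry` packs `n_cells` spheres with
lognormal radii (mean 3.0 µm, CV 0.15 — typical for human nuclei) into a
ball by rejection sampling against a spatial hash, capped at 10,000
attempts per cell; insertion order breaks ties, and a request whose total
nuclear volume exceeds 60% of the spheroid is rejected outright. Two
scales are used: the *test scale* (~200 nuclei, 40 µm radius, stacks of
roughly 30×176×176 voxels) keeps a full-pipeline run to a few seconds per
stack, which is what the test suite and the acceptance script use; the
*paper scale* preset (`paper_scale_geometry()`: 1700 nuclei, 75 µm radius,
one islet equivalent) matches a reaggregated microtissue of ~150 µm
diameter and runs the same code at ~8× the voxel count. Nuclear packing
density is equivalent at both scales (~8% of the spheroid volume), so
segmentation difficulty is comparable; conclusions from the test scale
transfer to geometry, not to depth-dependent optics (see Limitations).

**Phenotypes.** Each cell is independently β with probability
`beta_fraction` (default 0.55, inside the 40–65% β-fraction range expected
for human islet tissue) and proliferating with a class-specific Bernoulli
probability. The 4-day EdU labeling window is collapsed into this single
cumulative "proliferated during the window" event; no cell-cycle dynamics
are modeled. Baseline proliferation defaults to 0.2% per class,
reproducing the near-zero vehicle-control proliferation of cultured adult
human islet cells.

**Staining amplitudes.** NKX6.1 in β-cells is lognormal (mean 120 a.u.,
CV 0.40 — deliberately broad; per-nucleus NKX6.1 distributions in real
tissue are not well characterized, so this is a stand-in, not a claim),
multiplied by an attenuation factor 0.6 in proliferating β-cells to encode
the reduced NKX6.1 expression of EdU⁺NKX6.1⁺ cells; non-β cells carry a
constant 10 a.u. bleed-through floor. EdU amplitude (150 a.u., CV 0.15) is
nonzero only in proliferating cells; DAPI is 100 a.u. (CV 0.10) in every
nucleus. In addition, a diffuse interstitial DAPI component (20 a.u.)
fills the spheroid ball outside nuclei, modeling the cytoplasmic
background and scatter haze of cleared tissue. This component is what
makes whole-spheroid detection by global thresholding physically possible:
without any in-tissue background the DAPI histogram contains only "nuclei"
and "non-tissue", and no global threshold can delineate the tissue ball.

**Imaging.** Expected images are sums of per-nucleus indicator volumes
scaled by amplitude (plus the interstitial ball), convolved with an
anisotropic Gaussian PSF (σ<sub>xy</sub> = 0.6 µm, σ<sub>z</sub> = 1.8 µm),
plus a constant background (8 a.u.). Noise is Poisson resampling at a
configurable photon gain followed by additive Gaussian read noise
(SD 2 a.u.), clipped to the bit depth. Setting the photon gain to infinity
and the read noise to zero yields the exact expected image, which the
linearity and geometry tests exploit. The Poisson–Gaussian form is the
standard fluorescence noise model; no detector-specific calibration is
implied.

**Dose effects.** Proliferation probabilities follow a Hill curve,
`baseline + (emax − baseline)·d^h/(ec50^h + d^h)`, with defaults
emax<sub>β</sub> = 1.5%, emax<sub>non-β</sub> = 11.5%, EC50 = 1.2 µM,
h = 2.5 over the 0–10 µM dose ladder (0, 1, 3.3, 5, 10 µM). At a β
fraction of 0.55 this saturates at ~6% total proliferation with non-β
proliferation ~7.7× β proliferation, matching the intended 5–10× ratio.
Functional endpoints are drawn lognormally (CV 0.15 per microtissue; real
per-MT dispersion is unknown — reports give SEM only) around
dose-dependent means: stimulated and chronic secretion rise along the same
Hill curve, basal secretion rises linearly with dose, insulin content
decays exponentially, and ATP/caspase are flat (the compound is modeled as
non-toxic). Because stimulated secretion saturates while basal keeps
rising, fold-stimulation peaks at an intermediate dose — with the defaults,
at 3.3 µM — reproducing the qualitative bell shape of the functional
dose-response.

## The analysis pipeline

**Otsu threshold.** The histogram (default 256 bins over [min, max]) is
split at every interior bin edge; the between-class variance
w₀w₁(µ₀ − µ₁)² is evaluated in exact integer arithmetic (bin centers enter
only through an affine map, which cannot change the maximizer, so the
integers 2i+1 substitute for them), and ties break to the lowest edge.
Exact arithmetic makes the result reproducible against an independent
exhaustive search even when adjacent splits are near-tied, which happens
routinely on smooth bimodal histograms. A constant image raises a
degenerate-histogram error.

**Spheroid detection.** The DAPI channel is Gaussian-smoothed (1.5 µm) so
the tissue region rather than individual nuclei dominates the histogram,
then Otsu-thresholded. The threshold must exceed the stack median by 3
robust SDs (MAD-based); otherwise the "foreground" is merely the upper
half of the noise and a no-spheroid error is raised. The mask is closed
with an ellipsoidal element (4 µm physical radius, scaled per axis),
reduced to its largest connected component, and hole-filled per Z-plane.
A foreground below 10,000 µm³ is also a no-spheroid error. On noise-free
test-scale renders the detected mask overlaps the true ball at
Jaccard ≈ 0.93 and underestimates its volume by ~7% (Otsu sits slightly
above the half-edge level, eroding the rim by ~1 voxel); the volume bias
is stable across seeds, so *relative* volume changes over time are
essentially unbiased.

**Dynamic thresholding.** "Dynamic" is implemented as
local-mean-plus-offset: a voxel is foreground when its smoothed intensity
(Gaussian, 1.0 µm) exceeds the mean over a 15 µm window by `offset_k`
robust SDs of the in-mask residuals. Two details matter. The window mean
is *mask-normalized* (sum over in-mask voxels divided by in-mask count):
a plain boxcar near the spheroid surface averages in dark exterior voxels,
depresses the local mean, and flags a spurious interstitial rim. And the
robust SD is taken of the residual (smoothed minus local mean) inside the
mask, i.e. of the noise scale, not of the intensity distribution. The
offset default is `offset_k = 3`: at k = 1 the threshold sits ~1 noise-SD
above the local mean, so on a signal-free channel (EdU at dose 0) noise
alone pushes 3–4% of nuclei over the 50% positive-voxel criterion, two
orders of magnitude above the true 0.2% baseline; k = 3 reduces this false
positive rate to ≈ 0 while leaving true positives (≥ 10× contrast)
untouched. Whether the commercial implementation uses a local mean, local
median, or per-object adaptive rule is not determinable; local-mean is the
documented stand-in, and the window, offset, and smoothing are all
exposed in configuration.

**Nuclear segmentation.** Foreground from the dynamic threshold (inside
the spheroid mask only) is distance-transformed with physical per-axis
sampling; seeds are distance maxima separated by at least 4 µm (an
ellipsoidal footprint — slightly above the mean nucleus radius, the value
that empirically balances split and merge errors at test-scale density),
and a marker-controlled watershed on the negated distance splits touching
nuclei. Labels outside 30–1500 µm³ (plausible human-nucleus bounds) are
discarded and the rest relabeled consecutively. An empty mask yields a
zero-label map, not an error; a window under 3 voxels on any axis is a
configuration error.

**NKX6.1 truncation.** Intensities are clipped to the (1, 99.5)
percentile bounds computed over in-mask voxels, per stack. Order
statistics use the `lower`/`higher` interpolation rules, which makes the
operation exactly idempotent (a second application recomputes the same
bounds). Per-stack application is the default; whether a real screen
would truncate per-well or per-plate is an open choice the configuration
exposes (analyze each group of stacks with bounds you compute once and
pass through the config).

**Marker scoring and colocalization.** A nucleus is marker-positive when
more than 50% of its voxels pass the marker channel's dynamic threshold;
its mean marker intensity is recorded regardless. The proliferating-β set
is exactly the intersection of the β and EdU label sets. Mean NKX6.1
intensity per microtissue averages over β-classified nuclei by default
(the alternative, averaging over all nuclei, is a flag: the averaging
domain of the real readout is ambiguous, and the two differ systematically
because non-β nuclei contribute only the bleed-through floor).

**Percentages and missing values.** pct_prolif_β = 100·N<sub>EdU∩β</sub>/N<sub>β</sub>
and pct_prolif_non-β = 100·(N<sub>EdU</sub> − N<sub>EdU∩β</sub>)/(N − N<sub>β</sub>);
zero denominators produce explicit missing values (`nan` in memory, `NA`
in CSV), never zeros and never exceptions. Count identities
(N<sub>EdU∩β</sub> ≤ min(N<sub>β</sub>, N<sub>EdU</sub>), conservation of
the EdU and β partitions) are asserted on every quantification.

## Statistics

**ROUT, one-sample reduction.** ROUT was published for nonlinear
regression; applied to a single group of measurements the regression model
degenerates to a constant, for which the construction reduces to: center =
median; robust scale (RSDR) = 68.27th percentile of absolute residuals ×
n/(n − 1); two-tailed p-values from the t distribution with n − 1 df on
the studentized residuals; stepping inward from the most extreme residual,
point i (1 = most extreme) is flagged while p_i < Q·(n − i + 1)/n. Groups
under 4 points are returned untouched with a warning. Monte-Carlo
calibration (2000 clean Gaussian samples, n = 12, Q = 0.05) gives a mean
flagged fraction of ≈ 3%, below the nominal 5%, and a planted 15-SD
outlier is caught in 100% of 500 seeds. Outlier removal is applied per
endpoint per dose group — never to proliferating-cell fractions, which are
summarized as measured.

**Dunnett's test.** Group comparisons against the shared vehicle control
use `scipy.stats.dunnett` (the equicorrelated multivariate-t
distribution of the many-to-one statistics, integrated with a fixed
internal seed; repeatability ≈ 1e-3). With a single comparison the
adjustment is vacuous and the adjusted p equals the pooled two-sample
t-test p to within the integration tolerance, which the tests assert;
null simulations put the familywise error rate within Monte-Carlo margin
of the nominal 5%. The one-way ANOVA F/p accompany the table.
Student's t-test is pooled-variance by default (Welch by flag).

**Dose-response tables.** Per endpoint and dose: ROUT-cleaned n,
mean, SEM, outliers removed, Dunnett p versus control, and a peak flag on
the dose with the maximal cleaned mean. Fold-stimulation is derived
per microtissue from its basal/stimulated pair (guarded against
non-positive basal) and summarized like any endpoint. Chronic secretion
is normalized to ng/MT/day by the collection-interval length at
simulation time. All summaries are invariant to record order.

## Reproducibility

Every run writes its resolved configuration, seed, and a manifest of
output files with SHA-256 hashes; identical (seed, config) pairs produce
byte-identical stacks, truth tables, and CSVs. Per-microtissue seeds are
spawned from the root seed by (well-index, replicate) so results do not
depend on plate iteration order or Python hash randomization. Per-stack
analysis failures are logged and skipped (configurable to fail-fast);
they never abort a plate.

## Limitations

- The simulator validates the *algorithmic* chain, not the optics of deep
  tissue: no depth-dependent attenuation, spectral bleed-through beyond
  the constant non-β NKX6.1 floor, clearing artifacts, or cell
  migration/death. Passing recovery tests here shows the pipeline is
  correct on data obeying its stated assumptions, not that those
  assumptions hold for any particular instrument.
- Segmentation accuracy is reported at test-scale density; crowded or
  irregular real tissue will sit closer to the watershed's failure modes
  (merges at < 1.5× radius-sum spacing, splits of strongly elongated
  nuclei).
- The spheroid mask volume carries a stable ~7% negative bias (threshold
  placement at the blurred rim); use relative volume changes, not absolute
  volumes, for time-course claims.
- ROUT's one-sample reduction is a faithful degeneration of the published
  construction, but published software may differ in small-sample details;
  calibration (false-flag rate ≤ Q) is what the tests pin down.
- No mixed-effects donor modeling, no EC50 fitting of real functional
  data, no multi-spheroid stacks beyond largest-component selection, and
  no machine-learned segmentation — all deliberately out of scope.
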