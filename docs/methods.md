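# Methods

`lungdfi` simulates and analyses grating-based (Talbot-Lau) tri-modal chest
radiography of a murine single-left-lung transplantation cohort.  Because no
raw scans of such a study are publicly deposited, the package generates
calibrated digital phantoms, pushes them through a physical forward model of
the interferometer, and applies the analysis chain — retrieval, ROI
quantification, airway classification, paired statistics — to the simulated
data.  This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Forward model

A Talbot-Lau interferometer (source/phase/analyser gratings with 10 / 3.24 /
4.28 µm periods; metadata only in this model) produces at every detector
pixel a sinusoidal *stepping curve* as one grating is scanned over `M`
positions:

    I_k = a0 · (1 + V · cos(2πk/M + φ)),  k = 0 … M−1.

A sample modifies the three curve parameters per pixel:

    a0 = N₀ · T,   V = V_r · exp(−ε),   φ = φ_ref + Δφ,

with `T ∈ (0,1]` the transmission, `ε ≥ 0` the dark-field extinction
(visibility reduction by small-angle scattering, dominated in the healthy
lung by the alveolar air–tissue interfaces), and `Δφ` the fringe-phase shift
from refraction.  Defaults: `M = 4` steps, 5 s per step (metadata), 35 kVp /
20 W tube (metadata), 50 µm detector pixel, 29 µm effective pixel in the
sample plane, reference visibility `V_r = 0.30` and `N₀ = 10⁴` expected
counts per pixel per step — the last two are not fixed by the emulated
acquisition protocol and are set to values typical of pre-clinical
Talbot-Lau scanners;
both are configuration-exposed.  The model is monochromatic at an effective
energy: no spectral integration, no grating-fabrication physics.  Phase is
imprinted directly as a fringe-phase map in radians; the refraction-angle
conversion constant is deliberately not modelled because the analysis treats
the phase image qualitatively (edge positions), which is invariant to it.
Poisson noise replaces each model intensity by a seeded draw.

## Retrieval

Per pixel, the M samples are reduced by the M-point discrete Fourier
analysis — for a uniform step grid this *is* the least-squares fit of
`a0 + a1·cos(θ_k + φ)` (the test suite checks this against an independent
grid-search fit).  Sample and reference fits combine into:

* absorption  `A = −ln(a0_s/a0_r)`,
* dark-field  `D = −ln((a1_s/a0_s)/(a1_r/a0_r))`,
* differential phase `Δφ = wrap(φ_s − φ_r)` in `(−π, π]`.

The −ln convention for both A and D is forced by the value ranges the
analysis reproduces: a healthy-lung dark-field mean of ≈1.475 is impossible
for a raw visibility ratio.  Negative noise-induced signals are kept
unclipped so ROI means stay unbiased; thresholding happens only in the
downstream detectors.  Pixels with non-positive mean counts or vanishing
modulation amplitude in either scan are excluded through a quality mask (the
sample-amplitude condition `a1_s > 0` is included so every unmasked signal
is finite).  Numerically flat curves (amplitude at round-off level,
`a1 ≤ 10⁻¹² max(a0, 1)`) are snapped to `a1 = 0, φ = 0` so the
zero-amplitude convention is reproducible.  No unwrapping beyond the
principal value is performed.

With noise, `−ln` of the amplitude ratio carries two opposing O(σ²/a1²)
terms — the Rician bias of `|c|` and the Jensen term of the logarithm — that
largely cancel; measured ROI-mean dark-field bias at the defaults is
≈ +0.002, well inside the acceptance bands, so no explicit debiasing is
applied.

## Thorax phantom and signal calibration

The phantom is a 512 × 512 projection at 29 µm effective pixels (≈15 mm
field of view): an elliptical thorax, a spine column, nine curved rib bands
(absorbance 2.5, zero extinction), two lung fields, trachea and both main
bronchi as air tubes, and a cuff marker (two dense blobs) at the anastomosis
on the left main bronchus.  Images are stored supine with the anatomical
left lung on the viewer's right; x is the grating-stepping direction.

Signal calibration inverts the retrieval definitions in closed form:
targets `(A, D)` are realised by `T = exp(−A), ε = D`, so a noiseless
simulation followed by retrieval returns the targets exactly (machine
precision); this exactness anchors the whole quantitative chain.
Parenchyma endpoints: healthy aerated lung `(0.788, 1.475)` (the control-arm
means at the first time point) and airless tissue `(1.05, 0.10)`.
`atelectasis_severity` interpolates linearly between them.

Per-animal heterogeneity: one lung-wide draw per lung per animal from the
configured normal distributions, plus a smooth multiplicative texture (10 %
relative SD, ≈12 px correlation length) standardised to exactly zero
mean / unit SD over each lung's ROI so cohort calibration is preserved
pixel-exactly.

Airways are rendered as soft-edged tubes: a logistic profile of distance to
the centerline with 1.5 px edge softness, truncated 12 px beyond the wall so
the tube's footprint has strictly bounded support (lung ROI masks exclude it
exactly).  The differential-phase map is the x-gradient of the tube field,
scaled to a 0.8 rad peak for an x-normal wall — the bipolar wall signature
the tracer exploits.  The logistic wall places the gradient extrema exactly
at the geometric lumen radius, which is what makes sub-pixel diameter
metrology meaningful.  Pathologies: *stenosis* dips the lumen radius at the
cuff to `stenosis_fraction` of the proximal calibre over a ±14 px cosine
window; *truncation* tapers the lumen to zero at the cuff and deletes it
distally; *pneumothorax* sets the left hemithorax to near-air transmission
(A = 0.05) and zero extinction.  A lumen narrower than 2 px at the requested
resolution is rejected as unrenderable.  In the labelled anatomy the bone
label excludes the airway footprint (an air lumen projected in front of
spine or rib dominates that pixel), keeping the ground-truth labels
consistent with the rendered image.

## Cohort model

The first time point is a 51-recipient cohort: per-animal `(A, D)` targets
for the transplanted and control lung are drawn from the four configured
normal distributions (transplanted 0.943 ± 0.078 / 0.681 ± 0.215; control
0.788 ± 0.069 / 1.475 ± 0.184); 4 animals develop a left-sided pneumothorax
and 1 dies after the first scan (both excluded, leaving 46 analysable).
Each animal's atelectasis severity is *derived* from its drawn dark-field
target (its position between the healthy and airless endpoints), and airway
pathologies are assigned by descending severity rank: the 10 most severe
lungs carry a bronchial truncation, the next 4 a stenosis
(`stenosis_fraction ~ U(0.3, 0.5)`, distal calibre `U(1.1, 1.5)` mm), and
further animals up to 24 show decreased ventilation without a visible
airway irregularity.  This keeps the drawn distributions — and hence the
cohort means the pipeline must recover — untouched while matching the
clinical picture that truncated bronchi come with (sub)total atelectasis and
stenotic ones with constrained but present ventilation.  Draws are floored
at 0.02 (a ≈3σ event for the lowest mean) to keep targets physical; the
induced mean shift is ≪ 1 SE.  All randomness flows from one seed through
`numpy.random.SeedSequence`, with per-animal child seeds recorded in the
manifest; equal seeds reproduce byte-identical cohort manifests.

The rescanned subgroup (n = 27) draws each signal from a bivariate normal
whose marginals are the subgroup's two time-point calibrations (transplanted
dark-field 0.656 ± 0.234 → 0.722 ± 0.251; control dark-field 1.507 ± 0.168 →
1.442 ± 0.263; control absorption 0.789 ± 0.075 → 0.836 ± 0.067) and whose
between-time-point correlation is 0.8.  The correlation is not identifiable
from cohort summary statistics; 0.8 reflects that lung-wide signal is a
stable per-animal trait and reproduces the reported significance pattern of
the four within-lung comparisons (dark-field improvement of the transplanted
lung significant near p ≈ 0.04, its absorption change not significant, both
control-lung drifts significant).  The transplanted-lung absorption mean at
the second time point is reported qualitatively only ("slight,
non-significant decrease"); the preset uses 0.927 ± 0.080.  Eight animals
improve their ventilation (largest dark-field gains, preferring animals with
an airway pathology); six of those resolve their bronchial irregularity —
a truncation reopens into a mild residual narrowing, a stenosis resolves
with a 1.1 mm distal calibre.

## ROI quantification

Lung outlines come from the phantom's ground-truth anatomy — in the original
setting these were drawn manually by radiologists, and no algorithm exists
to substitute for them — while the osseous exclusion is algorithmic:
threshold the pre-smoothed absorption image (isotropic Gaussian, σ = 2 px)
and open the result morphologically.  The opening is implemented as r-fold
erosion then dilation with the unit disk (r = 2 default), i.e. a true
opening by the r-fold Minkowski sum: idempotent, and monotone in the radius
(a larger radius never adds pixels).  The default threshold is adaptive: the
midpoint between the in-body median (soft tissue) and the 99.5th percentile
(cortical bone plateau).  A fixed in-body percentile was rejected because
the bone area fraction of a projected thorax (~25 %) puts any single
percentile either inside the bone distribution or exactly at the soft-tissue
plateau, where the smoothed halo makes thresholding unstable; the midpoint
rule lands between the two modes for any bone fraction below ~50 %.
ROI means are arithmetic means over the final mask (lung outline minus
segmented bone minus quality-masked pixels, ≥ 50 px enforced); absorption
and dark-field use the identical pixel set, which is meaningful because both
images come from the same exposure.

Pneumothorax screening uses the conjunction of two thresholds over the left
lung: dark-field mean < 0.3 *and* absorption mean < 0.5.  Air in the pleural
space is both scatter-free and hyper-transparent, whereas atelectasis shares
the low dark-field but *raises* absorption — the conjunction is what
separates the two.  The values sit in the wide gap between the calibrated
regimes (healthy D ≈ 1.5, airless D ≈ 0.1 with A ≈ 1.05, pleural air
A ≈ 0.05) and are configuration-exposed.

## Bronchus tracing, metrology and classification

The left main bronchus is traced in the differential-phase image from a
proximal seed (taken from the phantom geometry; the cuff marker itself is
plainly visible in the absorption image, so anchoring the cuff position from
the manifest mirrors what a reader does).  At each 2 px step the tracer
samples a cross-profile perpendicular to the current direction (half-pixel
sampling, linear interpolation), locates the positive and negative wall
extrema, re-centres on their midpoint and blends the direction with the
recent drift.  A wall pair is accepted only if (a) both extrema exceed the
visibility threshold — 3× the robust noise SD (1.4826·MAD) of the phase
image, floored at 0.05 rad; (b) the pair is sign-ordered as the x-gradient
of an air lumen dictates; and (c) the weaker wall is at least 15 % of the
stronger (walls slanted along a tapering lumen are genuinely asymmetric, so
the ratio is permissive; the sign ordering is what rejects noise).  The
trace stops at the image border or after 4 consecutive positions without an
accepted pair.

Lumen diameter at a position is the distance between the sub-pixel
(3-point parabolic) locations of the two wall extrema on the perpendicular
cross-profile, times the effective pixel size.  On noiseless tubes of
0.5–2.0 mm the absolute error is a few µm, far inside the one-pixel
(29 µm) requirement; with Poisson noise at the defaults it stays within two
pixels in ≥ 95 % of trials.

Classification relative to the cuff replaces the original reader
assessment with a deterministic rule — a stated substitution, not a claim
of equivalence: *truncation* if no measurable lumen exists beyond the cuff
margin (5 px), requiring at least 3 visible distal positions so an isolated
noise blip cannot make the distal bronchus "visible"; otherwise *stenosis*
if the minimum calibre within the ±15 px cuff window falls below θ = 0.7 of
the proximal reference (median calibre proximal to the window); otherwise
*normal*.  All thresholds are configuration-exposed.

## Statistics

Paired comparisons use the Student t-test for paired samples
(`t = mean(d)/(sd(d)/√n)`, `df = n−1`, two-sided p), matching the study
design in which each animal's native right lung is its own control.
Degenerate zero-variance differences return p = 1 (zero mean) or p = 0 with
a warning.  No multiple-testing correction is applied, matching the
per-comparison reporting this reproduces.  The test suite validates p-values
against direct numerical integration of the t density.

## Determinism and problem sizes

Every stage is deterministic given the run seed; re-running a configuration
reproduces byte-identical manifests and tables.  The full first-time-point
pipeline (51 animals, 512², 4 steps, Poisson noise, tracing and statistics)
runs in ≈ 30 s on one CPU; the acceptance script, which adds the 27-animal
second-time-point run and the tube metrology, in ≈ 90 s.  Property tests use
reduced rasters (10–128 px) where the property is resolution-independent.

## What the synthetic data does and does not show

The generator emulates the *statistical and geometric structure* of the
study — calibrated signal distributions, exclusion and pathology counts,
airway geometry at the reported calibres, Poisson counting noise — not the
animals themselves.  It omits, among others: respiratory and cardiac motion,
polychromatic beam hardening and visibility dispersion, scatter, detector
cross-talk, anatomical variability beyond a smooth texture, partially
collapsed (dystelectatic) sub-regions, pleural effusion as a distinct
signal, and any reader variability.  Passing tests therefore demonstrate
that the analysis chain is correct and well-calibrated on data that obey its
forward model; they do not demonstrate robustness to the un-modelled physics
of real scans.  The classification accuracy on phantoms (exact tallies) in
particular should not be read as expected in-vivo reader agreement.
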