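# Methods

## Measurement model

A telomere hybridized with a fluorescent PNA probe is treated as a
sub-diffraction point source: its image is the microscope PSF scaled by a
peak amplitude proportional to the number of bound probes, hence to
telomere length. The pipeline therefore reports *brightness* — the fitted
peak amplitude in photon counts above local offset — rather than integrated
intensity, which is more sensitive to segmentation and background choices.
All comparisons between conditions are ratios of mean brightness, valid as
relative length changes under the linear brightness–length relationship;
absolute calibration to kilobases is out of scope (it needs a length
standard imaged under identical settings).

Coordinates are (z, y, x), 0-based, with the centre of voxel (iz, iy, ix)
at (iz·dz, iy·dy, ix·dx) nm. Default voxel size is 80 × 80 nm lateral,
200 nm axial. Intensities are used as photon counts with no gain
calibration, since all thresholds are specified in counts.

## Pipeline stages and numerical choices

**Nuclear masking.** Global 3D Otsu on the DAPI channel, hole filling,
26-connected labelling, components under 1000 voxels dropped. This
replaces manual masking; a manual mask can be passed to `measure_stack`
for parity with hand-curated analyses. A constant DAPI stack yields an
empty mask with a warning.

**Smoothing.** Gaussian filter with physical σ = 80 nm, i.e. per-axis
voxel sigmas of (0.4, 1.0, 1.0) at default geometry. Symmetric-reflect
boundaries are used because they both preserve constants and conserve
total intensity exactly for a normalized kernel.

**Spot detection.** Voxels strictly above 25 counts (on the smoothed
image, inside nuclei) are grouped by 26-connectivity. Components holding
more than one 3D local maximum above threshold are split by marker-based
watershed on the inverted smoothed image; touching equal-valued maxima
(plateaus straddling a voxel boundary, as produced by a spot centred
between voxels) are merged into a single marker first, so symmetric spots
are never split. The 10-voxel minimum size is applied per split region.
Centres of mass are intensity-weighted over the region.

**Amplitude fitting.** Two 1D profiles (11 voxels; at least 7 after edge
truncation, else the fit is invalid) through the centre of mass, along x
and y in the nearest z-plane, are fitted with amplitude·Gaussian + offset
by Levenberg–Marquardt least squares (amplitude bounded ≥ 0). Fits run on
the **raw** channel by default: fitting the smoothed channel would deflate
amplitudes by a known factor (≈0.67 for a 120 nm-σ lateral PSF smoothed at
80 nm); `fit_on="smoothed"` is available for comparison. r² = 1 −
SS_res/SS_tot, defined as 0 for zero-variance profiles. A spot is accepted
iff its better fit has r² > 0.8 (strict) and a positive amplitude; exact
r² ties resolve to the x-axis fit. Because profiles pass through the
nearest voxel line rather than the exact sub-voxel centre, a fitted
amplitude underestimates the true peak by up to ≈10% (mean ≈5%) for
off-grid spots; this attenuation is condition-independent and cancels in
brightness ratios, which is what the group statistics consume.

## Group statistics

**Nested ANOVA.** Telomere log-brightness values (natural log; the base
does not affect F or p) are averaged per nucleus, and a one-way ANOVA
across conditions is run on the nucleus means. With equal telomere counts
per nucleus this equals the classical nested ANOVA test of the group
effect against nucleus-within-group variation; with unequal counts it is a
close approximation that weights nuclei equally (a defensible choice,
since the nucleus is the biological replicate). A linear mixed model with
a random nucleus intercept (`anova_method="mixed"`, Wald test) is provided
as an alternative; the two agree closely on realistic designs. Degenerate
inputs (all nucleus means equal) return F = 0, p = 1 rather than 0/0.

**Lognormal model.** Brightness within a population of telomeres is
modelled as lognormal; the fit is the closed-form MLE on logs, with a KS
test against the fitted distribution. Since parameters are estimated from
the same sample, the KS p-value is approximate and anti-conservative; it
is used as a sanity check, not an inference.

**Dark telomeres.** "Dark" is defined here as brightness below the 10th
percentile of the pooled reference condition. The cutoff is always
reported next to the fractions; it is a pipeline definition, not an
estimate of any published cutoff.

**Percent shortening.** 100·(mean_ref − mean_case)/mean_ref on per-nucleus
mean brightness averaged per condition; invariant to common rescaling of
both means.

**Detection efficiency.** One-way ANOVA on per-nucleus accepted counts; a
non-significant result supports the assumption that detection does not
depend on average brightness, which is a precondition for unbiased group
comparison.

## Synthetic scenes: what they emulate, and what not

The generator emulates the statistical structure the measurement assumes:
one ellipsoidal nucleus per stack (default semi-axes 7 × 7 × 2.5 µm in a
256 × 256 × 40 stack), 92 telomeres (two per chromosome for 46
chromosomes, giving coverage a known denominator), uniform placement with
a hard ≥ 200 nm pairwise separation (rejection sampling, 10⁵-proposal
budget), lognormal amplitudes, a separable anisotropic Gaussian PSF with
peak normalized to 1 (σ = 120 nm lateral, 300 nm axial) evaluated at voxel
centres with sub-voxel spot positions, constant background (5 counts),
Poisson photon noise, 16-bit quantization.

Defaults the source imagery does not determine, fixed once as assumptions:
within-nucleus lognormal σ(log) = 0.5 (CV ≈ 53%, a realistic Q-FISH
spread), with μ solved so the analytic mean is 126.3 counts for wild type;
background 5 counts and PSF widths chosen so the 25-count threshold and
10-voxel minimum are meaningful gates (amplitudes near the 0.1st
percentile fall below detectability, everything else is detectable).

Not emulated: Airy/aberrated PSFs, photobleaching, chromatin texture in
DAPI, multiple nuclei per field, telomere clustering, detector read noise.
A green synthetic test therefore establishes correctness of the algorithms
and their statistical calibration under the stated model — not robustness
to optical artefacts outside it.

## Known limitations

- Brightness is a relative length proxy; no kb calibration.
- Two 1D lateral fits (not a 3D volumetric fit) define brightness; axially
  elongated or overlapping-in-z spots inherit the confocal axial
  resolution limit.
- The nucleus-means ANOVA assumes nuclei are exchangeable replicates
  within a condition; strong per-nucleus count imbalance would argue for
  the mixed-model variant.
- With the between-nucleus spreads and six-nuclei groups typical of this
  assay, the nested ANOVA's power to flag a 26% shortening at p < 0.01 is
  about 0.73–0.76 (Monte-Carlo and noncentral-F agree): a single
  significant experiment is typical, but replication is not guaranteed.
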