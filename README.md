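# telofish

Quantitative telomere-length analysis from 3D fluorescence microscopy
(Q-FISH). Telomeres hybridized with a fluorescent PNA probe show a
brightness proportional to their length, so per-telomere probe intensity is
a length proxy. `telofish` measures that brightness from confocal z-stacks
of whole nuclei and compares it across experimental groups — e.g. patient
versus control fibroblasts — without the out-of-focus and spot-overlap
artefacts of single-plane Q-FISH.

It is aimed at microscopy groups doing telomere biology: the input is a
DAPI z-stack plus a telomere-probe z-stack per nucleus (TIFF, anisotropic
voxels, e.g. 80 × 80 × 200 nm), the output is a per-telomere brightness
table and a group-comparison report.

## Method

Per stack, the pipeline is:

1. **Nuclear mask** from the DAPI channel (3D Otsu threshold, hole filling,
   size filter), so background outside nuclei never contributes.
2. **Smoothing** of the telomere channel with a Gaussian, σ = 80 nm.
3. **3D spot detection**: 26-connected voxels above a background threshold
   of 25 photon counts, regions with several local maxima split by
   marker-based watershed (resolving partially overlapping telomeres),
   minimum spot size 10 voxels; intensity-weighted centre of mass per spot.
4. **Orthogonal Gaussian fits**: through each centre of mass, two lateral
   1D profiles (along x and along y, in the nearest z-plane) are fitted with
   A·exp(−(u−c)²/2σ²) + b. The better fit supplies the telomere brightness
   A, accepted when its r² > 0.8. Nothing else is filtered.

Group statistics treat the **nucleus as the experimental unit**: brightness
is log-transformed and a nested one-way ANOVA (one-way ANOVA on per-nucleus
mean logs, exact under balance) tests the condition effect against
between-nucleus variation. The package also fits lognormal models to the
brightness distributions (MLE on logs + KS check), reports the frequency of
"dark" telomeres below a reference-derived low quantile, tests
detection-efficiency equality across groups, and converts mean-brightness
differences to percent shortening, 100·(ref − case)/ref.

Because microscopy data of this kind are rarely shareable, the package
includes a first-class synthetic-scene generator: ellipsoidal nuclei, 92
point-like telomeres with ≥ 200 nm pairwise separation, lognormal
amplitudes, anisotropic Gaussian PSF, constant background and Poisson
noise — every stage of the pipeline is testable against known ground truth.

## Worked example

Simulate a two-condition study (6 nuclei each; the "MUT" condition's
amplitude distribution scaled to 0.74× wild type, i.e. a true 26%
shortening), measure every stack, and fit the group comparison:

```python
from telofish import GeneratorParams, generate_study, measure_stack, TelomereStudy

wt = GeneratorParams()
study = generate_study({"WT": wt, "MUT": wt.scaled_brightness(0.74)}, seed=7)
measured = {
    cond: {i: measure_stack(dapi, telo, sample_id=cond)
           for i, (dapi, telo, _) in enumerate(scenes)}
    for cond, scenes in study.items()
}
results = TelomereStudy.from_measurements(measured, reference="WT").fit()
print(results.summary())
```

```
Telomere brightness study              reference: WT
================================================================
condition    nuclei  telomeres     mean  dark frac  shortening
MUT               6        500     95.2      0.240       25.7%
WT                6        515    128.1      0.101           —
----------------------------------------------------------------
nested ANOVA (log brightness, by nucleus): F = 424.233, p = 1.61e-09
detection efficiency: F = 3.462, p = 0.0924; n = 83.3 ± 2.8, 85.8 ± 1.7 (mean ± std)
dark-telomere threshold: 59.7 counts (reference WT quantile)
lognormal fit [MUT]: mu=4.446, sigma=0.453, KS=0.073 (p=0.00915, n=500)
lognormal fit [WT]: mu=4.736, sigma=0.479, KS=0.037 (p=0.475, n=515)
```

Reading this: the pipeline recovered 83–86 of the 92 true telomeres per
nucleus in both conditions (detection efficiency statistically equal, so
the brightness comparison is unbiased); mean brightness dropped from 128.1
to 95.2 counts, i.e. 25.7% estimated shortening against the true 26%; the
condition effect is highly significant against between-nucleus variation;
and dark telomeres (below the wild-type 10th percentile, 59.7 counts) are
2.4× more frequent in the shortened condition.

The same workflow is available from the shell:

```bash
telofish simulate --out scene_dir --condition WT:1.0 --condition MUT:0.74 --seed 7
telofish measure --dapi scene_dir/WT_nucleus00_dapi.tif \
                 --telomere scene_dir/WT_nucleus00_telomere.tif \
                 --out WT00.csv --sample-id WT
telofish compare WT00.csv ... --reference WT --out comparison.json
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic wild-type study
(6 nuclei × 92 telomeres, Poisson noise), runs the complete
mask → smooth → detect → fit pipeline, matches accepted measurements to
ground-truth spots within one voxel per axis, and reports the mean
percentage of true telomeres recovered:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/telofish/simulate.py` — ground-truthed synthetic confocal scenes
- `src/telofish/detect.py` — masking, smoothing, spot detection, Gaussian fits
- `src/telofish/stats.py` — `TelomereStudy` / `TelomereStudyResults` group statistics
- `src/telofish/io.py`, `config.py`, `stacks.py` — TIFF/CSV/JSON I/O, run configuration
- `src/telofish/evaluate.py` — truth matching and coverage for synthetic scenes
- `docs/methods.md` — modelling assumptions, parameter defaults, limitations
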