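# isletmt

Automated 3D quantification of β-cell proliferation and function in
reaggregated human islet microtissues (MTs).

Restoring β-cell mass by stimulating proliferation of residual β-cells is a
candidate therapeutic route for diabetes, and screening candidate compounds
(e.g. the DYRK1A inhibitor harmine) requires counting proliferating β-cells
inside intact 3D islet spheroids. `isletmt` implements the full analysis
chain for such a screen — and, because high-content confocal datasets of
donor islets are rarely shareable, it pairs the pipeline with a synthetic
confocal-stack generator with per-nucleus ground truth, so every stage can
be validated against known answers.

## What it does

**Image analysis** (per multi-channel confocal Z-stack, channels DAPI /
NKX6.1 / EdU):

1. *Spheroid detection* — Otsu thresholding of the (pre-smoothed) DAPI
   channel, morphological closing, largest connected component, per-plane
   hole filling.
2. *Nuclear segmentation* — dynamic (local-mean + offset) thresholding
   inside the spheroid, anisotropy-aware Euclidean distance transform, and
   a marker-controlled watershed to split touching nuclei.
3. *Marker segmentation* — the same dynamic-threshold rule on the NKX6.1
   (β-cell identity) and EdU (proliferation) channels, after per-stack
   NKX6.1 intensity truncation to percentile bounds so all wells sit in a
   comparable intensity range.
4. *Colocalization* — a nucleus is a proliferating β-cell when it carries
   both labels: the proliferating-β set is the intersection of the NKX6.1⁺
   and EdU⁺ label sets.

Per microtissue this yields the screen's metrics: total cell count *N*,
β-cell count *N*<sub>β</sub>, β-cell fraction 100·*N*<sub>β</sub>/*N*,
percent proliferating cells 100·*N*<sub>EdU</sub>/*N*, percent
proliferating β-cells 100·*N*<sub>EdU∩β</sub>/*N*<sub>β</sub> (and the
non-β analogue), mean NKX6.1 intensity, and spheroid volume.

**Statistics** for the functional endpoints (basal/stimulated/chronic
insulin secretion, insulin content, ATP, caspase): fold-stimulation
(stimulated/basal secretion at 16.7/2.8 mM glucose), one-sample ROUT
outlier removal at FDR *Q* (robust center = median, scale = 68.27th
percentile of absolute residuals with an *n*/(*n*−1) correction, t-based
per-point p-values, FDR stepping from the most extreme residual inward),
one-way ANOVA with Dunnett many-to-one comparisons against the vehicle
control, Student's t-test, and tidy mean ± SEM dose-response tables with
peak annotation.

**Simulator**: non-overlapping nuclei packed into a spheroid (~150 µm
diameter at full scale, 3 µm confocal Z-step, 0.5 µm XY pixels), Bernoulli
β identity (default fraction 0.55) and proliferation status, lognormal
NKX6.1 amplitudes with attenuation in proliferating β-cells, Hill-type
dose effects on proliferation and secretion endpoints, Gaussian-PSF
rendering with Poisson + Gaussian noise, and CSV/TIFF output with a hashed
manifest for byte-identical reproducibility.

## Worked example

Simulate one compound-treated microtissue at test scale (200 nuclei,
40 µm radius) and push it through the full pipeline:

```python
from isletmt import synthetic as syn
from isletmt.pipeline import detect_spheroid, segment_nuclei, truncate_intensities
from isletmt.quantify import extract_records, quantify_mt, spheroid_volume

phenotype = syn.PhenotypeModel(prolif_rate_beta=0.02, prolif_rate_nonbeta=0.10)
optics = syn.OpticsConfig()
geometry = syn.GeometryConfig()

cells = syn.generate_spheroid_geometry(geometry.n_cells, geometry.spheroid_radius, seed=1)
truth = syn.assign_phenotypes(cells, phenotype, seed=2)
stacks = syn.render_stack(
    truth, optics, syn.default_stack_shape(geometry.spheroid_radius, optics),
    seed=3, spheroid=(geometry.spheroid_radius, {"dapi": phenotype.dapi_interstitial}))

spheroid = detect_spheroid(stacks["dapi"])
nkx = truncate_intensities(stacks["nkx6_1"], 1.0, 99.5, spheroid)
nuclei = segment_nuclei(stacks["dapi"], spheroid)
records = extract_records("demo_mt", nuclei, stacks["dapi"], nkx, stacks["edu"], spheroid)
q = quantify_mt(records, spheroid_volume(spheroid))

print(f"total cells:     {q.n_total}  (simulated: {len(truth)})")
print(f"beta cells:      {q.n_beta}  ({q.pct_beta:.1f}% of total)")
print(f"EdU+ cells:      {q.n_edu}  ({q.pct_prolif_total:.1f}% total proliferation)")
print(f"EdU+ beta cells: {q.n_edu_beta}  ({q.pct_prolif_beta:.1f}% of beta cells)")
```

prints

```
total cells:     201  (simulated: 200)
beta cells:      107  (53.2% of total)
EdU+ cells:      10  (5.0% total proliferation)
EdU+ beta cells: 2  (1.9% of beta cells)
```

The pipeline recovered 201 of 200 planted nuclei; the measured β fraction
(53.2%) matches the generative 55% draw for this seed, and the measured
proliferation (5.0% total, with non-β proliferation well above β
proliferation) reflects the simulated treated phenotype.

The same loop is available from the shell:

```sh
isletmt demo -o out/             # simulate + analyze a small plate
isletmt simulate -c config.yaml -o sim/
isletmt analyze  -c config.yaml --stacks sim/stacks --layout sim/layout.csv -o ana/
isletmt stats    --functional sim/functional.csv --per-mt ana/per_mt.csv -o stats/
```

## Layout

- `src/isletmt/synthetic.py` — geometry packing, phenotype assignment, stack rendering, plate simulation
- `src/isletmt/pipeline.py` — Otsu, spheroid detection, dynamic thresholding, nuclear segmentation, truncation, marker scoring
- `src/isletmt/quantify.py` — colocalization and per-MT metrics
- `src/isletmt/stats.py` — ROUT, Dunnett, t-tests, dose-response tables
- `src/isletmt/runner.py`, `src/isletmt/cli.py` — end-to-end runs and the CLI
- `docs/methods.md` — modeling assumptions, parameter defaults, numerical choices, limitations
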