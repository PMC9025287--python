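# habitatpipe

Perfusion-habitat analysis of breast DCE-MRI: discover intratumoral
subregions ("habitats") with distinct contrast-enhancement kinetics,
quantify the spatial heterogeneity of the resulting habitat map with
radiomics features, and condense them into a Cox-LASSO **habitat risk
score (HRS)** that stratifies disease-free survival.

Solid breast tumours are perfusionally heterogeneous: different
subregions wash contrast in and out at different rates, and the spatial
arrangement of those subregions carries prognostic information that
whole-tumour averages miss. From three time points of a dynamic
contrast-enhanced T1-weighted acquisition, each tumour voxel gets a
perfusion feature vector

```
Ein  = I_early − I_pre                 (wash-in)
Eout = I_early − I_delayed             (washout)
RWO  = Eout / I_early  if I_delayed < I_early else 0   (washout ratio)
```

Voxels of *all* development-cohort patients are pooled, quantised to
256 levels per feature, and clustered with k-means at the cohort level
(k = 2…32; Calinski-Harabasz + silhouette averaged over restarts select
k) so habitat labels are comparable across patients. Replacing each
voxel's intensity with its habitat index yields a habitat map whose
spatial heterogeneity is measured by 58 features (4 histogram, 24 GLCM,
16 GLSZM at bin size one, 14 mesh-based shape features) plus the
habitat volume proportions. An L1-penalised Cox model on the z-scored
features defines the risk score

```
HRS_i = h0(0) · exp( Σ_j β_j · x_ij )
```

and the development-median HRS splits patients into high/low-risk
groups, evaluated by hazard ratios and Harrell's C-index in both an
independent validation cohort and four comparator models (two
whole-tumour radiomics panels, clinical covariates, clinical + HRS).

Because patient imaging with linked outcomes is not redistributable,
the package ships a first-class synthetic-cohort generator that plants
five perfusion habitats — kinetic centres (wash-in, washout, washout
ratio) of (825, −667, 0.021), (2420, 864, 0.361), (2206, −14, 0.075),
(1154, 362, 0.338), (1302, 915, 0.717) at proportions
0.419/0.068/0.256/0.235/0.022 — in dual cohorts with different voxel
spacing and scanner intensity maps, and survival driven by a Cox model
on habitat-heterogeneity features. Every pipeline stage is tested
against this ground truth and against independent brute-force oracles.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk
scale (60 + 30 patients, k swept to 12) and write artifacts under
`results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_preprocess.py
python analysis/03_perfusion_maps.py
python analysis/04_discover_habitats.py
python analysis/05_extract_features.py
python analysis/06_fit_risk_models.py
```

`04_discover_habitats.py` prints the recovered structure:

```
selected k = 5 habitats
centres (wash-in, washout, washout ratio), canonical order:
  habitat 1: (   817.0,     16.4,  0.025)
  habitat 2: (  1172.5,    555.7,  0.353)
  habitat 3: (  1702.2,    381.8,  0.182)
  habitat 4: (  2228.3,    199.0,  0.076)
  habitat 5: (  2392.9,    802.9,  0.288)
development mean habitat proportions:
  0.374, 0.243, 0.100, 0.213, 0.070
```

Canonical order sorts centres by wash-in: recovered habitats 1, 2, 4
and 5 land on the planted low-enhancing persistent, moderate washout,
strong plateau and strong washout kinetics at close to their planted
prevalences, while habitat 3 collects the partial-volume blends that
1 mm resampling of 3 mm slices creates at patch boundaries (and absorbs
the rare 2.2% planted habitat). Note the rendered washout column is
`RWO · I_early` of the planted washout-ratio kinetics, not the bare
mixture's washout coordinate. `06_fit_risk_models.py` then prints the
selected HRS panel and the per-model report; on this run the HRS
stratified development patients at a hazard ratio of 3.1 (p = 0.001)
with C-indices of 0.674 (development) and 0.645 (validation), while the
whole-tumour DCE comparator overfit (0.699 development vs 0.568
validation) and the clinical panel carried no detectable signal at this
cohort size — the habitat signature generalises where the whole-tumour
one does not, because the planted hazard acts through habitat
heterogeneity.

The same machinery is available stage-by-stage from the command line:

```bash
habitatpipe all --config results/config.json
habitatpipe habitats --config results/config.json   # single stage
```

## Layout

```
src/habitatpipe/   library: cohort, preprocess, perfusion, habitats,
                   features, survival, pipeline
analysis/          numbered narrative drivers of the full study
scripts/           acceptance.py (headline quantities, JSON output)
tests/             pytest suite incl. brute-force oracles
docs/methods.md    model, parameters, numerical choices, limitations
```
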