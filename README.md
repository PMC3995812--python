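# stromascore

Compartment-specific quantification of chromogenic in situ hybridization
(ISH) signal on virtually double-stained serial sections, with a
tertile-based disease-free-survival analysis on top.

## The problem

In many carcinomas a biomarker of interest — here the microRNA miR-21 in
oral squamous cell carcinoma — is expressed mainly in the **tumor stroma**
(cancer-associated fibroblasts), not in the carcinoma cells themselves. To
score it compartment-specifically from chromogenic stains you need two
serial sections: a pan-cytokeratin IHC (brown DAB) that marks the
epithelial tumor compartment, and the ISH itself (blue NBT/BCIP on a
nuclear-fast-red counterstain). Aligning the sections lets the
cytokeratin-derived tumor mask be transferred onto the ISH section
("virtual double staining"), splitting its region of interest (ROI) into
tumor and stroma. The stromal score is

    TBS = (chromogen-positive stromal area) × (mean blue OD over those pixels)

which, with intensity measured in optical density (OD), is exactly the
integrated chromogen OD in the stroma — linear in the amount of bound
probe. `TBT` is the analogous tumor-compartment quantity and `TSA` the
total stroma area. Patients are then stratified into TBS tertiles and
analysed with Cox proportional-hazards models (univariate per covariate,
then multivariable with backward elimination), Spearman screens,
scaled-Schoenfeld PH diagnostics, and log-rank-tested survival curves.

The package is aimed at image-analysis and biostatistics people who want
this pipeline reproducible and testable end to end: every stage can be run
against a synthetic-data generator with exact ground truth (drawn per-pixel
ODs, known misalignment, configured hazard ratios).

## Worked example

```python
import stromascore as ss
from stromascore.pipeline import RunConfig, score_sample

# a synthetic serial-section pair with known truth
pair = ss.simulate_image_pair(ss.ImageSimConfig(seed=7))

# unmix -> DAB mask -> register -> transfer mask -> blue mask -> score
row = score_sample(pair.ihc_image, pair.ish_image, pair.roi_mask_ish.data, RunConfig())
print(row["tbs"], pair.tbs_true)
```

prints (seed 7):

```
TBS  = 8103.8   (ground truth 8156.0)
TBT  = 313.2    (ground truth 293.3)
TSA  = 25225 px (ground truth 25235)
blue threshold = 0.017 OD, registration NCC = 0.984
```

i.e. the recovered stromal score is within ~0.6% of the exact sum of the
drawn chromogen ODs, with the serial-section misalignment (4 px, −3 px,
1.5°) recovered automatically. The survival side, on the packaged 86-row
example cohort (synthetic outcomes, study-matched covariate margins):

```python
from stromascore import example_clinical_table
from stromascore.pipeline import run_survival

bundle = run_survival(None, example_clinical_table(), RunConfig())
```

yields tertile sizes 29/28/29 and, for this example draw, an upper-vs-lower
tertile hazard ratio of 4.30 (95% CI 1.40–13.20, log-rank p = 0.020) on
25 recurrence events — wide CIs being exactly what an 86-patient cohort
produces.

The same stages are scriptable from a shell:

```bash
stromascore simulate images --n 3 --seed 0 --out tiles/
stromascore score --manifest tiles/manifest.csv --out scored/
stromascore simulate cohort --n 500 --seed 0 --out cohort.csv
stromascore survival --clinical cohort.csv --out results/
```

## Package layout

| module | contents |
| --- | --- |
| `stromascore.stains` | OD conversion, stain matrices, least-squares unmixing, chromogen thresholding (triangle / Otsu / fixed) |
| `stromascore.registration` | deterministic similarity/affine registration on counterstain NCC, mask warping |
| `stromascore.compartments` | ROI/tumor/stroma masks, TBS/TBT/TSA scoring, mask-overlap statistics |
| `stromascore.synthetic` | image-pair and survival-cohort generators with exact ground truth |
| `stromascore.survival` | cohort filtering, tertiles, Spearman screen, Cox models, backward elimination, PH diagnostics, survival curves |
| `stromascore.pipeline` / `stromascore.cli` | batch orchestration and the `stromascore` command |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

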