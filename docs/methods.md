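# Methods

`stromascore` quantifies a chromogenic in situ hybridization (ISH) signal
specifically in the tumor stroma of a cancer section, and relates the
resulting per-patient score to disease-free survival (DFS). The package was
built around the analysis of stromal miR-21 in oral squamous cell carcinoma
(OSCC), where the blue NBT/BCIP precipitate marks the probe, a
pan-cytokeratin IHC on a serial section marks the epithelial tumor
compartment, and the prognostic question is whether stroma-specific signal
predicts recurrence. Everything below is, however, generic to any
two-chromogen serial-section design.

## The imaging model

**Optical density.** Brightfield transmitted intensity follows
Beer–Lambert, so per channel we work in optical density,
`OD_c = -log10((I_c + 1)/256)` for 8-bit input. The `+1/256` offset avoids
`log 0` and makes the transform exactly invertible on integers. OD is
linear in chromogen amount, which is what makes the scores below additive.

**Stain unmixing.** Each pixel's 3-vector of channel ODs is modelled as a
non-negative combination of at most three unit stain vectors. Concentration
maps are the least-squares projection onto that basis (pseudo-inverse),
with negative loadings clamped to zero. DAB and hematoxylin use the
Ruifrok–Johnston vectors. NBT/BCIP colorimetry is not standardized, so its
vector (and nuclear fast red's) defaults to the values the synthetic
renderer uses and is user-configurable via a JSON stain-matrix file. No
blind stain-vector estimation (Macenko-style) is attempted.

**Chromogen thresholding.** A chromogen OD map's histogram is a large
near-zero background spike plus a right-skewed positive class. The default
binarization is the triangle method, which places the threshold at the foot
of the background peak. Otsu is offered as an option but is documented to
bias high on such zero-inflated distributions (it balances class variances
and clips the low tail of the positive class; on default synthetic tiles it
costs ~6 points of mask Dice and ~3% of integrated signal). A fixed OD
threshold is available when reproducibility against a predefined cutoff
matters. Whichever threshold is used is recorded in the mask metadata and
in the per-sample output row.

## Serial-section registration

The tumor mask is derived on the IHC section and must be transferred to
the ISH section ("virtual double staining"). Serial sections a few
micrometres apart differ by slide placement, so the default transform
family is a similarity transform (translation, rotation, isotropic scale);
affine is available, deformable registration is deliberately out of scope —
residual local error is absorbed by the area-level scores.

The similarity metric is normalized cross-correlation (NCC) of the unmixed
*counterstain* OD maps (hematoxylin vs. nuclear fast red), lightly smoothed
(σ = 1 px). The counterstains label all tissue on both sections and share
cell-density structure, whereas the chromogens have opposite compartment
contrast (tumor dark on IHC, stroma dark on ISH), so total-OD NCC is
anti-correlated at the true alignment, and gradient-magnitude NCC proved
nearly flat in rotation on rounded lesions.

The optimizer is deterministic (no seeds): a 3-level coarse-to-fine
pyramid; at the coarsest level an exhaustive rotation × scale grid (1° and
2%-of-scale steps over ±6° and ±6%) each initialised with an FFT
cross-correlation translation estimate; the top three candidates are
refined by Powell's method against the NCC objective at successively finer
levels, with only the best candidate refined at full resolution. On default
synthetic tiles misalignments up to ±20 px / ±5° / ±5% are recovered to
roughly 0.1 px / 0.1° / 0.1%, against acceptance bounds of 0.5 px / 0.2° /
0.5%. A blank image (near-zero total OD) raises a "no tissue signal" error.

Masks are warped by nearest-neighbour resampling (masks stay binary);
pixels mapped from outside the source are false.

## Compartments and scores

With an operator-drawn region of interest (ROI) around the lesion and the
transferred epithelium mask, the compartments are

    tumor  = DAB mask AND ROI,        stroma = ROI AND NOT tumor,

disjoint by construction. Scores, with "intensity" defined as
blue-chromogen OD:

* `TBS = blue_area_stroma × mean_blue_od_stroma` — algebraically the
  integrated chromogen OD over positive stromal pixels, hence linear in
  the amount of precipitated chromogen;
* `TBT` — the same quantity in the tumor compartment;
* `TSA` — total stroma area (positive + negative stromal pixels).

Areas are in pixels; physical scaling is optional metadata. The mean over
an empty positive set is defined as 0, so TBS = 0 exactly when no stromal
pixel is positive. No morphological cleanup is applied by default
(`min_object_area` is available and defaults to 0). Whether the original
measurement used OD or inverted 8-bit brightness as "intensity" is
unknowable from the source material; this package defines it as OD and
records that choice in its outputs.

## Synthetic data

The generator exists so every stage can be tested against exact truth; its
defaults are the package's study conditions and are not tuned per test.

**Scene.** The ROI is a centred ellipse inset 24 px from the tile border
(so the default misalignment never carries tissue out of frame); tumor
nests are unions of random ellipses targeting a configurable fraction of
the ROI (default 0.30, 5 nests), matching the island morphology of invasive
carcinoma with trivially computable ground-truth masks. Chromogen
positivity is spatially clumped (a Gaussian-filtered noise field
thresholded at the compartment quantile; default positive fraction 0.45 in
stroma, 0.05 in tumor) because precipitate deposits are not iid salt
noise. Each positive pixel draws its OD iid from Gamma(shape 6, scale
0.12) — mean 0.72 OD, CV ≈ 0.41: positive, right-skewed, two parameters,
and the ground-truth TBS is then an exact sum of drawn values. DAB OD in
tumor pixels is Gamma(8, mean/8) with mean 0.9.

**Counterstains.** Both sections sample one shared cell-density field
(tumor epithelium 1.6× denser) with small independent per-section
perturbations — serial sections 5 µm apart share tissue structure, and
this shared texture is exactly what real cell-to-cell alignment exploits.

**Rendering.** Ground-truth scores are computed from the drawn ODs first;
the ISH scene is then warped by the configured misalignment (default
(4, −3) px translation + 1.5° rotation), both tiles are rendered through
the default stain matrices by Beer–Lambert mixing, quantized to 8-bit, and
perturbed with Gaussian RGB noise (default SD 1.5 gray levels).

**What it does not emulate.** Nuclear texture, scanner artifacts,
out-of-focus regions, stain variation between labs, tissue folds and
whole-slide pyramids are absent. Passing tests therefore demonstrate the
pipeline's correctness under its stated model (Beer–Lambert mixing, rigid
slide placement, known stain vectors), not robustness to every slide-level
artifact of production scanning.

**Cohorts.** Covariates are drawn independently at the observed margins of
the 86-patient study cohort (e.g. nodal spread 21/86, perineural invasion
15/86). The stromal score is a mixture: weight 10/86 of near-zero values
(uniform on (0,1)) — matching the observed fraction of specimens with
little to no stromal signal — plus a lognormal(6, 1) body. Event times are
exponential under proportional hazards with the linear predictor set by the
preset:

* `univariate_tertile` — hazard depends only on the within-cohort tertile
  index of the score, log HR per step log(2.7)/2, so the upper-vs-lower
  contrast is the headline 2.7;
* `univariate_single_factor` — one factor only (default nodal status,
  HR 3.0);
* `multivariate` — per-step HR 1.6 plus perineural 2.1 and nodal 2.5.

The univariate presets make the hazard depend on one factor by design:
Cox hazard ratios are non-collapsible, so marginal contrasts from a
multi-factor generator would not equal the configured conditional ones.
Censoring is the minimum of an administrative horizon (60 months) and an
exponential loss-to-follow-up (rate 0.005/month). When no baseline hazard
is given, it is calibrated by root-finding so the expected event fraction
equals the target (default 28/86 ≈ 0.33, the plausible recurrence count of
the study cohort; the true value is not recoverable from the published
tables, and the fraction is configurable). A PH-violation mode
(`ph_flip_time`) flips the sign of the linear predictor at a chosen time
and exists only to exercise the PH diagnostic.

## Survival statistics

* **Tertiles.** Scores sorted ascending, ties broken by patient id; lower
  and upper groups take the first and last ⌈n/3⌉ ranks. n = 86 gives
  29/28/29; for n = 3k+1 the outer groups exceed the middle by 2 (a direct
  consequence of the ceiling rule).
* **Cox fits** use the partial likelihood with Efron tie handling by
  default (Breslow available); the ties method is recorded in every fit.
  Wald CIs and p-values; for categorical variables a k-group log-rank p is
  attached as well, since published tables often mix the two. Reference
  level is the first sorted category. Diverging estimates (complete
  separation, monotone likelihood) are flagged as non-converged rather
  than silently returned.
* **Backward elimination** removes, per step, the variable whose smallest
  per-term Wald p is largest, while that p ≥ 0.10. The 0.10 default (not
  0.05) keeps borderline factors — the motivating analysis retained
  perineural invasion at p = 0.078 — and the removal trace is returned and
  logged.
* **PH diagnostic.** Schoenfeld residuals at each event time (covariate of
  the failing subject minus the risk-weighted mean over its risk set),
  scaled by d·Cov(β̂) (Grambsch–Therneau), Pearson-correlated with event
  time; two-sided t-test p per term. Measured type-I error at n = 150 over
  200 proportional-hazards replicates is ≈ 0.055 at nominal 0.05; power
  against the sign-flip violation at n = 1000 is ≈ 1.
* **Curves.** Cox-based group curves are S₀(t)^exp(βg) with a Breslow
  baseline from a fit on group indicators, alongside per-group
  Kaplan–Meier curves and the k-group log-rank test.

Limitations: no competing risks, no overall-survival models, no
imputation; covariates with missing values must be handled upstream.

## Problem sizes and numerics

Default tiles are 256×256: large enough for nests, clumped chromogen and
±20 px misalignments, small enough that a full image-to-score run takes a
few seconds. Recovery checks use cohorts of n = 2000 (log-HR SE ≈ 0.05–0.1
per draw) and average log-HRs over seeded replicates where a point
estimate of the recovered effect is reported. All randomness flows from
explicit integer seeds; registration and thresholding contain no
randomness at all. Degenerate inputs fail loudly: empty ROI, blank tiles,
constant maps under automatic thresholding, cohorts with no events,
cohorts under 10 patients.
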