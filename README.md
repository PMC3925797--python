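# biopsim

Monte-Carlo simulation of prostate biopsy on 3D gland/lesion models,
quantifying **risk inflation**: the systematic upward shift of
biopsy-derived risk parameters that occurs when cores are deliberately
aimed at an imaging-defined lesion instead of being placed blind to its
location.

## The problem

Prostate cancer risk is conventionally stratified from biopsy parameters —
maximum cancer core length (MCCL) and the proportion of positive cores —
with thresholds calibrated against systematic transrectal ultrasound (TRUS)
biopsy, which samples the gland by anatomy alone. Image-targeted biopsy
concentrates 1–5 cores on a lesion seen on imaging, so for the *same*
tumour it returns longer cancer lengths and a higher positive-core
fraction. Applying TRUS-calibrated thresholds (high risk ⇔ MCCL ≥ 6 mm
and/or ≥ 50 % positive cores) to targeted cores therefore reclassifies
disease upward. `biopsim` reproduces this phenomenon in silico and lets you
study how it depends on targeting error, core count and lesion geometry.

The package is aimed at researchers in urologic oncology, biostatistics and
image-guided intervention who need a reproducible, fully synthetic testbed —
no patient data are required or included.

## The model

* **Cohort** — synthetic prostates whose population statistics emulate a
  whole-mount prostatectomy series: gland volume ~ truncated lognormal
  (median 50.2 ml, range 26.8–127.7), lesions per gland with median 5
  (range 1–21), separate index/non-index lesion volume distributions
  (medians 1.215 / 0.019 ml), anterior/posterior placement, a Gleason mix
  over {≤6, 7, ≥8}, and benign "false-positive" imaging targets added so
  that 34 % of targeted sessions aim at a cancer-free region. Lesions are
  ellipsoids with randomized eccentricity and orientation.
* **Biopsy schemes** — a blinded, anatomy-parameterized 12-core TRUS
  template (left/right × base/mid/apex × medial/lateral, trajectories
  fanning from an anus reference point), and transperineal targeted plans
  of k = 1..5 cores on a 5-mm brachytherapy template grid (urethra at
  column D, row 2.0), with grid positions chosen to maximise the summed
  chord through the target ("aim at the deepest part of the lesion").
* **Targeting error** — every realised core is the planned core translated
  by a zero-mean Gaussian displacement with independent components in three
  orthogonal directions; the default total variance is 25 mm² (a 5-mm total
  targeting error combining needle deflection, per-axis SD 3 mm, and
  US–MRI registration error, per-axis SD 3 mm). Each (model, strategy) pair
  is simulated for `reps` independent sessions (default 500).
* **Outcomes** — per session: cancer length of each core against the
  *union* of true tumour foci, MCCL, % positive cores, detection;
  aggregated: sensitivity (all-cancer and clinically significant disease,
  i.e. lesion ≥ 0.5 ml and/or Gleason ≥ 7), Table-style summaries
  (mean ± SD, median, 90th percentile) and the high-risk attribution
  fraction, plus paired t and Kolmogorov–Smirnov comparisons between
  strategies.

A reconstruction pathway is also included: 5-mm step-section contour stacks
(a simple documented text format) are rigidly aligned to a midgland
reference, interpolated into voxel volumes via signed-distance shape-based
interpolation, and corrected for fixation shrinkage (isotropic linear
factor 1.10 ⇔ +33 % volume), so user-supplied histology contours can drive
the same simulation.

## Worked example

Twenty synthetic glands, 100 repetitions per strategy, 5-mm total error:

```python
import dataclasses
import pandas as pd
from biopsim import RunConfig, run_pipeline

cfg = RunConfig(
    cohort=dataclasses.replace(RunConfig().cohort, n_prostates=20, seed=1),
    reps=100,
    output_dir="demo_out",
)
run_pipeline(cfg)
summary = pd.read_csv("demo_out/summary.csv")
print(summary[summary.stratum == "significant"][
    ["strategy", "stratum", "n_cases", "mccl_mean", "mccl_median",
     "pct_positive_mean", "attribution_high"]
].round(2).to_string(index=False))
```

prints

```
  strategy     stratum  n_cases  mccl_mean  mccl_median  pct_positive_mean  attribution_high
TARGETED_3 significant       17      12.04        11.89              78.04              0.94
TARGETED_4 significant       17      12.46        12.41              76.85              1.00
    TRUS12 significant       17       4.60         3.29               8.82              0.24
```

Reading: among the 17 clinically significant cases, blinded 12-core TRUS
biopsy yields a mean MCCL of 4.6 mm and 9 % positive cores, so only 24 % of
cases cross the high-risk thresholds — while 3–4 targeted cores on the same
glands yield ≈12 mm and ≈77 %, pushing 94–100 % of the same cases into the
high-risk class. `demo_out/comparisons.json` carries the paired statistics
(here TRUS12 vs TARGETED_4 on MCCL: t = 6.10, p = 1.2e-06), and
`demo_out/sensitivity.csv` the detection sensitivities (TRUS12 0.55
all-cancer vs 0.98 for TARGETED_4 in this run). The inflation is an
artefact of deliberate oversampling, not of disease: the tumours are
identical between rows.

A command-line interface wraps the same pipeline:

```bash
biopsim simulate --seed 1 --reps 100 --out runs/demo      # full pipeline
biopsim sweep --errors 1,2,5,10 --reps 100 --out runs/sw  # sensitivity vs error
biopsim synthesize --out runs/cohort                      # contour stacks only
biopsim reconstruct --contours runs/cohort/contours --out runs/recon
```

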