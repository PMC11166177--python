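# pullstorm

Single-molecule pulldown (SiMPull) and dSTORM analysis of salivary protein
aggregates: diffraction-limited spot counting, super-resolution localization
post-processing and morphometry, and cohort-level discriminator statistics,
together with a fully synthetic ground-truth data generator.

## Scientific background

Protein aggregates of α-synuclein (αS) and amyloid-β (Aβ) circulate in saliva
and can be captured one molecule at a time on an antibody-coated coverslip
(SiMPull) and imaged by TIRF microscopy. Two complementary measurements are
made per participant:

1. **Counting** — each captured aggregate appears as a diffraction-limited
   spot in a short (50-frame) image stack; spots are counted over 16 fields of
   view (~2500 µm² each) per target protein. The per-participant ratio of
   αS to Aβ aggregate counts is elevated in Parkinson's disease.
2. **Morphology** — dSTORM imaging (thousands of frames of sparse fluorophore
   blinking) resolves the nanoscale shape of each aggregate. Localizations are
   drift-corrected, merged, density-filtered and rendered at 10 nm; segmented
   objects are described by area and circularity (4π·area/perimeter²).
   Disease donors carry a larger share of big (area > 0.03 µm²), elongated
   (circularity < 0.4) Aβ aggregates.

The two readouts combine into a per-participant **discriminator**

```
discriminator = (αS count / Aβ count) × P(Aβ aggregate has area > 0.03 µm² and circularity < 0.4)
```

which separates disease from control donors better than either readout alone.
The package implements the full chain — synthetic raw data, image processing,
localization processing, morphometry and the gated statistical comparisons
(Shapiro–Wilk → Levene → Student/Welch t or Wilcoxon rank-sum, ROC/Youden,
CDF-subtraction thresholds, logistic regression) — with every algorithm
re-implemented from its published description and tested against independent
oracles.

## Worked example

```python
import numpy as np
from pullstorm import (AcquisitionParams, BlinkParams, CohortModel, make_disc,
                       make_fibril, simulate_dl_stack, simulate_storm_table,
                       detect_spots, process_table, simulate_cohort_summaries)
from pullstorm.synthetic import CohortSpec

# --- diffraction-limited counting -----------------------------------------
acq = AcquisitionParams(fov_side=128)
rng = np.random.default_rng(0)
truths = [make_disc((2500.0 + 1800*k, 6000.0), 0.01, rng) for k in range(5)]
stack, truth = simulate_dl_stack(truths, acq, seed=0)
spots = detect_spots(stack)
print("detected", len(spots), "spots; threshold =", round(spots.threshold_used, 1), "ADU")

# --- dSTORM morphometry ----------------------------------------------------
acq2 = AcquisitionParams(fov_side=97, n_frames_storm=4000)
rng = np.random.default_rng(1)
aggs = [make_disc((3000.0, 3000.0), 0.045, rng),      # round aggregate
        make_fibril((7000.0, 7000.0), 0.06, rng)]     # fibrillar aggregate
table, _ = simulate_storm_table(aggs, acq2, drift=(0.0125, 0.0),
                                blink=BlinkParams(), seed=1)
morphs, _ = process_table(table, acq2.n_frames_storm, acq2.fov_side_nm)
for m in morphs:
    print(f"label {m.label}: area {m.area:.3f} um^2, circularity {m.circularity:.2f}, "
          f"{m.n_localizations} localizations")

# --- cohort statistics -----------------------------------------------------
df = simulate_cohort_summaries(CohortSpec(seed=0))    # 10 PD vs 10 control
results = CohortModel(df).fit()
print(results.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

Output:

```
detected 5 spots; threshold = 137.8 ADU
label 1: area 0.048 um^2, circularity 0.79, 627 localizations
label 2: area 0.069 um^2, circularity 0.22, 856 localizations
      measure      test  statistic     df     p  effect_size effect_kind   auc  cutoff  sensitivity  specificity
   count_asyn  wilcoxon     63.000    NaN 0.345        0.220           r 0.630 163.500        0.500        1.000
  count_abeta   welch_t     -1.467 12.658 0.167       -0.656    cohens_d 0.355 130.500        1.000        0.100
        ratio  wilcoxon     67.000    NaN 0.212        0.287           r 0.670   0.832        0.500        1.000
    prop_area student_t      2.195 18.000 0.042        0.982    cohens_d 0.780   0.040        0.900        0.500
    prop_circ student_t      2.309 18.000 0.033        1.033    cohens_d 0.820   0.145        0.600        1.000
    prop_both student_t      2.206 18.000 0.041        0.986    cohens_d 0.790   0.103        0.600        0.900
discriminator  wilcoxon     76.000    NaN 0.054        0.439           r 0.760   0.086        0.500        1.000
```

The simulated disc measures circularity 0.79 and the fibril 0.22 — on the
correct sides of the 0.4 classification threshold — and both areas land within
~15% of the generated truth (0.045 and 0.06 µm²). In this single seeded
cohort the morphology proportions reach significance while the ratio alone
does not; pooled over many seeds the ratio contrast is significant in the
majority of cohorts (see the acceptance results below).

## Command line

```
pullstorm run-all --config config.yaml --seed 7     # full pipeline into a run directory
pullstorm simulate --seed 7 --out data/             # small synthetic dataset
pullstorm count    --input data/ --out counts.csv
pullstorm storm    --input data/ --out morph.csv
pullstorm analyze  --counts counts.csv --morph morph.csv --groups groups.yaml
```

Every run directory receives `counts.csv`, `morph.csv`, `summaries.csv`,
`comparisons.txt`, `roc.csv`, the resolved `config.yaml` and a `pipeline.log`
with per-stage row counts and exclusions. Exit codes: 0 success, 2 config
error, 3 stage failure. Fixed seed ⇒ byte-identical CSVs.

## Reproduction

```
pip install --no-build-isolation -e ".[test]"
python -m pytest tests                # full suite, ~4 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes every headline quantity from scratch
(~2 min): the published worked effect sizes (r = 0.490, 0.351, 0.625;
d = 1.082, 1.344, 1.368, 1.279; folds 2.23× and 1.86×), the ROC-AUC ≡
U/(n₁n₂) identity (max deviation ~1e-16), exact CDF-threshold oracle
agreement, drift recovery within 10 nm on a 100 nm ramp, detection
recall/precision ≥ 0.95 at SNR 10, ≥ 90% shape classification, uniform null
p-values (KS p = 0.25 at seed 1), a significant ratio contrast in the majority
of study-scale cohorts, and a combined-discriminator AUC at or above the
ratio-only AUC in 79% of 100 seeded cohorts.

See `docs/methods.md` for the full description of the algorithms, parameter
defaults and the generative model, including its known limitations.
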