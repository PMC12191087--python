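# adcqual

Early quality assessment for prostate MRI: predicting **non-diagnostic ADC
maps from the T2-weighted images acquired earlier in the same visit**.

ADC maps from diffusion-weighted imaging are central to prostate cancer
detection, but their echo-planar readout is vulnerable to susceptibility
distortion — especially from rectal gas — and the ADC acquisition is the
longest, latest step of a multi-parametric exam. A model that flags a likely
non-diagnostic ADC map *while the patient is still in the scanner*, using
only the routinely acquired T2 images, enables corrective action (patient
preparation, repositioning, protocol change) instead of a repeat visit.

`adcqual` implements the full pipeline on a synthetic phantom cohort with
planted, parameterized artifacts, so every stage has recoverable ground
truth:

- **phantom** — paired T2/ADC slice stacks with bladder/prostate/rectum
  anatomy, five artifact operators (gas susceptibility, motion ghosting, low
  contrast, aliasing, Rician noise), ordinal 1–3 quality labels with a
  calibrated correlation structure (within-visit T2↔ADC Pearson r, and
  same-patient cross-site r), and an acquisition-metadata table.
- **preprocess** — centred slice selection, CLAHE (clip 2.0, 8×8 tiles),
  center crop, three overlapping anatomical region windows, stochastic
  augmentation (flip / rotation / contrast / cutout).
- **ordinal** — compact CNN backbones with CORN (Consistent Rank Logits)
  ordinal heads: logit k models P(y > k | y > k−1), so rank probabilities
  are monotone by construction. Class-weighted CORN loss (lowest class ×5),
  Adam + decoupled weight decay, cosine learning-rate annealing, two-pass
  adaptive sharpness-aware (ASAM) updates, AUC-based early stopping.
- **fusion** — a three-level stack of L2 logistic regressions:
  networks → region score, regions → modality score, modalities → final
  score; positive class = non-diagnostic, threshold 0.5.
- **protocol** — patient-level 20% holdout + stratified 5-fold
  cross-validation with nested stacking and hard leakage guards; accuracy /
  NPV / PPV / specificity / sensitivity / midrank AUC.
- **rectal** — an interpretable alternative: few-shot support-conditioned
  soft segmentation of the rectum on the central T2 slice, soft-sum area in
  mm², Kruskal-Wallis + Dunn group tests, and piecewise (segmented)
  logistic regression `logit P = β₀ + β₁·area + β₂·(area − ψ)₊` with a
  profile-likelihood breakpoint ψ.
- **acqstats** — Kruskal-Wallis / exact Kolmogorov-Smirnov / threshold scans
  over acquisition parameters with Holm-Šídák or Bonferroni (Dunn-family)
  multiplicity control, plus a configurable protocol-adherence checker.

## Worked example

```python
from adcqual import phantom, protocol, workbench

cfg = workbench.desk_scale_config(60, 2, seed=1)          # 60 patients, 2 sites
visits, metadata = phantom.generate_cohort(cfg.phantom)
print(phantom.empirical_label_correlations(visits))

pcfg = protocol.ProtocolConfig(preprocess=cfg.preprocess, train=cfg.train,
                               k=3, seed=5)
res = protocol.run_protocol(visits, pcfg)
for name, agg in res.aggregate.items():
    print(name, round(agg["auc"][0], 3), "+-", round(agg["auc"][1], 3))
```

Output from this exact configuration:

```
{'cross_modality': 0.949, 'cross_site': 0.110, ...}
t2 0.846 +- 0.01
adc 0.856 +- 0.065
final 0.898 +- 0.03
```

Reading: the cohort was generated with strongly correlated modality quality
(empirical within-visit label correlation 0.95). On the untouched holdout
patients, the T2-only score — available before any diffusion imaging —
ranks ADC binary quality with AUC 0.85; the retrospective ADC score reaches
0.86, and fusing both modalities 0.90. At the larger desk-scale study size
(200 patients, 5 folds) the same pipeline reaches T2-only AUC ≈ 0.83 with
NPV ≈ 0.96 for the combined score: most scans are fine, and a negative call
is reliable — the operating regime a screening tool needs.

Everything is also scriptable from the shell:

```bash
adcqual generate --patients 50 --sites 2 --seed 1 --out data/
adcqual run-all --patients 60 --seed 1 --out results/
adcqual rectal-area --data data/ --out results/
adcqual acq-stats --data data/ --out results/
```

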