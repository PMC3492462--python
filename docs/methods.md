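# Methods

This note documents the models behind `radpanel`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where more than one reading was defensible.

## Study design

The simulated experiment is an ex vivo whole-blood model: blood from 5
healthy donors, drawn twice about a month apart, is split into four
treatment cultures per draw — untreated (N), 2 Gy X-rays (R), 50 ng/ml LPS
(L), and both (RL) — and assayed 24 h later. qPCR measures 13 DNA-damage
response transcripts plus two candidate reference genes (*ACTB*, *GAPDH*),
in technical triplicate; ELISA measures phospho-CHK2-thr68 (no standard
curve) and BAX (with one). The class order N < R < L < RL is fixed
throughout.

## qPCR generative model

Ct values are additive in cycles, equivalently multiplicative in
expression:

```
Ct(g, donor, draw, trt, rep) = B_g + u_donor + v_sample − log2 F_{g,trt}
                               + e_{g,sample} + ε_rep
```

* `B_g` — baseline Ct per gene (defaults 16–27 cycles, in the plausible
  qPCR range for blood transcripts).
* `u_donor ~ N(0, donor_sd)`, default 0.25 cycles — donor-level offset
  shared by every measurement from that donor.
* `v_sample ~ N(0, draw_sd)`, default 0.15 cycles — a loading/input
  effect of one culture aliquot, i.e. one (donor, draw, treatment) cell,
  shared across genes *within* that sample. Because each treatment arm of
  a draw is a separate culture, this term is what the reference-gene
  stability filter can trip on; had it been shared across treatments the
  filter would be vacuous.
* `F_{g,trt}` — the configured linear fold change versus N.
* `e_{g,sample} ~ N(0, response_sd)`, default 0.5 cycles, target genes
  only — per-gene biological response variability. This is the dominant
  dispersion in real fold-change data. The default is calibrated so that
  the *CDKN1A* radiation-vs-LPS contrast (true folds 7.3 vs 8.2, n = 10
  per group) is usually not significant by a two-sample t-test, matching
  the observed behaviour of that comparison; 0.5 cycles corresponds to a
  ~35–40% coefficient of variation on the expression scale. Reference
  genes carry no response term: they are modelled as stable by
  definition, with *GAPDH*'s LPS artefact added explicitly as a +0.54
  cycle shift under L and RL (the documented reason *GAPDH* is unusable
  as a control here).
* `ε_rep ~ N(0, tech_sd)`, default 0.15 cycles — technical replicate
  noise, independent per well.

Because `u` and `v` are shared across genes within a sample, ΔCt
normalization cancels them exactly; the model therefore makes ΔΔCt
identifiable and gives the normalization machinery something real to do.
With every SD at zero the generator is deterministic and all downstream
estimates recover their configured parameters exactly — the basis of the
pipeline's exactness tests.

Configured effect sizes use the known values where available (*FDXR* R:17,
L:1/1.5, RL:10; *CDKN1A* R:7.3, L:8.2, RL:10.2; *BBC3* R:2.7, L:1/2.9,
RL:1.7; *LIG1* R:2.3; *RAD51* R:1/2.5; *CHK2* unresponsive). Radiation
folds without a published magnitude (*GADD45a*, *PCNA*, *XPC*, *DDB2*,
*POLH*, *BAX*, *CCNG1*) are set once to documented defaults between 2 and
4 — inside the observed 2.3–17-fold range — and are overridable in
`GeneratorConfig`. The five LPS-insensitive panel genes get RL = R/1.2
(mild suppression, below the 1.4-fold significance bar); genes never
assayed under LPS keep L = 1 and RL = R.

## ΔΔCt estimation choices

* Technical replicates are averaged on the Ct scale before ΔCt — standard
  comparative-Ct practice for triplicate readout.
* The group fold is the **arithmetic mean** of per-donor-draw 2^−ΔΔCt
  values (`geometric=True` switches to the geometric mean). Under
  multiplicative noise the arithmetic mean estimates
  `F·exp(σ_ln²/2)` — about +0.8% at 0.1 cycles of noise, +13% at the
  default biological variability. The geometric mean is exactly unbiased
  on the log scale; recovery tests therefore check the arithmetic
  estimate against its own Monte-Carlo spread and the log-scale estimate
  against a 3-SEM band.
* t-tests run two-sided on the relative-expression (2^−ΔCt) values of the
  two groups, pooled-variance by default with a Welch option; with two
  exactly constant groups the limiting p (0 or 1) is returned rather than
  NaN.
* The reference-stability exclusion (|ΔCt_ref| ≥ 0.3 cycles) is applied
  per donor-draw pair per comparison — the least destructive reading of
  excluding "one sample" from one analysis — not globally.
* Each donor-draw is one observation (n up to 10 per group). Raw
  per-gene p-values are thresholded by default; `select_panel(fdr=True)`
  applies Benjamini–Hochberg adjustment across the candidate genes first.
* Panel selection: responsive = p < 0.05 and fold ≥ 2 (or ≤ 0.5);
  non-overlap additionally requires disjoint group ranges, the property
  that permits classification without a pre-exposure baseline.

## Panel score

"Mean normalization" is division by the per-gene grand mean over all
samples (not mean subtraction): the summed score is then positive,
equal to the panel size on average, and its ratio to the sham group is a
dose-dependent fold — which only division yields on linear intensities.
Matrices are assumed linear-scale; `log2_input=True` exponentiates first
(the storage scale must be declared, never guessed). For the
dose-response design the gene means pool both timepoints, while the
sham normalization is per timepoint; a config flag can split the gene
means per timepoint instead.

The dose-response generator uses mean intensity
`base·(1 + (F_R−1)·(d/2 Gy)^0.8·τ(t))` with τ(6 h) = 1.5, τ(24 h) = 1.0:
monotone in dose, anchored to the qPCR 2 Gy folds at 24 h, and stronger
at the earlier timepoint. The TBI design elevates post-irradiation
samples 3-fold on every panel gene over 14 healthy and 18 pre-irradiation
profiles. Both use lognormal noise (default log-SD 0.15); with the
default margin the post-TBI and baseline score distributions do not
overlap.

## ELISA

The standard curve is a four-parameter logistic
`y = d + (a−d)/(1+(x/c)^b)` — the universal immunoassay model — fitted
by `scipy.optimize.curve_fit` and inverted algebraically
(`x = c·((a−d)/(y−d) − 1)^{1/b}`). Absorbances outside the open asymptote
interval are flagged NaN, never extrapolated. A log-linear fallback is
available. Duplicate wells are averaged on absorbance before
interpolation. pCHK2-thr68 is handled curve-free as absorbance relative
to the sham mean (a paired-difference mode exists behind a flag); its
generator draws true levels `group_mean·exp(N(0, 0.0625))`, putting the
radiation group at 1.6 ± 0.1 relative to sham, plus 0.005 absorbance
units of plate noise, with typical readings inside 0.1–0.7. Group
inference log_e-transforms and mean-centers the readout before
two-sample t-tests.

## Classification

* **Gini ranking.** Node impurity is `G = 1 − Σ p_k²`. For one continuous
  marker restricted to a class pair, the marker's score is the minimum,
  over midpoints of consecutive sorted unique values, of the size-weighted
  mean impurity of the two children — a one-split decision stump, the
  canonical CART reduction of node impurity to a single continuous
  feature. Ties take the smallest threshold; marker ties break by name.
* **Ordering.** Pairs are visited in the fixed order (N,R), (N,L),
  (N,RL), (R,L), (R,RL), (L,RL) — the first two are prescribed, the rest
  follow lexicographic order over the class listing and are
  configurable. Selection runs rank-round by rank-round (rank 1 of every
  pair, then rank 2, …), taking each marker at its first appearance.
* **5NN.** k = 5 (odd, preventing two-way vote ties). Features are
  z-scored per marker with training-fold statistics inside each CV fold —
  transcript ratios and absorbances are on incommensurate scales, and
  fitting the scaler on the training fold avoids leakage (a raw-scale
  flag exists). Residual ties are fully determinised: neighbour
  candidates order by (distance, training index); class vote ties break
  by smallest mean neighbour distance, then canonical class order.
* **Cross-validation.** Ten repeats of stratified 10-fold CV; under the
  default 40-observation design each fold holds exactly one observation
  per class. Accuracy is averaged over repeats; confusion counts are
  pooled (total 400), and screening metrics come from the pooled counts
  (per-run averaging available behind a flag). The two draws of a donor
  are independent observations, as in the n = 40 construction; a
  donor-grouped CV flag supports sensitivity analysis.
* **Screening metrics.** Each class's 2×2 collapse of the 4×4 matrix
  gives sensitivity `M_cc/row_c`, specificity `TN/(total−row_c)`,
  PV+ `M_cc/col_c`, PV− `TN/(total−col_c)`; zero rows/columns yield
  flagged NaNs.

## What the generators do and do not emulate

The generators reproduce the study's design structure, effect sizes, and
plausible noise anatomy (donor, aliquot, biological response, technical).
They do **not** model cell-subtype composition shifts, time-course
kinetics beyond the assayed timepoints, amplification-efficiency
deviations from 2.0, plate-layout or inter-plate ELISA effects, or
non-Gaussian outliers. Passing tests therefore demonstrate that the
algorithms are correct and that the printed effect structure is
recoverable under realistic dispersion — not that the classifier's
absolute accuracy would transfer to any real cohort. In particular the
published single-marker (0.65) and 5-marker (0.88) accuracies derive from
raw measurements that are not publicly printed; on the calibrated
synthetic study the single best marker lands near 0.65 but the full-panel
ceiling is higher (~0.95), because synthetic noise is cleaner than real
biological data.

## Numerical notes and limitations

* Zero-variance t-tests return the limiting p-value rather than NaN.
* 4PL fitting needs ≥ 4 distinct standards and rejects flat responses;
  initialisation uses the absorbance extremes and the geometric-mean
  concentration.
* All randomness flows from `numpy.random.default_rng` seeds; a run's
  global seed derives per-stage seeds (< 2³¹), and identical seeds give
  bit-identical datasets, folds and reports.
* Monte-Carlo suites use 100 replicate studies for fold recovery and
  confounding checks and 10 permutations for chance-level classification;
  these sizes keep the full test suite under a minute while leaving
  3-SE/majority margins far from their thresholds.
* `fold_change_ddct` requires ≥ 2 matched pairs; fewer yields a flagged,
  statistic-free result rather than an exception.
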