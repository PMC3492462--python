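# radpanel

Radiation biodosimetry from peripheral blood: a tested, reusable
implementation of a transcript/protein biomarker-panel analysis for
distinguishing ionizing-radiation exposure from inflammation stress.

## The problem

After a radiological incident, triage needs a way to tell who absorbed a
medically significant dose — without a pre-exposure baseline sample, and
without confusing radiation injury with the inflammation (fever, infection,
endotoxin exposure) that will be common in the same population. DNA-damage
response transcripts in blood cells are strong radiation dosimeters, but
several of them also respond to inflammatory stimuli such as bacterial
lipopolysaccharide (LPS).

`radpanel` implements the complete analysis chain for a whole-blood model
that crosses a 2 Gy X-ray exposure with an LPS challenge in four groups —
untreated (**N**), radiation only (**R**), LPS only (**L**), and both
(**RL**) — across 5 donors, 2 blood draws each, with qPCR in triplicate:

1. **ΔΔCt quantification** (`radpanel.qpcr`). Technical replicates are
   averaged on the Ct scale; expression is normalized to the β-Actin
   (*ACTB*) endogenous control, ΔCt = Ct_target − Ct_ref, relative
   expression 2^−ΔCt; group fold changes are 2^−ΔΔCt per matched
   donor-draw pair. A stability filter drops any donor-draw pair whose
   reference-gene Ct differs by ≥ 0.3 cycles between the compared
   conditions (and *GAPDH* is rejected as a reference outright, because
   LPS shifts it by ~0.54 cycles). Panel selection keeps genes with
   p < 0.05 and ≥ 2-fold response, and flags the subset whose sham and
   irradiated expression ranges are fully disjoint — the markers usable
   with no baseline.
2. **Summed panel score** (`radpanel.score`). For validation expression
   matrices, each panel gene is divided by its grand mean (every
   normalized column has mean exactly 1), summed per sample, and expressed
   relative to a reference group (sham dose per timepoint, or healthy
   donors): `score_i = Σ_g x_ig / x̄_g`.
3. **ELISA quantification** (`radpanel.elisa`). Four-parameter logistic
   standard curves `y = d + (a−d)/(1+(x/c)^b)` fitted by least squares and
   inverted algebraically; curve-free markers (phospho-CHK2-thr68) read as
   absorbance relative to the sham mean; values are log_e-transformed and
   mean-centered before two-sample t-tests.
4. **Four-class screening** (`radpanel.classify`). For each of the 6 class
   pairs, each of the 9 markers (8 transcripts + pCHK2) is scored by the
   Gini impurity `G = 1 − Σ p_k²` of its best decision-stump split;
   markers are ordered by first appearance across the pairwise rankings,
   then a 5-nearest-neighbour classifier is evaluated by ten repetitions
   of stratified 10-fold cross-validation on nested marker subsets.
   Pooled confusion counts yield per-class sensitivity, specificity, PV+
   and PV−.

A calibrated synthetic-data generator (`radpanel.simulate`) reproduces the
study design and effect sizes (e.g. *FDXR* 17-fold, *CDKN1A* 7.3-fold under
radiation; *CDKN1A* 8.2-fold under LPS alone), so the whole pipeline is
testable end to end without any external data.

## Worked example

```sh
radpanel run --seed 1 --out demo/
# panel: 9 non-overlapping genes; CV accuracy 0.953
```

`demo/` now holds CSVs for every stage. The marker ordering and accuracy
curve from this run:

```text
$ head -4 demo/accuracy_curve.csv
n_markers,added_marker,accuracy
1,BBC3,0.64
2,CDKN1A,0.7975
3,pCHK2,0.9499999999999998
```

One marker alone classifies 64% of the 40 observations into the right one
of four classes; adding the second-ranked transcript and the phosphoprotein
(which is suppressed by LPS, so it splits R from RL) lifts accuracy to 95%,
after which the curve plateaus. The screening table for the full panel:

```text
$ cat demo/screening_metrics.csv
class,sensitivity,specificity,ppv,npv,flag
N,1.0,1.0,1.0,1.0,
R,0.9,0.97,0.9090909090909091,0.9667774086378738,
L,1.0,1.0,1.0,1.0,
RL,0.91,0.9666666666666667,0.900990099009901,0.9698996655518395,
```

Misclassifications concentrate in the R↔RL pair — exactly the confusion
the protein marker was added to resolve, and the hardest contrast by
construction. The same stages are available as library calls:

```python
import radpanel as rp
from radpanel import qpcr

ct = rp.generate_ct_dataset(rp.default_config(seed=1))
rel = qpcr.delta_ct(qpcr.collapse_replicates(ct), "ACTB")
r = qpcr.fold_change_ddct(rel, "FDXR", "R", "N")
print(round(r.mean_fold, 1), r.nonoverlap)   # 25.7 True
```

(The configured *FDXR* effect is 17-fold; a single simulated study of 10
donor-draw pairs under the default biological variability estimates it
with the same wide dispersion real qPCR fold data shows. With the noise
parameters set to zero the estimate is exactly 17.0.)

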