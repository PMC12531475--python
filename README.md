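# agreekit

Agreement analysis for binary clinical ratings: observed, specific and
chance-corrected agreement for two **or more** observers, delta-method and
bootstrap confidence intervals, and sample-size planning — built for
studies like inter-observer CTG (cardiotocograph) classification, where
several clinicians label the same patients *normal*/*abnormal* and the
question is how well they agree and how reliably the scale separates
patients.

## The statistics

For two observers classifying N objects into a 2×2 table with cells
n11, n12, n21, n22 (proportions p_jk, marginals p1., p.1):

* proportion of agreement  `po = p11 + p22`
* specific positive / negative agreement (Dice / F1)
  `ppos = 2 n11 / (2 n11 + n12 + n21)`,  `pneg = 2 n22 / (2 n22 + n12 + n21)`
* Jaccard `pJ = n11 / (n11 + n12 + n21)`, linked exactly by
  `pJ = ppos / (2 − ppos)`
* chance-corrected agreement `κ = (po − pe) / (1 − pe)` under three chance
  models: a fair coin (`pe = 0.5`, the G index / PABAK), observer-specific
  coins (Cohen), or one pooled coin (Scott's pi / intraclass kappa), plus
  Krippendorff's alpha (finite-sample-corrected) and Gwet's AC1.

With R observers every coefficient is the (weighted) mean over all
R(R−1)/2 observer pairs, computed from the per-patient counts m_i1 of
positive ratings, e.g.

```
po = (1/N) Σ_i [m_i1(m_i1−1) + m_i2(m_i2−1)] / (R_i(R_i−1))
ppos = Σ_i m_i1(m_i1−1)/(R_i−1) / Σ_i m_i1      (pooled generalization)
```

giving Conger/Hubert kappa (observer-specific chance) and Fleiss kappa
(pooled chance). Point estimates are exact rationals; standard errors come
from closed-form multinomial delta formulas (two observers) or per-patient
influence values (R > 2), with patient-bootstrap and Fisher-Z intervals as
alternatives. Sample-size calculators answer "how many patients for a CI
of width w?" and "how many patients to show agreement exceeds ρ0?" under a
latent two-class planning model.

## Worked example

The built-in fixture is the classic study in which five obstetricians
(A–E) each classified 20 CTGs, flagging 6, 6, 9, 7 and 12 of them as
abnormal:

```
$ agreekit fixture --out ctg.csv
positive_counts: {'A': 6, 'B': 6, 'C': 9, 'D': 7, 'E': 12}
po: 0.73
ppos_pooled: 0.66
kappa_def2: 0.45

$ agreekit agree --input ctg.csv --coef po,ppos,pneg,kappa --chance def2 --ci wald
coefficient  estimate  se  lower  upper  method  chance
po  0.73  0.05  0.63  0.83  wald_delta
ppos  0.66  0.1  0.46  0.86  wald_delta
pneg  0.78  0.05  0.68  0.87  wald_delta
kappa  0.45  0.12  0.21  0.68  wald_delta  def2
```

Any pair of obstetricians agrees on 73% of tracings on average, but only
66% of positive calls are matched by the partner, and after removing
observer-specific chance agreement just under half of the non-chance
disagreement is resolved (κ₂ = 0.45, 95% CI 0.21–0.68 — wide, because 20
patients carry little information). Planning a follow-up study to *show*
agreement exceeds 0.80 when it is truly 0.85 (one-sided α = 0.05, power
0.80, 35% abnormal):

```
$ agreekit design --mode power --prevalence 0.35 --rho0 0.80 --rho-a 0.85 --raters 3-8
n_raters  min_patients
3  192
4  140
5  110
6  91
7  77
8  67
```

The same computations are available as a library:

```python
import agreekit as ak
t = ak.PairTable(6, 0, 3, 11)          # obstetricians A and C
float(ak.kappa_pair(t, "def2"))        # 0.6875
ak.se_kappa_pair(t, "def2")            # 0.158
```

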