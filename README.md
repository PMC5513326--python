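# pairedsse

Sample-size estimation and interim re-estimation for **paired comparative
diagnostic accuracy studies** with a binary gold standard.

## The problem

Two index tests, a new test A and a comparator B, are applied to every
subject, and a gold standard classifies each subject as diseased or
non-diseased. The study tests superiority of A on both endpoints — the
ratio of sensitivities γ₁ = TPR_A/TPR_B and the ratio of specificities
γ₂ = TNR_A/TNR_B — and is sized to the larger of the two endpoint
requirements. The size needed to power the sensitivity comparison is

```
n = ( (z₁₋β + z₁₋α/₂) / log γ₁ )² · ((γ₁+1)·TPR_B − 2·TPPR) / (γ₁·TPR_B²) / π
```

where π is the disease prevalence and **TPPR** is the probability that a
diseased subject is positive on *both* tests (the specificity formula is
the same with TNR, TNNR and 1 − π). TPPR encodes the conditional
dependence between the tests within the diseased stratum: given the
marginals, it can range from TPR_B − (1 − TPR_A) (maximal negative
dependence, largest study) up to TPR_B (maximal positive dependence,
smallest study). This dependence is almost never known at the design
stage, so planning at the worst case can more than triple the study.

`pairedsse` implements the adaptive alternative: at a planned interim,
estimate TPPR (and TNNR) by **maximum likelihood under the constrained
multinomial model** whose cell probabilities are pinned to the
hypothesised marginals,

```
L(p₁ | x) = p₁^x₁ (TPR_A − p₁)^x₂ (TPR_B − p₁)^x₃ (1 − TPR_A − TPR_B + p₁)^x₄ ,
p₁ ∈ [TPR_B − (1 − TPR_A), TPR_B],
```

and feed the MLE back into the closed form to re-estimate the study size.
Unlike the naive plug-in of raw observed proportions — which can even
return a negative size — the constrained MLE always lies in the feasible
range. A Monte-Carlo engine simulates the whole adaptive pipeline
(interim draw → re-estimate → complete recruitment → pooled ratio test)
to verify type-I error, power, bias, coverage and the RMSE of the
re-estimated size.

## Worked example

A study of augmenting the standard diagnostic battery for pancreatic
cancer with a PET/CT scan hypothesised sensitivity rising from 0.81 to
0.90, specificity from 0.66 to 0.80, at prevalence 0.47:

```python
from pairedsse import DesignHypotheses, PairedCounts, plan_study, reestimate

h = DesignHypotheses(alpha=0.05, beta=0.2, tpr_a=0.90, tpr_b=0.81,
                     tnr_a=0.80, tnr_b=0.66, prevalence=0.47)
worst = plan_study(h, assume="worst")
best = plan_study(h, assume="best")
print(worst.n_sensitivity, worst.n_specificity)   # 598 409
print(best.n_sensitivity, best.n_specificity)     # 186 106
```

The dependence assumption moves the study between 186 and 598
participants, so an interim re-estimation was planned. After 187
participants the eight-cell table was (diseased: 66, 3, 3, 10;
non-diseased: 21, 4, 11, 69):

```python
interim = PairedCounts(66, 3, 3, 10, 21, 4, 11, 69)
r = reestimate(interim, h, prevalence_source="interim", rounding="up")
print(round(r.tppr_mle, 3), round(r.tnnr_mle, 3))  # 0.793 0.635
print(r.n_sensitivity, r.n_specificity, r.n_overall)  # 275 136 275
```

The interim data point to strong positive dependence between the tests,
cutting the required recruitment from 598 to 275 while preserving the
nominal 80% power.

The same operations are available from a CLI (`pairedsse plan`,
`pairedsse reestimate`, `pairedsse test`, `pairedsse simulate`), each
emitting machine-readable JSON or CSV; see `pairedsse --help`.

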