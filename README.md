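# markermi

Threshold-free analysis of marker co-expression in multiplex imaging
data.

Multiplex platforms (mIHC, MIBI, IMC) measure continuous per-cell
intensities for many protein markers. Whether markers co-express in a
subject's tumor microenvironment — and whether that co-expression
predicts outcomes such as survival or recurrence — is usually assessed
by binarizing each marker at a positivity cutoff and counting
multi-positive cells. Cutoff choice is subjective and discards
information. `markermi` instead measures dependence between the raw
intensities directly, with a mutual-information statistic that needs no
thresholds, captures non-linear dependence and extends to any number of
markers.

## The statistic

For subject *j*, with joint density *f₁..p* of the *p* marker
intensities and marginals *f_k*, the standardized Euclidean quadratic
mutual information is

    EQMI* = (V_J − 2·V_C + V_M) / (V_J + V_M) ∈ [0, 1]

where `V_J = ∫ f₁..p²`, `V_C = ∫ f₁..p · Π f_k`, `V_M = ∫ (Π f_k)²`.
EQMI* is 0 exactly under independence. Plugging Gaussian kernel density
estimates into the integrals gives closed-form pairwise kernel sums
(no p-dimensional grid, O(n²·p) per subject), valid for unequal
per-marker bandwidths chosen by a plug-in rule or Silverman's rule.
The per-subject values **E** = (E₁, …, E_N) are then tested against
outcomes: OLS/Wald for continuous, logistic/Wald for binary, Cox
proportional hazards with a likelihood-ratio test for right-censored
survival. The traditional quantile-thresholding pipeline and the
absolute-Pearson-correlation statistic are included as baselines, along
with simulation scenarios and an empirical-power engine to compare all
methods.

## Worked example

Simulate a 10-subject cohort in which half the subjects have markers
coupled through a Gaussian copula (correlation 0.75–0.9) and half are
nearly independent, then test the per-subject EQMI* against a continuous
outcome that differs between the groups:

```python
from markermi import (CoexpressionModel, SimScenario, generate,
                      simulate_outcomes)

scn = SimScenario(scenario_tag="copula2", N=10, ncells=500, seed=7)
cells, groups = generate(scn)                       # CellTable + group labels
outcome = simulate_outcomes(groups, beta=2.0, sigma=0.5,
                            outcome_reps=1, seed=8)[0]

res = CoexpressionModel(cells, outcome).fit()
print(res.summary())
```

```
Marker co-expression association
================================================
statistic:      eqmi_star
markers:        M1;M2
outcome type:   continuous
subjects used:  10
E mean (sd):    0.0724 (0.0763)
------------------------------------------------
coefficient:    -13.5302
WALD p-value:    0.002409
================================================
```

The dependent group carries outcome mean 0 and the independent group
mean β = 2, so the negative coefficient (≈ −13.5 per unit of EQMI*,
which spans only ≈ 0.2 here) and the small Wald p-value recover the planted
association: subjects with higher marker co-expression have
systematically lower outcome values. `res.per_subject` holds the
per-subject EQMI*, bandwidths and cell counts.

The same analyses are available from the shell:

```sh
markermi simulate --scenario copula2 --n-subjects 10 --ncells 500 \
    --seed 7 --out cells.csv
markermi eqmi --input cells.csv --markers M1,M2 \
    --outcome cells.subjects.csv --out eqmi.csv
markermi power --scenario squared --methods eqmi,corr \
    --betas 0,1,2 --repeats 5 --outcome-reps 20 --out power.csv
```

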