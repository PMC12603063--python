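# grouplearn

Computational modeling of how impressions of social groups change through
direct experience. In the task this package models, participants repeatedly
receive good or bad monetary outcomes from members of their own group
(ingroup) and another group (outgroup) — 96 trials in 4 blocks, 75%
positive events, identical objective experience with both groups — under
one of two mathematically equivalent payoff frames (money given vs money
taken from an endowment). On every trial they rate their expectancy of a
positive outcome and their social closeness to each group; impressions of
both groups are measured before and after learning.

The package is aimed at computational cognitive modelers: it implements the
full modeling pipeline as a tested library (`src/grouplearn/`) plus a set
of numbered analysis drivers (`analysis/`) that run it end to end on
synthetic data generated by the package itself.

## Models

**Expectancy (Rescorla–Wagner family).** Each group *i* carries a value
*V<sub>i</sub>(t)* updated from the prediction error of its own outcomes:

> δ<sub>i</sub>(t) = R(t) − V<sub>i</sub>(t),  V<sub>i</sub>(t+1) = V<sub>i</sub>(t) + α δ<sub>i</sub>(t),  rating(t) = β·V<sub>i</sub>(t)

with α ∈ [0,1], β ∈ (0,3]. Three variants: **M1** one shared α; **M2**
α per group; **M3** α per group × error valence (four rates).

**Closeness (discounted prediction-error models).** The trial-wise change
in rated closeness to group *i* is a linear function of exponentially
discounted sums of that group's past prediction errors:

> **C1**: ΔCloseness<sub>i</sub>(t) = W0 + W·Σ<sub>j≤t</sub> γ<sup>t−j</sup> δ<sub>ij</sub>
> **C2**: ΔCloseness<sub>i</sub>(t) = W0 + W<sub>pos</sub>·Σ γ<sup>t−j</sup> δ<sup>pos</sup><sub>ij</sub> + W<sub>neg</sub>·Σ γ<sup>t−j</sup> δ<sup>neg</sup><sub>ij</sub>

with W ∈ [−10,10], W0 ∈ [0,10], γ ∈ [0,1]. Trials belonging to the other
group contribute a prediction error of zero but still advance the discount
clock.

Models are fitted per participant by least squares under a Gaussian
likelihood (multi-start bounded quasi-Newton; the conditionally linear
closeness problem is profiled over γ), compared by AIC = −2 ln L + 2k and
random-effects Bayesian model selection (exceedance probabilities from a
variational Dirichlet posterior). The pipeline is validated by parameter
recovery (true-vs-refitted Pearson correlations over 100 simulations) and
model identifiability (confusion matrices over 30-agent cohorts × 10
repetitions), and closed by regression/moderation analyses linking fitted
parameters to pre/post impression change.

## Worked example

```python
from grouplearn.task_design import make_schedule
from grouplearn.learning_models import LearningParams
from grouplearn.synthetic_data import AgentProfile, generate_session
from grouplearn.closeness_models import ClosenessParams
from grouplearn.fitting import fit_learning

schedule = make_schedule(n_blocks=4, block_length=24, positive_rate=0.75, seed=1)
profile = AgentProfile(
    participant="demo", frame="loss",
    learning=LearningParams(0.4, 0.2, 0.5, 0.3, beta=1.0,
                            v0_ingroup=0.5, v0_outgroup=0.6),
    closeness_in=ClosenessParams(0.2, 2.0, 3.0, 0.6),
    closeness_out=ClosenessParams(0.2, 1.0, 1.0, 0.6),
    identification=4.0, impression_pre_in=6.0, impression_pre_out=5.5,
)
session = generate_session(profile, schedule, seed=7)
fit = fit_learning(session, "M3", n_restarts=10, seed=0)
print({k: round(float(v), 3) for k, v in fit.params.items()}, round(fit.r2, 3))
```

prints

```
{'alpha_in_pos': 0.325, 'alpha_in_neg': 0.162, 'alpha_out_pos': 0.477,
 'alpha_out_neg': 0.303, 'beta': 0.963} 0.581
```

— the four generating learning rates (0.4, 0.2, 0.5, 0.3) and β = 1 are
recovered from a single noisy 96-trial session to within estimation error,
with r² = 0.58 of the expectancy series explained.

The numbered scripts run the same machinery at study scale:
`analysis/01_simulate_study.py` (two culture-profile cohorts, n = 112 and
100) through `analysis/06_linkage.py` (stepwise regression, frame and
identification moderation, influence diagnostics), writing tables under
`results/`. On the default seeds, M3 and C2 win model comparison with
exceedance probability ≈ 1.0 in both cohorts, and the loss-frame stepwise
regression recovers the planted negative association between the weight on
negative ingroup prediction errors and intergroup impression change.

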