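# premopt

Key-driver prioritization for inpatient satisfaction surveys: fit a
proportional-odds model of overall satisfaction on patient-reported experience
measures (PREMs), then solve a constrained optimization that selects the most
efficient combination of per-item improvements achieving a target gain in
predicted satisfaction — reported separately per departmental area (surgical
vs. medical discharge).

The package is aimed at healthcare-quality analysts who collect hospitalization
PREM questionnaires (19 experience items plus one overall-satisfaction item,
all on 1–5 Likert scales) and need to answer: *which experience items should be
improved, and by how much, to raise overall satisfaction by t%, at minimum
total effort?*

## Model and optimization

**Stage 1 — ordinal regression.** Overall satisfaction Y ∈ {1,…,5} follows a
cumulative-logit (proportional-odds) model per stratum,

    P(Y ≤ k | x) = F(κ_k − Σ_j b_j x_j),   k = 1..4,

with F the standard logistic CDF, x_j the 1–5 experience scores entered as
continuous predictors, and κ_1 < … < κ_4 the cutpoints (no separate
intercept).  Estimation is exact maximum likelihood with analytic score,
deterministic initialization and observed-information standard errors
(`premopt.ordinal_model`); a positive b_j means a better experience on item j
raises the odds of a higher satisfaction category.

**Stage 2 — capped-improvement optimization.** With x̄_j the stratum item
means and S(x) the model-predicted satisfaction (expected score Σ_k k·p_k by
default, top-box P(Y = 5) optionally), choose percent improvements δ_j to

    minimize  Σ_j δ_j
    s.t.      100 · (S(x̄ ⊙ (1 + δ/100)) − S(x̄)) / S(x̄) ≥ t
              0 ≤ δ_j ≤ min(c, 100·(5 − x̄_j)/x̄_j)

with a per-item cap c (default 15%) further tightened by the 1–5 scale
ceiling.  Because the linear predictor is linear in δ and S is strictly
increasing in it, the problem is a continuous knapsack solved exactly
(`premopt.optimizer`); a brute-force grid oracle independently verifies
solutions on small instances.  Targets above the feasibility bound (every
eligible item at its cap) are flagged infeasible — with satisfaction baselines
near the top of the scale, gains beyond a few percent are typically
unreachable.

Because the underlying respondent-level survey data are confidential,
`premopt.synthetic_data` generates surveys with the documented structure of
the real ones (top-skewed items, inter-item correlation, published per-area
regression coefficients and cutpoints, monotone questionnaire drop-off), so
the full pipeline is testable end to end.

## Worked example

```python
import premopt as po

scenario = po.default_scenario("surgical", seed=1)      # published estimates
data = po.generate_survey(scenario)                      # synthetic survey
fit = po.fit_collapsed_proportional_odds(data, stratum="surgical")
items = list(fit.item_ids)
complete = po.listwise_complete(data, ["satisfaction", *items])
baseline = complete.frame[items].mean().to_numpy(float)

problem = po.ImprovementProblem(fit=fit, baseline=baseline, target=1.0)
print("baseline predicted satisfaction:", round(po.baseline_score(problem), 3))
print("feasibility bound: %.2f%%" % po.feasibility_bound(problem))
table = po.build_priority_table(fit, baseline, targets=[1, 2, 3, 4, 5])
frame = table.to_frame()
print(frame[(frame != "").any(axis=1)])
```

prints

```
baseline predicted satisfaction: 4.687
feasibility bound: 6.11%
                      1%   2%    3%    4%    5%
item
fear_anxiety_nurses                         8.5
pain_management                       1.5   4.9
teamwork             2.9  6.2  10.1  14.4  14.4
discharge_selfcare                         12.7
required_items_n       1    1     1     2     4
```

Read column "4%": improving teamwork by 14.4% of its baseline mean and pain
management by 1.5% raises predicted satisfaction by 4%; a 1% gain needs a
single item, and the required-item count grows with the target until the 6.11%
feasibility bound, beyond which no combination of capped improvements
suffices.  (Which items are selected depends on the seed-drawn synthetic
baselines: effort per percentage point buys b_j·x̄_j units of linear
predictor, so high-coefficient, high-baseline items with headroom win.)

The same analysis runs from the shell:

```
premopt simulate --area both --seed 1 --out survey.csv
premopt run --input survey.csv --targets 1,2,3,4,5 --out report/
```

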