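# netpanel

Longitudinal egocentric network panel analysis for hidden-population
cohort studies — with a fully synthetic, seeded cohort generator so
every stage of the analysis is testable without access to restricted
study data.

## The problem this package addresses

Cohort studies of hidden populations (here: young Black transgender
women, TGW, and Black men who have sex with men, MSM) often recruit by
**respondent-driven sampling** (RDS): a small set of well-connected
seeds receive a limited number of coupons and recruit their peers, and
so on, producing a recruitment forest. At each survey wave respondents
complete bounded **name generators** — up to 5 confidants ("people with
whom you discuss things that are important to you") and up to 6 sexual
partners (5 most recent plus the current primary partner). At later
waves respondents confirm which listed alters match earlier
nominations; those respondent-confirmed matches are the only identity
information available across waves.

From such data, analysts want to quantify how much each respondent's
network *churns* between visits, how respondents are positioned in the
composite sociometric network, how their networks are composed, and
whether these quantities differ between groups. `netpanel` implements
that whole pipeline:

* **Tie churn.** For an ego with ordered attended visits v1..vk, let
  O be the original network size (the v1 roster), R the retained ties
  (original alters present at every later attended visit), N the new
  ties (alters first nominated after v1), L the lost ties (original
  alters that disappeared between consecutive visits), and C the
  cumulative network size (unique alters over all visits, C = O + N).
  Then

  - **stability ratio** = R / O
  - **turnover ratio** = (N + L) / C

  Each alter contributes at most once to N + L, which bounds turnover
  by 1 and makes turnover = 1 − R/C an exact identity for two-visit
  egos.

* **Structure.** The composite graph joins RDS, confidant, and sexual
  edge layers. Per node: degree k; betweenness centrality normalized
  by (n−1)(n−2)/2; closeness centrality over the reachable set with
  the component-size correction (r−1)/(n−1); and the mean geodesic
  distance to reachable nodes.

* **Composition and comparison.** Per-ego covariates from the resolved
  rosters (proportion of transgender confidants, HIV-positive
  confidants, exchange-sex partners, partner preferences, ...), Welch
  t-tests, chi-square / Fisher exact tests, and unadjusted
  logistic-regression odds ratios comparing TGW with MSM (reference),
  with a Haldane–Anscombe-corrected 2×2 fallback when a zero cell
  defeats maximum likelihood.

* **Simulation.** A two-block random-graph hidden population with
  group homophily, coupon-based RDS recruitment, per-tie retention and
  Poisson new-tie arrival dynamics, group-specific wave attrition
  (0.864 MSM / 0.667 TGW by default), and roster emission with caps
  and respondent-confirmed matches — plus ground truth for every
  nomination, so estimators can be validated against known parameters.

## Worked example

```python
from netpanel.simulate import SimulationConfig, simulate_cohort
from netpanel.roster import from_simulation
from netpanel.dynamics import cohort_dynamics

sim = simulate_cohort(SimulationConfig(rng_seed=1))   # 618-ego, 3-wave cohort
ds = from_simulation(sim)                             # validate + resolve identities
summaries, comparisons, excluded = cohort_dynamics(ds)
print(comparisons[["kind", "ratio", "mean_tgw", "mean_msm",
                   "t_statistic", "p_value"]].round(3).to_string(index=False))
```

prints

```
     kind     ratio  mean_tgw  mean_msm  t_statistic  p_value
confidant stability     0.184     0.173        0.307    0.760
confidant  turnover     0.873     0.879       -0.215    0.831
   sexual stability     0.105     0.108       -0.061    0.952
   sexual  turnover     0.954     0.922        1.827    0.074
```

Reading this: each row compares the group means of one churn ratio in
one roster kind, with a two-sided Welch t-test. Mean three-visit
strict-retention stability near 0.17–0.18 is what the default
wave-to-wave retention probabilities (~0.41 confidant, ~0.28 sexual,
compounded over two inter-wave intervals) imply. With only ~45 TGW in
a 618-ego sample the TGW means are noisy, so none of the group
differences reach significance in this particular draw.

The same analysis runs from the shell, end to end:

```sh
netpanel all --seed 1 --out results/run1
netpanel simulate --seed 1 --out data/      # or stage by stage
netpanel dynamics --in data/ --out results/
```

Outputs are delimited text tables (`tie_change_summaries.csv`,
`ratio_comparisons.csv`, `structure_comparison.csv`,
`baseline_table.csv`, `network_odds_ratios.csv`), a GraphML export of
the composite network, and a `summary.json` with the seed, every flag,
and record counts. Runs are byte-identical given the same seed.

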