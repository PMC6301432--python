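# Methods

This note documents the models, estimators, and numerical choices in
`netpanel`, what the synthetic cohort generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## 1. The cohort simulator

### Population model

The hidden population is a fixed set of `population_size` members,
each labeled TGW with probability `prop_tgw` (default 0.16) and MSM
otherwise. Confidant and sexual ties are drawn independently from a
**two-block degree-homogeneous random graph**: the per-pair Bernoulli
probability is proportional to a symmetric 2×2 `mixing` weight matrix
(default within-group 1.0, between-group 0.3) and scaled so the
population mean degree equals `mean_confidant_degree` (default 5) and
`mean_sexual_degree` (default 4). This is the simplest structure that
exposes group homophily; degree-corrected block models are out of
scope.

A consequence worth noting: with homophilous mixing and unequal group
sizes, the smaller group has lower expected degree, and degree-weighted
RDS recruitment under-samples it. The default population share of 0.16
was chosen once so that the *emitted sample* lands near the reference
composition of 7.6% TGW in a 618-ego sample; the default attrition
retentions (0.864 MSM, 0.667 TGW), seed count (62), sample size (618),
wave count (3), and roster caps (5 confidants; 5 recent + 1 primary
sexual partner) are the reference study conditions directly.

### Recruitment

Seeds (default 62) are drawn without replacement, degree-weighted by
default — seeds in such studies are deliberately well-connected —
with a uniform option. Recruitment propagates over confidant ties only
(coupons pass through social, not sexual, contacts; a union option
exists). Every enrollee offers at most `coupons_per_recruit` (default
3; the instrument's true coupon count is not public, so this is a
documented assumption) coupons to currently unenrolled neighbors;
coupons are redeemed breadth-wise in issue order; recruitment halts at
`target_sample` or queue exhaustion, the latter reported as a warning
with the achieved size, never an exception. The result is a forest:
acyclic, one recruiter per non-seed, out-degree ≤ the coupon cap.

### Tie dynamics and attrition

Between waves each existing tie persists independently with
`retain_prob[kind, group]`; since a tie joins two members whose groups
may differ, the probability used is that of a uniformly chosen "owner"
endpoint. Experiments that need exact group attribution (parameter
recovery) set the between-group mixing weight to 0 so owner and ego
group always coincide. New ties arrive per member as a Poisson draw
with mean `new_tie_rate[kind, group]`, attached to uniformly chosen
eligible partners. Default retention probabilities (0.408/0.334
confidant, 0.278/0.175 sexual for MSM/TGW) are the values that, for a
two-visit design with no arrivals, reproduce stability ratios of the
size reported for this kind of cohort; the default arrival rates were
chosen once to put turnover in the 0.6–0.85 range.

Attendance is universal at wave 1; at each later wave an ego attends
with the group's `attrition_retention`, drawn independently per wave.
Independence (rather than conditioning on the previous wave) lets
non-monotone patterns occur — an ego seen at waves 1 and 3 only — which
the dynamics module must and does handle.

### Roster emission and matches

Per attending ego and kind, the roster is the current tie set, uniform
subsample when over the cap (the instrument imposes no salience
ordering, so uniform is the neutral choice; all subsampling is seeded).
For sexual rosters, an ego in a relationship names a primary partner
drawn from their current sexual ties; if already listed the existing
row is flagged rather than duplicated, otherwise a sixth row is
appended. Wave-1 sexual rosters carry a "past 6 months" window label,
later waves "since the last interview"; the label is metadata and does
not change computation. Matches link each nomination to the same
alter's most recent earlier nomination by the same ego and kind —
confirmation against wave w−1 at wave 2 and cumulatively at wave 3+,
exactly as a cumulative confirmation list would behave. Simulated
confirmation is perfect; imperfect confirmation is modeled in tests by
deleting match records.

All randomness streams from one master seed through named
sub-generators (population, recruitment, dynamics, attrition, rosters,
covariates), so stages are independently reproducible and equal seeds
give byte-identical tables.

### What the generator does not emulate

No coupon expiry or incentives, no geography, no degree correction, no
cis-women partners (all simulated partners come from the two-group
population, so the cis-women covariates are structurally empty in
simulation and exercise the zero-cell fallback), no measurement error
in alter attributes, and no informative (network-position-dependent)
attrition. Passing tests therefore demonstrate correctness of the
estimators under these idealized conditions, not robustness to the
messiness of real field data.

## 2. Identity resolution

Alter identities are the connected components of the match graph over
nominations, **per ego and per kind** — the instrument never links
alters across respondents, and cross-kind (confidant ≡ sex partner)
overlap is kept as a flag rather than a merged identity so each network
remains separately analyzable. Matches are processed in canonical
sorted order, making resolution idempotent and independent of input row
order. A match whose acceptance would merge two same-wave nominations
(one person cannot appear twice on one list) is skipped and reported;
how the field study reconciled such conflicts is not documented, so
this split-and-report rule is an implementation choice. Unmatched
nominations become singleton alters. Component labels are the
lexicographically smallest member nomination id; all downstream
statistics are invariant to relabeling.

## 3. Stability and turnover

Definitions as in the README: stability = R/O, turnover = (N + L)/C.
Three counting decisions deserve justification:

* **Retained (default "strict")**: an original alter present at every
  subsequent attended visit. The alternative — present at *any* later
  visit — is available as `retained_rule="any-later"` and reported side
  by side; with two visits they coincide.
* **Each alter counts at most once in N + L.** A tie lost and later
  regained counts one loss (and no new tie, since the alter was already
  in C); a tie first acquired after v1 and later dropped counts once,
  as new. Counting every per-transition disappearance separately looks
  natural but allows (N + L)/C > 1 — a single-alter example: rosters
  {a}, {b}, {c} across three visits would give N = 2, L = 2, C = 3 —
  whereas per-alter counting guarantees turnover ∈ [0, 1] and yields
  the exact two-visit identity turnover = 1 − R/C. Reported values of
  this statistic in the field respect the [0, 1] range.
* **Eligibility.** Ratios are computed for egos with ≥ 2 attended
  visits, using their attended-visit sequence without interpolation.
  An ego with O = 0 (or C = 0) gets an undefined-ratio signal and is
  excluded from group means with a logged reason — never a zero.

Group comparison uses Welch's unequal-variance t-test by default
(robust to the group-size imbalance typical here); pooled-variance is a
flag. Zero variance in both groups is reported as a degenerate test,
not a p-value.

## 4. Structural metrics

Metrics are computed on the full composite graph (egos plus alter
nodes) and compared across groups over enrolled egos only. On observed
data the same real person named by two egos cannot be merged — matches
are confirmed only within a respondent's own lists — so each ego's
alters are distinct nodes; this inflates path lengths and is a
structural limitation mirroring the instrument itself. On simulated
data, ground-truth identities can merge alters across egos
(`merge_alters=True`), which tests use to check edge counts against
the true pair set.

Numerical conventions: betweenness normalized by (n−1)(n−2)/2;
closeness over each node's reachable set scaled by (reachable−1)/(n−1)
(the standard component-size correction; harmonic closeness by flag);
mean geodesic distance over reachable nodes, NaN for isolates;
isolated nodes get betweenness and closeness 0. All four metrics are
verified to 1e-9 against an exhaustive Floyd–Warshall /
path-enumeration oracle on random graphs of up to 8 nodes.

A calibration caveat established by simulation: node-level metrics
within one shared graph are not independent observations. With
homophilous mixing, group labels cluster along recruitment chains and
the ego-level t-test on centralities becomes anti-conservative (null
rejection rates up to ~0.3 in our replicates). The type-I calibration
experiment therefore uses flat mixing, under which labels are
independent of topology and the test is exact in the permutation
sense; the caveat applies equally to observed RDS data and should
temper interpretation of "no significant structural differences"
findings in this design.

## 5. Comparative statistics

Ego-level composition covariates are computed per wave from the
resolved roster sets, proportions over non-missing alter attributes
with the effective denominator recorded. Every statistic uses
pairwise-complete records — denominators vary by variable, as they
visibly do in real baseline tables — and nothing is imputed.

Income is dichotomized at $20,000 with exactly $20,000 mapped to
not-below: the survey wording ("<$20,000 or >$20,000") leaves the
boundary unassigned and a deterministic rule is required.

Unadjusted odds ratios compare TGW with MSM (reference) by
maximum-likelihood logistic regression (Newton, statsmodels defaults,
convergence checked), Wald 95% CIs and two-sided p. Two framings
exist and the choice is recorded in every output row: binary ego-level
outcomes regress outcome on the group indicator; counts and
proportions regress the group indicator on the covariate (OR per
unit). For binary-binary tables with a zero cell, the cross-product OR
with the Haldane–Anscombe 0.5 correction engages and is flagged; on
non-degenerate 2×2 tables the logistic OR equals the cross-product OR
(saturated-model identity, verified to 1e-6). No multiple-testing
correction is applied by default, matching the plain p ≤ 0.05
convention of the study design this mirrors; Benjamini–Hochberg is
available but off.

Baseline summaries use Welch t-tests for continuous variables and
chi-square (no continuity correction) for categoricals, with Fisher's
exact test on sparse 2×2 tables (any expected cell < 5).

## 6. Problem sizes and reproducibility choices

The packaged experiments use: a 618-ego, 3-wave default cohort
(population 3000); parameter recovery on a two-wave, two-block cohort
recruited to exhaustion (~550 egos per group — partial-sample stops
are arbitrarily unbalanced between disconnected blocks because chain
growth is supercritical, so exhaustion is the balanced design); and
200 replicate null cohorts of ~110 egos with wave-1 composite graphs
for the calibration study. These sizes give Monte-Carlo standard
errors small enough for 3-SE parameter checks while keeping the full
suite fast on a single CPU.

Determinism is a contract: no stage reads the clock or locale, floats
are written with 6 significant digits, JSON keys are sorted, and
GraphML/edge-list exports are emitted in canonical orders, so re-runs
with equal seeds are byte-identical.

## 7. Known limitations

* RDS inference weights are deliberately out of scope; all statistics
  are unweighted sample quantities, as in the design this mirrors.
* The per-ego alter-node representation makes cross-ego structural
  quantities (path lengths, betweenness) instrument-relative rather
  than sociometrically true.
* The turnover/stability ratios are roster-window statistics: caps
  truncate large networks (the bias is negligible at the default mean
  degrees but grows if mean degree greatly exceeds the cap).
* Ego-level tests on shared-graph metrics are anti-conservative under
  homophily (see §4).
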