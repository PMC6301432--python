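"""Simulation experiments validating the estimators against ground truth.

Two study designs are packaged here because both the test suite and the
reproduction script run them:

* parameter recovery — a two-wave cohort with no new-tie arrivals and
  group-specific tie retention (0.3 for TGW vs 0.6 for MSM, both roster
  kinds, no between-group mixing so every tie's retention probability
  is its ego's own). With two visits and no arrivals the expected
  per-ego stability ratio equals the retention probability, so the
  group mean stabilities estimate the simulation parameters directly.

* type-I error calibration — repeated small cohorts in which the two
  groups have identical network and dynamics parameters, so every
  group comparison (four structural metrics, stability and turnover in
  both roster kinds) tests a true null; the pooled rejection fraction
  at p <= 0.05 should sit near 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np

from netpanel.dynamics import cohort_dynamics
from netpanel.roster import from_simulation
from netpanel.simulate import KINDS, RecruitmentWarning, SimulationConfig, simulate_cohort
from netpanel.structure import assemble_graph, group_structure_comparison, node_metrics


def recovery_config(seed: int, retain_tgw: float = 0.3, retain_msm: float = 0.6,
                    n_per_group: int = 550) -> SimulationConfig:
    """Two-wave, two-block recovery design (~n_per_group egos per group).

    Recruitment runs to exhaustion of the coupon queue (the target is
    the whole population), enrolling essentially the giant component of
    each block: supercritical chain growth makes a partial-sample stop
    arbitrarily unbalanced between blocks, whereas exhaustion yields
    groups balanced at the block-size level.
    """
    population = int(2 * n_per_group * 1.12)
    return SimulationConfig(
        population_size=population,
        prop_tgw=0.5,
        n_seeds=40,
        coupons_per_recruit=3,
        target_sample=population,
        n_waves=2,
        mixing=((1.0, 0.0), (0.0, 1.0)),  # no cross-group ties: owner == ego group
        mean_confidant_degree=3.0,
        mean_sexual_degree=3.0,
        retain_prob={(k, "TGW"): retain_tgw for k in KINDS}
        | {(k, "MSM"): retain_msm for k in KINDS},
        new_tie_rate={(k, g): 0.0 for k in KINDS for g in ("TGW", "MSM")},
        attrition_retention={"MSM": 1.0, "TGW": 1.0},
        rng_seed=int(seed),
    )


def parameter_recovery(seed: int, retain_tgw: float = 0.3, retain_msm: float = 0.6,
                       n_per_group: int = 550, kind: str = "confidant") -> dict:
    """Recover group retention probabilities from emitted rosters.

    Returns group mean stabilities with their Monte-Carlo standard
    errors, z-scores against the true parameters, and the Welch p-value
    of the group comparison.
    """
    cfg = recovery_config(seed, retain_tgw, retain_msm, n_per_group)
    with warnings.catch_warnings():
        # recruiting to exhaustion leaves isolates unenrolled by design
        warnings.simplefilter("ignore", RecruitmentWarning)
        dataset = from_simulation(simulate_cohort(cfg))
    summaries, comparisons, _ = cohort_dynamics(dataset)
    sub = summaries[(summaries["kind"] == kind) & summaries["stability"].notna()]
    out = {"kind": kind, "true": {"TGW": retain_tgw, "MSM": retain_msm}}
    for group, true in (("TGW", retain_tgw), ("MSM", retain_msm)):
        vals = sub.loc[sub["group"] == group, "stability"].to_numpy()
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        out[group] = {"n": int(len(vals)), "mean_stability": mean, "se": se,
                      "z": (mean - true) / se if se > 0 else np.nan}
    row = comparisons[(comparisons["kind"] == kind)
                      & (comparisons["ratio"] == "stability")].iloc[0]
    out["welch_p"] = float(row["p_value"])
    return out


def null_config(seed: int) -> SimulationConfig:
    """Small cohort in which TGW and MSM share every parameter.

    Mixing is flat (between-group weight equal to within-group), so the
    group label is independent of every node's network position and the
    two-sample null holds exactly. With homophilous mixing the label
    would still have identical marginal parameters, but labels cluster
    along recruitment chains and node-level metrics become
    label-correlated, which the ego-level t-test does not model — a
    caveat that applies equally to observed RDS data.
    """
    return SimulationConfig(
        population_size=320,
        prop_tgw=0.5,
        n_seeds=10,
        coupons_per_recruit=3,
        target_sample=110,
        n_waves=2,
        mixing=((1.0, 1.0), (1.0, 1.0)),
        mean_confidant_degree=3.0,
        mean_sexual_degree=2.5,
        retain_prob={(k, g): 0.5 for k in KINDS for g in ("TGW", "MSM")},
        new_tie_rate={(k, g): 0.5 for k in KINDS for g in ("TGW", "MSM")},
        attrition_retention={"MSM": 1.0, "TGW": 1.0},
        rng_seed=int(seed),
    )


def null_replicate_pvalues(seed: int) -> list:
    """All group-comparison p-values from one null cohort (NaNs dropped)."""
    dataset = from_simulation(simulate_cohort(null_config(seed)))
    _, ratio_comparisons, _ = cohort_dynamics(dataset)
    # wave-1 composite graph: keeps each replicate's metric pass cheap
    graph = assemble_graph(dataset, waves=(1,))
    metrics = node_metrics(graph)
    structure_comparison = group_structure_comparison(metrics, dataset.respondents)
    ps = list(ratio_comparisons["p_value"].dropna()) + list(
        structure_comparison["p_value"].dropna()
    )
    return [float(p) for p in ps]


def child_seeds(seed: int, n: int) -> list:
    """n reproducible sub-seeds (< 2^31) derived from a master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def type_one_error(seed: int, n_reps: int = 200, alpha: float = 0.05) -> dict:
    """Pooled null rejection fraction over n_reps replicate cohorts."""
    rejected = 0
    total = 0
    per_rep = []
    for s in child_seeds(seed, n_reps):
        ps = null_replicate_pvalues(s)
        k = sum(1 for p in ps if p <= alpha)
        rejected += k
        total += len(ps)
        per_rep.append(k / len(ps) if ps else np.nan)
    rate = rejected / total if total else float("nan")
    se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {"n_reps": n_reps, "n_tests": total, "rejection_rate": rate,
            "alpha": alpha, "binomial_se_per_rep": se,
            "mean_per_replicate_rate": float(np.nanmean(per_rep))}
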