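import numpy as np
import pandas as pd
import pytest

from netpanel.simulate import (
    ConfigError,
    Population,
    RecruitmentWarning,
    SimulationConfig,
    evolve_ties,
    generate_population,
    run_rds_recruitment,
    simulate_cohort,
)

from conftest import SMALL_CONFIG


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"prop_tgw": 1.5}, "prop_tgw"),
        ({"population_size": 0}, "population_size"),
        ({"n_seeds": 700}, "n_seeds"),  # exceeds target_sample
        ({"coupons_per_recruit": -1}, "coupons_per_recruit"),
        ({"retain_prob": {("confidant", "MSM"): 1.2}}, "retain_prob"),
        ({"new_tie_rate": {("sexual", "TGW"): -0.1}}, "new_tie_rate"),
        ({"attrition_retention": {"MSM": 2.0}}, "attrition_retention"),
        ({"mixing": ((1.0, 0.5), (0.3, 1.0))}, "mixing"),
        ({"seed_selection": "alphabetical"}, "seed_selection"),
    ],
)
def test_invalid_config_rejected_with_named_field(overrides, field):
    with pytest.raises(ConfigError, match=field):
        SimulationConfig(**overrides)


def test_degenerate_mixture_yields_single_group():
    pop = generate_population(SimulationConfig(
        population_size=200, prop_tgw=0.0, n_seeds=5, target_sample=50, rng_seed=0))
    assert set(pop.attrs["group"]) == {"MSM"}


def test_zero_mean_degree_yields_no_ties():
    pop = generate_population(SimulationConfig(
        population_size=200, mean_confidant_degree=0.0, n_seeds=5,
        target_sample=50, rng_seed=0))
    assert pop.ties_by_wave[(1, "confidant")] == set()


def test_mean_degree_recovered_by_edge_count():
    """Empirical mean degree matches the configured rate within 3 SE."""
    n, target = 2000, 4.0
    pop = generate_population(SimulationConfig(
        population_size=n, mean_sexual_degree=target, n_seeds=10,
        target_sample=100, rng_seed=7))
    edges = pop.ties_by_wave[(1, "sexual")]
    mean_degree = 2 * len(edges) / n
    # edge count is a sum of independent Bernoullis with mean n*target/2
    se = 2 * np.sqrt(n * target / 2) / n
    assert abs(mean_degree - target) < 3 * se
    assert all(u < v and u != v for u, v in edges)


def _path_population(n=5):
    cfg = SimulationConfig(population_size=n, n_seeds=1, target_sample=n,
                           coupons_per_recruit=1, rng_seed=0)
    attrs = pd.DataFrame({"group": ["MSM"] * n})
    ties = {(1, "confidant"): {(i, i + 1) for i in range(n - 1)},
            (1, "sexual"): set()}
    return Population(config=cfg, attrs=attrs, ties_by_wave=ties), cfg


def test_path_recruitment_is_a_chain():
    """1 seed at the end of a 5-path with 1 coupon recruits all 5 in order."""
    pop, cfg = _path_population(5)
    forest, sample = run_rds_recruitment(pop, cfg, seeds=[0])
    assert sample == [0, 1, 2, 3, 4]
    assert forest.recruiter_of == {1: 0, 2: 1, 3: 2, 4: 3}
    assert forest.depth_of == {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}


def test_zero_coupons_enrolls_seeds_only():
    pop, cfg = _path_population(5)
    cfg2 = SimulationConfig(population_size=5, n_seeds=2, target_sample=5,
                            coupons_per_recruit=0, rng_seed=0)
    with pytest.warns(RecruitmentWarning):
        forest, sample = run_rds_recruitment(pop, cfg2, seeds=[0, 3])
    assert sample == [0, 3]
    assert forest.recruiter_of == {}


def test_recruitment_forest_invariants(sim_small):
    truth = sim_small.ground_truth
    resp = sim_small.respondents
    recruiters = resp.set_index("ego_id")["recruiter_id"]
    depths = resp.set_index("ego_id")["rds_depth"]
    out_degree = recruiters.dropna().value_counts()
    assert (out_degree <= SMALL_CONFIG["coupons_per_recruit"]).all()
    assert not resp["ego_id"].duplicated().any()
    for ego, recruiter in recruiters.dropna().items():
        assert depths[ego] == depths[recruiter] + 1  # acyclic by construction
    assert (depths[recruiters.isna()] == 0).all()
    assert truth.config.n_seeds == int(recruiters.isna().sum())


def _frozen_config(retain, rate, **kw):
    kinds = ("confidant", "sexual")
    groups = ("MSM", "TGW")
    base = dict(population_size=300, n_seeds=5, target_sample=100, n_waves=2,
                mean_confidant_degree=3.0, mean_sexual_degree=2.0, rng_seed=3)
    base.update(kw)
    return SimulationConfig(
        retain_prob={(k, g): retain for k in kinds for g in groups},
        new_tie_rate={(k, g): rate for k in kinds for g in groups},
        **base)


def test_frozen_network_is_unchanged():
    cfg = _frozen_config(retain=1.0, rate=0.0)
    pop = generate_population(cfg)
    before = {k: set(pop.ties_by_wave[(1, k)]) for k in ("confidant", "sexual")}
    nxt, _ = evolve_ties(pop, 1, cfg)
    assert nxt == before


def test_total_loss_empties_network():
    cfg = _frozen_config(retain=0.0, rate=0.0)
    pop = generate_population(cfg)
    nxt, records = evolve_ties(pop, 1, cfg)
    assert nxt == {"confidant": set(), "sexual": set()}
    assert all(not r["persisted"] for r in records)


def test_persistence_fraction_matches_retention_probability():
    """Pooled ground-truth persistence is within 3 binomial SE of 0.4."""
    cfg = _frozen_config(retain=0.4, rate=0.0, population_size=1500,
                         target_sample=500, mean_confidant_degree=5.0)
    pop = generate_population(cfg)
    _, records = evolve_ties(pop, 1, cfg)
    kept = np.array([r["persisted"] for r in records])
    assert len(kept) > 2500
    se = np.sqrt(0.4 * 0.6 / len(kept))
    assert abs(kept.mean() - 0.4) < 3 * se


def test_roster_caps_and_no_padding(sim_small):
    rosters = sim_small.rosters
    conf = rosters[rosters["kind"] == "confidant"]
    sex = rosters[rosters["kind"] == "sexual"]
    conf_sizes = conf.groupby(["ego_id", "wave"]).size()
    sex_sizes = sex.groupby(["ego_id", "wave"]).size()
    assert (conf_sizes <= 5).all()
    assert (sex_sizes <= 6).all()
    # under the cap the roster equals the true current tie count (no padding)
    truth = sim_small.ground_truth
    em = dict(zip(truth.ego_members["ego_id"], truth.ego_members["member"]))
    degree = {}
    for (wave, kind), ties in truth.ties_by_wave.items():
        for u, v in ties:
            degree[(f"P{u:05d}", wave, kind)] = degree.get((f"P{u:05d}", wave, kind), 0) + 1
            degree[(f"P{v:05d}", wave, kind)] = degree.get((f"P{v:05d}", wave, kind), 0) + 1
    checked = 0
    for (ego, wave), size in conf_sizes.items():
        true_deg = degree.get((em[ego], wave, "confidant"), 0)
        if true_deg < 5:
            assert size == true_deg
            checked += 1
    assert checked > 20


def test_at_most_one_primary_partner_and_deduplication(sim_small):
    sex = sim_small.rosters[sim_small.rosters["kind"] == "sexual"]
    primaries = sex[sex["is_primary_partner"] == True]  # noqa: E712
    assert primaries.groupby(["ego_id", "wave"]).size().max() <= 1
    # the primary is never a duplicate nomination of a listed partner
    truth = sim_small.ground_truth.nomination_members
    merged = sex.merge(truth[["nomination_id", "member"]], on="nomination_id")
    dup = merged.groupby(["ego_id", "wave", "member"]).size()
    assert dup.max() == 1


def test_match_records_link_every_renomination_once(sim_small):
    """One match per (ego, kind, alter) re-nomination at a later wave."""
    truth = sim_small.ground_truth.nomination_members
    expected = 0
    for _, grp in truth.groupby(["ego_id", "kind", "member"]):
        expected += len(grp) - 1
    assert len(sim_small.matches) == expected
    m = sim_small.matches
    assert (m["wave_earlier"] < m["wave_later"]).all()


def test_full_attendance_without_attrition():
    cfg = SimulationConfig(population_size=300, n_seeds=5, target_sample=80,
                           n_waves=3, mean_confidant_degree=3.0,
                           attrition_retention={"MSM": 1.0, "TGW": 1.0},
                           rng_seed=5)
    sim = simulate_cohort(cfg)
    per_ego = sim.attendance.groupby("ego_id")["attended"].agg(["size", "sum"])
    assert (per_ego["size"] == 3).all()
    assert (per_ego["sum"] == 3).all()


def test_same_seed_reproduces_tables_exactly(sim_small):
    again = simulate_cohort(SimulationConfig(**SMALL_CONFIG))
    for name, df in sim_small.tables().items():
        pd.testing.assert_frame_equal(df, again.tables()[name])


def test_group_attrition_rates_recovered():
    cfg = SimulationConfig(population_size=2500, n_seeds=20, target_sample=800,
                           prop_tgw=0.4, n_waves=2, mean_confidant_degree=4.0,
                           rng_seed=9)
    sim = simulate_cohort(cfg)
    att = sim.attendance.merge(sim.respondents[["ego_id", "group"]], on="ego_id")
    w2 = att[att["wave"] == 2]
    for group, p in (("MSM", 0.864), ("TGW", 0.667)):
        sub = w2[w2["group"] == group]["attended"]
        se = np.sqrt(p * (1 - p) / len(sub))
        assert abs(sub.mean() - p) < 3 * se
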