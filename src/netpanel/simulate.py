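"""Synthetic RDS cohort simulator.

Generates a two-group hidden population (transgender women, TGW, and men
who have sex with men, MSM — both assigned male at birth), recruits a
study sample through seeded coupon-based respondent-driven sampling over
confidant ties, evolves confidant and sexual-partner ties between survey
waves with known retention and arrival parameters, and emits the tabular
files a field study's name-generator instrument would produce:
respondents, per-wave rosters (capped at 5 confidants and 5 recent + 1
primary sexual partner), respondent-confirmed cross-wave match records,
and attendance. Ground truth (true alter identities, per-tie persistence
outcomes) is attached so downstream estimators can be validated against
known parameters.

All randomness flows from one master seed through named sub-streams
(population, recruitment, dynamics, attrition, rosters, covariates), so
each stage is independently reproducible and two runs with the same seed
produce byte-identical tables.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

GROUPS = ("MSM", "TGW")
KINDS = ("confidant", "sexual")
CONFIDANT_CAP = 5
SEXUAL_RECENT_CAP = 5
SEXUAL_TOTAL_CAP = 6  # 5 recent + 1 primary (deduplicated if already listed)

ORIENTATIONS = ("gay", "straight", "bisexual", "other")
PARTNER_PREFS = ("men", "tgw", "cis_women", "other_unknown")

_STREAMS = {
    "population": 0,
    "recruitment": 1,
    "dynamics": 2,
    "attrition": 3,
    "rosters": 4,
    "covariates": 5,
}


class ConfigError(ValueError):
    """A SimulationConfig field failed validation (message names the field)."""


class RecruitmentWarning(UserWarning):
    """Recruitment exhausted before reaching the target sample size."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child generator of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


# Group-level covariate prevalences used for respondent and alter
# attribute draws. Values emulate a young, urban, majority-unemployed
# cohort of individuals assigned male at birth who have sex with men:
# HIV prevalence near 30-40%, >80% with income under $20k, and markedly
# different employment between groups. Alter attributes (exchange sex,
# payment, partner preference) are drawn per population member from that
# member's own group's distribution.
DEFAULT_COVARIATES = {
    "MSM": {
        "age_mean": 22.8,
        "age_sd": 3.2,
        "hiv_positive": 0.423,
        "hiv_known": 0.82,
        "employed": 0.711,
        "income_lt_20k": 0.808,
        "stably_housed": 0.754,
        "ever_jail": 0.455,
        "insured": 0.548,
        "in_relationship": 0.399,
        "orientation": {"gay": 0.684, "straight": 0.011, "bisexual": 0.279, "other": 0.026},
        "orientation_stable": 0.836,
        "partners_mean": 4.0,
        "partners_sd": 4.9,
        "alter_exchange_sex": 0.10,
        "alter_received_payment": 0.05,
        "alter_partner_pref": {"men": 0.60, "tgw": 0.05, "cis_women": 0.20, "other_unknown": 0.15},
    },
    "TGW": {
        "age_mean": 22.1,
        "age_sd": 2.6,
        "hiv_positive": 0.306,
        "hiv_known": 0.77,
        "employed": 0.396,
        "income_lt_20k": 0.935,
        "stably_housed": 0.688,
        "ever_jail": 0.521,
        "insured": 0.587,
        "in_relationship": 0.333,
        "orientation": {"gay": 0.438, "straight": 0.333, "bisexual": 0.167, "other": 0.062},
        "orientation_stable": 0.688,
        "partners_mean": 7.6,
        "partners_sd": 15.2,
        "alter_exchange_sex": 0.30,
        "alter_received_payment": 0.18,
        "alter_partner_pref": {"men": 0.45, "tgw": 0.20, "cis_women": 0.15, "other_unknown": 0.20},
    },
}


def _default_retain() -> dict:
    # Wave-to-wave tie retention probability by (roster kind, group).
    # With two visits and no new-tie arrivals these equal the expected
    # per-ego stability ratio, so the defaults encode a cohort whose
    # sexual networks are much less stable than its confidant networks
    # and less stable for TGW than for MSM.
    return {
        ("confidant", "MSM"): 0.408,
        ("confidant", "TGW"): 0.334,
        ("sexual", "MSM"): 0.278,
        ("sexual", "TGW"): 0.175,
    }


def _default_new_rate() -> dict:
    # Expected new ties per ego per inter-wave interval; chosen so the
    # turnover ratios land in the 0.6-0.85 range typical of this kind of
    # cohort, higher for TGW and for sexual ties.
    return {
        ("confidant", "MSM"): 0.5,
        ("confidant", "TGW"): 0.7,
        ("sexual", "MSM"): 0.4,
        ("sexual", "TGW"): 0.8,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the reference study conditions: a sample of 618
    drawn from a larger hidden population via 62 seeds, three waves,
    wave-to-wave study retention of 86.4% (MSM) and 66.7% (TGW), 7.6%
    TGW share, roster caps of 5 confidants and 5 recent + 1 primary
    sexual partner.
    """

    population_size: int = 3000
    #: population share of TGW. Degree-weighted RDS over a homophilous
    #: graph under-recruits the smaller, less-connected group, so a 0.16
    #: population share yields roughly the reference 7.6% TGW sample share.
    prop_tgw: float = 0.16
    n_seeds: int = 62
    coupons_per_recruit: int = 3
    target_sample: int = 618
    n_waves: int = 3
    #: 2x2 within/between tie-probability weights, group order (MSM, TGW)
    mixing: tuple = ((1.0, 0.3), (0.3, 1.0))
    mean_confidant_degree: float = 5.0
    mean_sexual_degree: float = 4.0
    retain_prob: dict = field(default_factory=_default_retain)
    new_tie_rate: dict = field(default_factory=_default_new_rate)
    attrition_retention: dict = field(
        default_factory=lambda: {"MSM": 0.864, "TGW": 0.667}
    )
    covariate_prevalences: dict = field(
        default_factory=lambda: {g: dict(DEFAULT_COVARIATES[g]) for g in GROUPS}
    )
    seed_selection: str = "degree"  # "degree" (weighted) or "uniform"
    recruit_over: str = "confidant"  # "confidant" or "union"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _positive_int(name):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")

        for name in ("population_size", "n_seeds", "target_sample", "n_waves"):
            _positive_int(name)
        if not isinstance(self.coupons_per_recruit, (int, np.integer)) or self.coupons_per_recruit < 0:
            raise ConfigError(
                f"coupons_per_recruit must be a nonnegative integer, got {self.coupons_per_recruit!r}"
            )
        if not 0.0 <= self.prop_tgw <= 1.0:
            raise ConfigError(f"prop_tgw must be in [0, 1], got {self.prop_tgw!r}")
        if not (self.n_seeds <= self.target_sample <= self.population_size):
            raise ConfigError(
                "require n_seeds <= target_sample <= population_size, got "
                f"n_seeds={self.n_seeds}, target_sample={self.target_sample}, "
                f"population_size={self.population_size}"
            )
        mix = np.asarray(self.mixing, dtype=float)
        if mix.shape != (2, 2) or (mix < 0).any():
            raise ConfigError("mixing must be a nonnegative 2x2 weight matrix")
        if not np.allclose(mix, mix.T):
            raise ConfigError("mixing must be symmetric (undirected ties)")
        for name in ("mean_confidant_degree", "mean_sexual_degree"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for (kind, group), p in self.retain_prob.items():
            if kind not in KINDS or group not in GROUPS or not 0.0 <= p <= 1.0:
                raise ConfigError(f"retain_prob[{kind!r}, {group!r}]={p!r} invalid")
        for (kind, group), r in self.new_tie_rate.items():
            if kind not in KINDS or group not in GROUPS or r < 0:
                raise ConfigError(f"new_tie_rate[{kind!r}, {group!r}]={r!r} invalid")
        for group, p in self.attrition_retention.items():
            if group not in GROUPS or not 0.0 <= p <= 1.0:
                raise ConfigError(f"attrition_retention[{group!r}]={p!r} invalid")
        if self.seed_selection not in ("degree", "uniform"):
            raise ConfigError(f"seed_selection must be 'degree' or 'uniform', got {self.seed_selection!r}")
        if self.recruit_over not in ("confidant", "union"):
            raise ConfigError(f"recruit_over must be 'confidant' or 'union', got {self.recruit_over!r}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Population:
    """Hidden population: per-member attributes plus per-wave tie sets."""

    config: SimulationConfig
    attrs: pd.DataFrame  # indexed by member id (0..n-1)
    ties_by_wave: dict  # (wave, kind) -> set of (u, v) with u < v

    @property
    def n(self) -> int:
        return len(self.attrs)

    def neighbors(self, wave: int, kind: str) -> dict:
        adj: dict = {m: set() for m in range(self.n)}
        for u, v in self.ties_by_wave[(wave, kind)]:
            adj[u].add(v)
            adj[v].add(u)
        return adj


@dataclass
class RecruitmentForest:
    """RDS recruitment chains: a forest rooted at the seeds."""

    recruiter_of: dict  # member -> recruiter member (seeds absent)
    depth_of: dict  # member -> recruitment chain depth (seeds: 0)
    order: list  # members in enrollment order

    def seeds(self) -> list:
        return [m for m in self.order if m not in self.recruiter_of]

    def out_degrees(self) -> dict:
        out: dict = {m: 0 for m in self.order}
        for recruiter in self.recruiter_of.values():
            out[recruiter] += 1
        return out


@dataclass
class GroundTruth:
    """Simulator-side truth for validating downstream estimators."""

    config: SimulationConfig
    nomination_members: pd.DataFrame  # nomination_id -> true member id
    persistence: pd.DataFrame  # one row per existing tie per transition
    ties_by_wave: dict
    ego_members: pd.DataFrame = None  # ego_id -> true member id

    def realized_retention(self) -> pd.DataFrame:
        """Observed per-(kind, group) tie persistence fractions."""
        if self.persistence.empty:
            return pd.DataFrame(columns=["kind", "group", "n_ties", "retention"])
        g = (
            self.persistence.groupby(["kind", "owner_group"])["persisted"]
            .agg(["size", "mean"])
            .reset_index()
        )
        g.columns = ["kind", "group", "n_ties", "retention"]
        return g


@dataclass
class SimulatedDataset:
    """The emitted study tables plus attached ground truth."""

    respondents: pd.DataFrame
    rosters: pd.DataFrame
    matches: pd.DataFrame
    attendance: pd.DataFrame
    ground_truth: GroundTruth

    def tables(self) -> dict:
        return {
            "respondents": self.respondents,
            "rosters": self.rosters,
            "matches": self.matches,
            "attendance": self.attendance,
        }


# ---------------------------------------------------------------------------
# population generation


def _sample_distinct_pairs(rng, left, right, m, same_block):
    """m distinct unordered pairs with one endpoint from each index array."""
    chosen: set = set()
    if m <= 0:
        return chosen
    while len(chosen) < m:
        k = m - len(chosen)
        us = left[rng.integers(0, len(left), size=2 * k + 8)]
        vs = right[rng.integers(0, len(right), size=2 * k + 8)]
        for u, v in zip(us, vs):
            if u == v:
                continue
            e = (int(u), int(v)) if u < v else (int(v), int(u))
            chosen.add(e)
            if len(chosen) == m:
                break
    return chosen


def _two_block_edges(rng, group_idx, mean_degree, mixing) -> set:
    """Two-block degree-homogeneous random graph with block weights.

    Per-pair Bernoulli probabilities are proportional to the mixing
    weight of the pair's block combination, scaled so the expected mean
    degree over the whole population equals ``mean_degree``.
    """
    n = len(group_idx)
    if n < 2 or mean_degree == 0:
        return set()
    blocks = [np.flatnonzero(group_idx == 0), np.flatnonzero(group_idx == 1)]
    mix = np.asarray(mixing, dtype=float)
    pairs = {}
    for a in range(2):
        for b in range(a, 2):
            na, nb = len(blocks[a]), len(blocks[b])
            pairs[(a, b)] = na * (na - 1) / 2 if a == b else na * nb
    denom = sum(mix[a, b] * pairs[(a, b)] for (a, b) in pairs)
    if denom == 0:
        return set()
    c = mean_degree * n / (2.0 * denom)
    edges: set = set()
    for (a, b), npairs in pairs.items():
        if npairs == 0:
            continue
        p = min(1.0, c * mix[a, b])
        m = int(rng.binomial(int(npairs), p))
        edges |= _sample_distinct_pairs(rng, blocks[a], blocks[b], m, a == b)
    return edges


def _draw_covariates(rng, groups: np.ndarray, prev: dict) -> pd.DataFrame:
    n = len(groups)
    cols: dict = {"group": groups}

    def per_group(fn):
        out = np.empty(n, dtype=object)
        for g in GROUPS:
            mask = groups == g
            if mask.any():
                out[mask] = fn(g, int(mask.sum()))
        return out

    cols["age_years"] = per_group(
        lambda g, k: np.clip(
            rng.normal(prev[g]["age_mean"], prev[g]["age_sd"], size=k), 16.0, 29.0
        ).round(1)
    )
    for name in ("hiv_positive", "employed", "income_lt_20k", "stably_housed",
                 "ever_jail", "insured", "in_relationship", "hiv_known",
                 "alter_exchange_sex", "alter_received_payment"):
        cols[name] = per_group(lambda g, k, nm=name: rng.random(k) < prev[g][nm])
    cols["alter_partner_pref"] = per_group(
        lambda g, k: rng.choice(
            PARTNER_PREFS, size=k, p=[prev[g]["alter_partner_pref"][o] /
                                      sum(prev[g]["alter_partner_pref"].values())
                                      for o in PARTNER_PREFS]
        )
    )

    def _negbin(g, k):
        m, s = prev[g]["partners_mean"], prev[g]["partners_sd"]
        var = s * s
        if var <= m:
            return rng.poisson(m, size=k)
        r = m * m / (var - m)
        return rng.negative_binomial(r, r / (r + m), size=k)

    cols["n_sex_partners_6mo"] = per_group(_negbin)
    df = pd.DataFrame(cols)
    return df


def _draw_orientations(rng, attrs: pd.DataFrame, prev: dict, n_waves: int) -> None:
    groups = attrs["group"].to_numpy()
    n = len(attrs)
    current = np.empty(n, dtype=object)
    for g in GROUPS:
        mask = groups == g
        if not mask.any():
            continue
        dist = prev[g]["orientation"]
        p = np.array([dist[o] for o in ORIENTATIONS], dtype=float)
        current[mask] = rng.choice(ORIENTATIONS, size=int(mask.sum()), p=p / p.sum())
    attrs["orientation_w1"] = current.copy()
    for w in range(2, n_waves + 1):
        nxt = current.copy()
        for g in GROUPS:
            mask = groups == g
            if not mask.any():
                continue
            stay = rng.random(int(mask.sum())) < prev[g]["orientation_stable"]
            dist = prev[g]["orientation"]
            p = np.array([dist[o] for o in ORIENTATIONS], dtype=float)
            redrawn = rng.choice(ORIENTATIONS, size=int(mask.sum()), p=p / p.sum())
            sub = nxt[mask]
            sub[~stay] = redrawn[~stay]
            nxt[mask] = sub
        attrs[f"orientation_w{w}"] = nxt
        current = nxt


def generate_population(config: SimulationConfig) -> Population:
    """Hidden population with attributes and Wave-1 confidant/sexual ties."""
    config.validate()
    rng_pop = _stream(config.rng_seed, "population")
    rng_cov = _stream(config.rng_seed, "covariates")
    n = config.population_size
    groups = np.where(rng_pop.random(n) < config.prop_tgw, "TGW", "MSM").astype(object)
    group_idx = (groups == "TGW").astype(int)

    ties_by_wave = {
        (1, "confidant"): _two_block_edges(rng_pop, group_idx, config.mean_confidant_degree, config.mixing),
        (1, "sexual"): _two_block_edges(rng_pop, group_idx, config.mean_sexual_degree, config.mixing),
    }
    attrs = _draw_covariates(rng_cov, groups, config.covariate_prevalences)
    _draw_orientations(rng_cov, attrs, config.covariate_prevalences, config.n_waves)
    return Population(config=config, attrs=attrs, ties_by_wave=ties_by_wave)


# ---------------------------------------------------------------------------
# RDS recruitment


def run_rds_recruitment(population: Population, config: SimulationConfig,
                        seeds: Optional[list] = None):
    """Coupon-based chain recruitment over confidant ties.

    Seeds are drawn without replacement (degree-weighted by default,
    uniform by config; an explicit ``seeds`` list overrides the draw);
    every enrollee hands at most ``coupons_per_recruit`` coupons to
    currently unenrolled neighbors, coupons are redeemed breadth-wise in
    issue order, and recruitment halts at ``target_sample`` or when the
    coupon queue is exhausted (a warning reports the achieved size).

    Returns ``(forest, sample)`` with ``sample`` in enrollment order.
    """
    cfg = config
    adj = population.neighbors(1, "confidant")
    if cfg.recruit_over == "union":
        for u, v in population.ties_by_wave[(1, "sexual")]:
            adj[u].add(v)
            adj[v].add(u)
    rng = _stream(cfg.rng_seed, "recruitment")
    n = population.n

    if seeds is None:
        degrees = np.array([len(adj[m]) for m in range(n)], dtype=float)
        if cfg.seed_selection == "degree" and degrees.sum() > 0:
            weights = degrees / degrees.sum()
            seeds = rng.choice(n, size=cfg.n_seeds, replace=False, p=weights)
        else:
            seeds = rng.choice(n, size=cfg.n_seeds, replace=False)
    seeds = [int(s) for s in seeds]

    recruiter_of: dict = {}
    depth_of: dict = {}
    order: list = []
    enrolled: set = set()
    queue: deque = deque()

    def enroll(member: int, recruiter: Optional[int]) -> None:
        enrolled.add(member)
        order.append(member)
        if recruiter is None:
            depth_of[member] = 0
        else:
            recruiter_of[member] = recruiter
            depth_of[member] = depth_of[recruiter] + 1
        candidates = sorted(m for m in adj[member] if m not in enrolled)
        if candidates and cfg.coupons_per_recruit > 0:
            picks = rng.permutation(len(candidates))[: cfg.coupons_per_recruit]
            for i in sorted(picks):
                queue.append((member, candidates[i]))

    for s in seeds:
        if len(enrolled) >= cfg.target_sample:
            break
        enroll(s, None)
    while queue and len(enrolled) < cfg.target_sample:
        recruiter, target = queue.popleft()
        if target in enrolled:
            continue
        enroll(target, recruiter)

    if len(enrolled) < cfg.target_sample:
        warnings.warn(
            f"recruitment exhausted at {len(enrolled)} enrollees "
            f"(target {cfg.target_sample})",
            RecruitmentWarning,
            stacklevel=2,
        )
    return RecruitmentForest(recruiter_of=recruiter_of, depth_of=depth_of, order=order), list(order)


# ---------------------------------------------------------------------------
# tie dynamics


def evolve_ties(population: Population, from_wave: int, config: SimulationConfig,
                rng: Optional[np.random.Generator] = None):
    """Evolve both kinds of ties one inter-wave interval forward.

    Each existing tie persists independently with the retention
    probability of a uniformly chosen "owner" endpoint's group; each
    member initiates Poisson-many new ties to uniformly chosen eligible
    partners. The next wave's tie sets are stored on the population and
    per-tie persistence outcomes are returned for ground truth.
    """
    if rng is None:
        rng = _stream(config.rng_seed, "dynamics")
    groups = population.attrs["group"].to_numpy()
    n = population.n
    records: list = []
    for kind in KINDS:
        current = sorted(population.ties_by_wave[(from_wave, kind)])
        nxt: set = set()
        for (u, v) in current:
            owner = u if rng.random() < 0.5 else v
            p = config.retain_prob.get((kind, groups[owner]), 1.0)
            kept = bool(rng.random() < p)
            if kept:
                nxt.add((u, v))
            records.append(
                {"kind": kind, "wave_from": from_wave, "u": u, "v": v,
                 "owner_group": groups[owner], "persisted": kept}
            )
        if n > 1:
            for m in range(n):
                rate = config.new_tie_rate.get((kind, groups[m]), 0.0)
                if rate <= 0:
                    continue
                k = int(rng.poisson(rate))
                for _ in range(k):
                    for _attempt in range(20):
                        other = int(rng.integers(0, n))
                        if other == m:
                            continue
                        e = (m, other) if m < other else (other, m)
                        if e not in nxt:
                            nxt.add(e)
                            break
        population.ties_by_wave[(from_wave + 1, kind)] = nxt
    return (
        {kind: population.ties_by_wave[(from_wave + 1, kind)] for kind in KINDS},
        records,
    )


# ---------------------------------------------------------------------------
# wave table emission


@dataclass
class EmissionState:
    """Cross-wave bookkeeping for match-record emission."""

    # (ego_id, kind, member) -> (nomination_id, wave) of latest nomination
    last_nomination: dict = field(default_factory=dict)
    attended_prev: dict = field(default_factory=dict)  # ego_id -> attended last wave


ROSTER_COLUMNS = [
    "ego_id", "wave", "kind", "nomination_id", "position", "is_primary_partner",
    "window", "alter_gender", "alter_msm", "alter_hiv", "alter_exchange_sex",
    "alter_received_payment", "alter_partner_pref", "also_confidant",
]


def _alter_attr_row(attrs: pd.DataFrame, member: int, kind: str) -> dict:
    row = attrs.iloc[member]
    gender = "transgender_woman" if row["group"] == "TGW" else "man"
    hiv = (("positive" if row["hiv_positive"] else "negative")
           if row["hiv_known"] else "unknown")
    out = {"alter_gender": gender, "alter_msm": True, "alter_hiv": hiv}
    if kind == "sexual":
        out.update(
            alter_exchange_sex=bool(row["alter_exchange_sex"]),
            alter_received_payment=bool(row["alter_received_payment"]),
            alter_partner_pref=row["alter_partner_pref"],
        )
    else:
        out.update(alter_exchange_sex=None, alter_received_payment=None,
                   alter_partner_pref=None)
    return out


def emit_wave_tables(population: Population, sample: list, wave: int,
                     config: SimulationConfig, *, roster_rng, attrition_rng,
                     state: EmissionState):
    """Emit one wave's roster, match, attendance, and ground-truth rows.

    Attendance at wave 1 is universal; at later waves each ego attends
    with their group's retention probability, independently per wave.
    Rosters are capped (uniform subsample over the cap); the primary
    sexual partner is flagged in place when already listed, otherwise
    appended as a sixth entry. Match records link each nomination to the
    same alter's most recent earlier nomination by the same ego and
    kind; the Wave-3+ confirmation list is cumulative over all earlier
    waves.
    """
    ego_ids = {m: f"E{i:04d}" for i, m in enumerate(sample)}
    attrs = population.attrs
    groups = attrs["group"].to_numpy()
    roster_rows: list = []
    match_rows: list = []
    attendance_rows: list = []
    truth_rows: list = []

    adj = {kind: population.neighbors(wave, kind) for kind in KINDS}
    window = "past_6_months" if wave == 1 else "since_last_interview"

    for m in sample:
        ego = ego_ids[m]
        if wave == 1:
            attended = True
        else:
            attended = bool(attrition_rng.random() < config.attrition_retention.get(groups[m], 1.0))
        attendance_rows.append({"ego_id": ego, "wave": wave, "attended": attended})
        if not attended:
            continue

        confidant_members: list = []
        for kind in KINDS:
            ties = sorted(adj[kind][m])
            cap = CONFIDANT_CAP if kind == "confidant" else SEXUAL_RECENT_CAP
            if len(ties) > cap:
                picks = roster_rng.choice(len(ties), size=cap, replace=False)
                listed = [ties[i] for i in sorted(picks)]
            else:
                listed = list(ties)

            primary: Optional[int] = None
            if kind == "sexual" and ties and bool(attrs.at[m, "in_relationship"]):
                primary = ties[int(roster_rng.integers(0, len(ties)))]
                if primary not in listed:
                    listed = listed + [primary]

            for pos, alter in enumerate(listed, start=1):
                nom = f"W{wave}-{ego}-{kind[0].upper()}{pos}"
                rec = {
                    "ego_id": ego, "wave": wave, "kind": kind,
                    "nomination_id": nom, "position": pos,
                    "is_primary_partner": (kind == "sexual" and alter == primary),
                    "window": window if kind == "sexual" else "current",
                    "also_confidant": (alter in confidant_members) if kind == "sexual" else None,
                }
                rec.update(_alter_attr_row(attrs, alter, kind))
                roster_rows.append(rec)
                truth_rows.append({"nomination_id": nom, "member": f"P{alter:05d}",
                                   "ego_id": ego, "wave": wave, "kind": kind})
                key = (ego, kind, alter)
                prior = state.last_nomination.get(key)
                if prior is not None:
                    match_rows.append({
                        "ego_id": ego, "kind": kind,
                        "nomination_id_earlier": prior[0],
                        "nomination_id_later": nom,
                        "wave_earlier": prior[1], "wave_later": wave,
                    })
                state.last_nomination[key] = (nom, wave)
            if kind == "confidant":
                confidant_members = listed
    return roster_rows, match_rows, attendance_rows, truth_rows


# ---------------------------------------------------------------------------
# full cohort simulation


def _respondents_table(population: Population, forest: RecruitmentForest,
                       sample: list, config: SimulationConfig) -> pd.DataFrame:
    ego_ids = {m: f"E{i:04d}" for i, m in enumerate(sample)}
    rows = []
    for m in sample:
        r = population.attrs.iloc[m]
        rec = {
            "ego_id": ego_ids[m],
            "group": r["group"],
            "age_years": float(r["age_years"]),
            "hiv_positive": bool(r["hiv_positive"]) if r["hiv_known"] else None,
            "employed": bool(r["employed"]),
            "income_lt_20k": bool(r["income_lt_20k"]),
            "stably_housed": bool(r["stably_housed"]),
            "ever_jail": bool(r["ever_jail"]),
            "insured": bool(r["insured"]),
            "in_relationship": bool(r["in_relationship"]),
            "n_sex_partners_6mo": int(r["n_sex_partners_6mo"]),
            "recruiter_id": ego_ids.get(forest.recruiter_of.get(m)),
            "rds_depth": forest.depth_of[m],
        }
        for w in range(1, config.n_waves + 1):
            rec[f"orientation_w{w}"] = r[f"orientation_w{w}"]
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_cohort(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Run the full simulator: population, RDS, waves, dynamics, tables."""
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    population = generate_population(cfg)
    forest, sample = run_rds_recruitment(population, cfg)

    rng_dyn = _stream(cfg.rng_seed, "dynamics")
    rng_att = _stream(cfg.rng_seed, "attrition")
    rng_ros = _stream(cfg.rng_seed, "rosters")
    state = EmissionState()

    roster_rows: list = []
    match_rows: list = []
    attendance_rows: list = []
    truth_rows: list = []
    persistence: list = []
    for wave in range(1, cfg.n_waves + 1):
        rr, mr, ar, tr = emit_wave_tables(
            population, sample, wave, cfg,
            roster_rng=rng_ros, attrition_rng=rng_att, state=state,
        )
        roster_rows += rr
        match_rows += mr
        attendance_rows += ar
        truth_rows += tr
        if wave < cfg.n_waves:
            _, records = evolve_ties(population, wave, cfg, rng=rng_dyn)
            persistence += records

    respondents = _respondents_table(population, forest, sample, cfg)
    rosters = pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS)
    matches = pd.DataFrame(
        match_rows,
        columns=["ego_id", "kind", "nomination_id_earlier", "nomination_id_later",
                 "wave_earlier", "wave_later"],
    )
    attendance = pd.DataFrame(attendance_rows, columns=["ego_id", "wave", "attended"])
    truth = GroundTruth(
        config=cfg,
        nomination_members=pd.DataFrame(
            truth_rows, columns=["nomination_id", "member", "ego_id", "wave", "kind"]
        ),
        persistence=pd.DataFrame(
            persistence,
            columns=["kind", "wave_from", "u", "v", "owner_group", "persisted"],
        ),
        ties_by_wave=population.ties_by_wave,
        ego_members=pd.DataFrame(
            {"ego_id": [f"E{i:04d}" for i in range(len(sample))],
             "member": [f"P{m:05d}" for m in sample]}
        ),
    )
    return SimulatedDataset(
        respondents=respondents, rosters=rosters, matches=matches,
        attendance=attendance, ground_truth=truth,
    )
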