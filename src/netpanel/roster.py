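"""Longitudinal roster data model and cross-wave alter identity resolution.

A dataset is four tables: respondents (one row per enrolled ego),
rosters (one row per alter nomination at a wave, confidant or sexual),
matches (respondent-confirmed links between a nomination and the same
alter's nomination at an earlier wave), and attendance (ego x wave).
Identity resolution takes the connected components of the match graph
over nominations, per ego and per kind; unmatched nominations become
singleton alters. Alters are never linked across egos: the interview
instrument only asks a respondent to compare their own lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from netpanel.simulate import (
    CONFIDANT_CAP,
    GROUPS,
    KINDS,
    SEXUAL_TOTAL_CAP,
    GroundTruth,
    SimulatedDataset,
)


class DatasetError(ValueError):
    """Hard validation failure (e.g. duplicated ego ids)."""


class AbsentVisitError(KeyError):
    """An ego's roster was requested for a wave they did not attend."""


@dataclass
class Violation:
    table: str
    row: object  # positional row index, or None for table-level problems
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.table}[{self.row}]" if self.row is not None else self.table
        return f"{where}: {self.message}"


@dataclass
class AlterIdentityMap:
    """nomination_id -> alter_id equivalence classes, per ego and kind."""

    alter_of: dict
    inconsistencies: list = field(default_factory=list)

    def __getitem__(self, nomination_id: str) -> str:
        return self.alter_of[nomination_id]


@dataclass
class Dataset:
    """A validated roster dataset with lazily resolved alter identities."""

    respondents: pd.DataFrame
    rosters: pd.DataFrame
    matches: pd.DataFrame
    attendance: pd.DataFrame
    violations: list = field(default_factory=list)
    ground_truth: Optional[GroundTruth] = None
    _alter_map: Optional[AlterIdentityMap] = None

    @property
    def waves(self) -> list:
        return sorted(self.attendance["wave"].unique())

    @property
    def alter_map(self) -> AlterIdentityMap:
        if self._alter_map is None:
            self._alter_map = resolve_alters(self.matches, self.rosters)
        return self._alter_map

    def _attendance_cache(self) -> dict:
        if not hasattr(self, "_attended_by_ego"):
            by_ego: dict = {}
            for r in self.attendance.itertuples(index=False):
                if r.attended:
                    by_ego.setdefault(r.ego_id, set()).add(int(r.wave))
            self._attended_by_ego = by_ego
        return self._attended_by_ego

    def _roster_cache(self) -> dict:
        if not hasattr(self, "_nominations_by_key"):
            by_key: dict = {}
            for r in self.rosters.itertuples(index=False):
                by_key.setdefault((r.ego_id, int(r.wave), r.kind), []).append(r.nomination_id)
            self._nominations_by_key = by_key
        return self._nominations_by_key

    def attended(self, ego: str, wave: int) -> bool:
        return wave in self._attendance_cache().get(ego, ())

    def attended_waves(self, ego: str) -> list:
        return sorted(self._attendance_cache().get(ego, ()))

    def group_of(self, ego: str) -> str:
        return self._group_lookup()[ego]

    def _group_lookup(self) -> dict:
        if not hasattr(self, "_groups_cache"):
            self._groups_cache = dict(
                zip(self.respondents["ego_id"], self.respondents["group"])
            )
        return self._groups_cache


def _check_rosters(rosters: pd.DataFrame, known_egos: set,
                   attended: set, out: list) -> None:
    seen_nominations: set = set()
    primaries: dict = {}
    for i, row in enumerate(rosters.itertuples(index=False)):
        if row.kind not in KINDS:
            out.append(Violation("rosters", i, f"unknown roster kind {row.kind!r}"))
            continue
        if row.ego_id not in known_egos:
            out.append(Violation("rosters", i, f"ego {row.ego_id!r} not enrolled"))
        if (row.ego_id, row.wave) not in attended and row.ego_id in known_egos:
            out.append(
                Violation("rosters", i,
                          f"roster entry for non-attended visit ego={row.ego_id} wave={row.wave}")
            )
        cap = CONFIDANT_CAP if row.kind == "confidant" else SEXUAL_TOTAL_CAP
        if not 1 <= row.position <= cap:
            out.append(
                Violation("rosters", i,
                          f"cap exceeded: position {row.position} outside 1..{cap} for {row.kind}")
            )
        if row.nomination_id in seen_nominations:
            out.append(Violation("rosters", i, f"duplicate nomination_id {row.nomination_id!r}"))
        seen_nominations.add(row.nomination_id)
        if bool(row.is_primary_partner):
            if row.kind != "sexual":
                out.append(Violation("rosters", i, "is_primary_partner set on a confidant entry"))
            else:
                key = (row.ego_id, row.wave)
                if key in primaries:
                    out.append(Violation("rosters", i, f"second primary partner for ego={row.ego_id} wave={row.wave}"))
                primaries[key] = i


def _check_matches(matches: pd.DataFrame, rosters: pd.DataFrame, out: list) -> None:
    info = {
        r.nomination_id: (r.ego_id, r.kind, r.wave)
        for r in rosters.itertuples(index=False)
    }
    for i, row in enumerate(matches.itertuples(index=False)):
        a = info.get(row.nomination_id_earlier)
        b = info.get(row.nomination_id_later)
        if a is None or b is None:
            missing = row.nomination_id_earlier if a is None else row.nomination_id_later
            out.append(Violation("matches", i, f"match references unknown nomination {missing!r}"))
            continue
        if a[0] != b[0]:
            out.append(Violation("matches", i, f"cross-ego match {a[0]!r} vs {b[0]!r}"))
        if a[1] != b[1]:
            out.append(Violation("matches", i, f"cross-kind match {a[1]!r} vs {b[1]!r}"))
        if not a[2] < b[2]:
            out.append(
                Violation("matches", i,
                          f"wave_earlier ({a[2]}) must precede wave_later ({b[2]})")
            )


def validate_dataset(respondents: pd.DataFrame, rosters: pd.DataFrame,
                     matches: pd.DataFrame, attendance: pd.DataFrame,
                     ground_truth: Optional[GroundTruth] = None) -> Dataset:
    """Check referential integrity and roster invariants.

    Duplicate ego ids abort with :class:`DatasetError`; all other
    violations are collected on the returned dataset with their table
    and row coordinates.
    """
    out: list = []
    dup = respondents["ego_id"].duplicated()
    if dup.any():
        raise DatasetError(
            f"duplicate ego_ids in respondents: {sorted(respondents['ego_id'][dup].unique())}"
        )
    known = set(respondents["ego_id"])
    bad_group = ~respondents["group"].isin(GROUPS)
    for i in respondents.index[bad_group]:
        out.append(Violation("respondents", int(i), f"unknown group {respondents.at[i, 'group']!r}"))

    for i, row in enumerate(attendance.itertuples(index=False)):
        if row.ego_id not in known:
            out.append(Violation("attendance", i, f"ego {row.ego_id!r} not enrolled"))
        if row.wave < 1:
            out.append(Violation("attendance", i, f"wave index {row.wave} must be >= 1"))

    attended = {
        (r.ego_id, r.wave)
        for r in attendance.itertuples(index=False)
        if r.attended
    }
    _check_rosters(rosters, known, attended, out)
    _check_matches(matches, rosters, out)
    return Dataset(
        respondents=respondents, rosters=rosters, matches=matches,
        attendance=attendance, violations=out, ground_truth=ground_truth,
    )


def from_simulation(sim: SimulatedDataset) -> Dataset:
    """Validate a simulator output bundle, keeping its ground truth."""
    ds = validate_dataset(sim.respondents, sim.rosters, sim.matches,
                          sim.attendance, ground_truth=sim.ground_truth)
    return ds


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def resolve_alters(matches: pd.DataFrame, rosters: pd.DataFrame) -> AlterIdentityMap:
    """Connected components of the match graph, per ego and kind.

    Alter labels are ``"<ego>|<kind>|<earliest nomination id>"``.  A
    match whose acceptance would merge two nominations made at the same
    wave by the same ego (the instrument forbids that: one person cannot
    appear twice on one list) is skipped and reported; matches are
    processed in a canonical sorted order, so the result is independent
    of input row order and re-resolution is idempotent.
    """
    uf = _UnionFind()
    wave_of: dict = {}
    scope: dict = {}
    for r in rosters.itertuples(index=False):
        uf.add(r.nomination_id)
        wave_of[r.nomination_id] = r.wave
        scope[r.nomination_id] = (r.ego_id, r.kind)

    # waves already present in each component, for same-wave conflict checks
    comp_waves: dict = {n: {wave_of[n]} for n in wave_of}
    inconsistencies: list = []

    edges = sorted(
        (r.nomination_id_earlier, r.nomination_id_later)
        for r in matches.itertuples(index=False)
        if r.nomination_id_earlier in wave_of and r.nomination_id_later in wave_of
        and scope[r.nomination_id_earlier] == scope[r.nomination_id_later]
    )
    for a, b in edges:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        if comp_waves[ra] & comp_waves[rb]:
            inconsistencies.append(
                f"match {a}~{b} would merge two same-wave nominations; kept split"
            )
            continue
        uf.union(a, b)
        root = uf.find(a)
        merged = comp_waves.pop(ra) | comp_waves.pop(rb)
        comp_waves[root] = merged

    members: dict = {}
    for n in wave_of:
        members.setdefault(uf.find(n), []).append(n)
    alter_of: dict = {}
    for root, noms in members.items():
        ego, kind = scope[root]
        label = f"{ego}|{kind}|{min(noms)}"
        for n in noms:
            alter_of[n] = label
    return AlterIdentityMap(alter_of=alter_of, inconsistencies=inconsistencies)


def roster_set(dataset: Dataset, ego: str, wave: int, kind: str) -> frozenset:
    """Deduplicated alter_ids nominated by ``ego`` at ``wave`` in ``kind``.

    The primary sexual partner is part of the sexual set.  Querying a
    wave the ego did not attend raises :class:`AbsentVisitError`, which
    is distinct from an attended visit with an empty roster.
    """
    if not dataset.attended(ego, wave):
        raise AbsentVisitError(f"ego {ego!r} did not attend wave {wave}")
    noms = dataset._roster_cache().get((ego, int(wave), kind), ())
    amap = dataset.alter_map
    return frozenset(amap[n] for n in noms)
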