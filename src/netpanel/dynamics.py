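"""Tie-change classification and the stability and turnover ratios.

For every ego with at least two attended study visits, each resolved
alter in a roster kind is classified over the ego's ordered attended
visits v1..vk:

* original — nominated at v1 (count O);
* retained — original and present at every subsequent attended visit
  under the default "strict" rule, or at any later visit under the
  "any-later" rule (count R);
* new — first nominated after v1, counted once (count N);
* lost — original with at least one disappearance between consecutive
  attended visits (count L).

The cumulative network size C is the number of unique alters over all
attended visits, so C = O + N. The stability ratio is R/O and the
turnover ratio is (N + L)/C. Each alter contributes at most once to
N + L (a tie lost and later regained counts one loss; a tie acquired
after v1 and later dropped counts once, as new), which bounds the
turnover ratio by 1 and makes it exactly 1 - R/C for two-visit egos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from netpanel.roster import Dataset, roster_set
from netpanel.simulate import GROUPS, KINDS

RETAINED_RULES = ("strict", "any-later")


class IneligibleEgoError(ValueError):
    """Ego excluded from dynamics (fewer than two attended visits)."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio denominator is zero (empty original or cumulative network)."""


@dataclass
class TieChangeSummary:
    """Per-ego, per-kind tie-change counts and ratios."""

    ego_id: str
    kind: str
    original: int  # O
    retained: int  # R
    lost: int  # L
    new: int  # N
    cumulative: int  # C
    n_visits: int
    retained_rule: str = "strict"

    @property
    def stability(self) -> float:
        return stability_ratio(self)

    @property
    def turnover(self) -> float:
        return turnover_ratio(self)


@dataclass
class RatioComparison:
    """Group comparison of one ratio for one roster kind."""

    kind: str
    ratio: str  # "stability" or "turnover"
    mean_tgw: float
    mean_msm: float
    n_tgw: int
    n_msm: int
    t_statistic: float
    p_value: float
    flag: Optional[str] = None  # "degenerate" or "not-computable"


def classify_ties(dataset: Dataset, ego: str, kind: str,
                  retained_rule: str = "strict"):
    """Classify one ego's ties; returns (TieChangeSummary, per-alter records).

    Raises :class:`IneligibleEgoError` for egos with fewer than two
    attended visits — such egos are excluded with a reason, never given
    a zero ratio.
    """
    if retained_rule not in RETAINED_RULES:
        raise ValueError(f"retained_rule must be one of {RETAINED_RULES}")
    visits = dataset.attended_waves(ego)
    if len(visits) < 2:
        raise IneligibleEgoError(
            f"ego {ego!r} attended {len(visits)} visit(s); dynamics require >= 2"
        )
    rosters = [roster_set(dataset, ego, w, kind) for w in visits]
    original = rosters[0]
    all_alters = sorted(set().union(*rosters))

    records = []
    retained_set: set = set()
    lost_set: set = set()
    new_set: set = set()
    for alter in all_alters:
        present = [alter in r for r in rosters]
        is_original = present[0]
        disappearances = sum(
            1 for i in range(len(visits) - 1) if present[i] and not present[i + 1]
        )
        if is_original:
            strictly_kept = all(present)
            any_later = any(present[1:])
            kept = strictly_kept if retained_rule == "strict" else any_later
            if kept:
                retained_set.add(alter)
            if disappearances > 0:
                lost_set.add(alter)
            status = "retained" if kept else "lost"
        else:
            new_set.add(alter)
            status = "new"
        records.append({
            "ego_id": ego, "kind": kind, "alter_id": alter, "status": status,
            "first_visit": visits[present.index(True)],
            "n_appearances": sum(present),
            "n_disappearances": disappearances,
        })

    summary = TieChangeSummary(
        ego_id=ego, kind=kind,
        original=len(original), retained=len(retained_set),
        lost=len(lost_set), new=len(new_set),
        cumulative=len(all_alters), n_visits=len(visits),
        retained_rule=retained_rule,
    )
    return summary, records


def stability_ratio(summary: TieChangeSummary) -> float:
    """Retained ties divided by the original network size, R/O."""
    if summary.original == 0:
        raise UndefinedRatioError(
            f"ego {summary.ego_id!r} ({summary.kind}): original network empty"
        )
    return summary.retained / summary.original


def turnover_ratio(summary: TieChangeSummary) -> float:
    """New plus lost ties divided by the cumulative network size, (N+L)/C."""
    if summary.cumulative == 0:
        raise UndefinedRatioError(
            f"ego {summary.ego_id!r} ({summary.kind}): cumulative network empty"
        )
    return (summary.new + summary.lost) / summary.cumulative


def _welch(a, b, pooled=False):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan, "not-computable"
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, np.nan, "degenerate"
        # zero within-group variance but distinct means: infinitely strong
        return np.inf, 0.0, "degenerate"
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p), None


def cohort_dynamics(dataset: Dataset, retained_rule: str = "strict",
                    ttest: str = "welch"):
    """Per-ego tie-change summaries and group ratio comparisons.

    Returns ``(summaries, comparisons, exclusions)``: one summary row
    per eligible ego per kind (egos with an undefined ratio keep their
    counts, with NaN in that ratio column), one comparison row per
    (kind, ratio), and a list of (ego, kind, reason) exclusions.
    """
    rows = []
    exclusions = []
    for ego in dataset.respondents["ego_id"]:
        for kind in KINDS:
            try:
                summary, _ = classify_ties(dataset, ego, kind, retained_rule)
            except IneligibleEgoError as e:
                exclusions.append((ego, kind, str(e)))
                continue
            try:
                stab = stability_ratio(summary)
            except UndefinedRatioError as e:
                stab = np.nan
                exclusions.append((ego, kind, str(e)))
            try:
                turn = turnover_ratio(summary)
            except UndefinedRatioError:
                turn = np.nan
            rows.append({
                "ego_id": ego, "kind": kind, "group": dataset.group_of(ego),
                "original": summary.original, "retained": summary.retained,
                "lost": summary.lost, "new": summary.new,
                "cumulative": summary.cumulative, "n_visits": summary.n_visits,
                "stability": stab, "turnover": turn,
            })
    summaries = pd.DataFrame(
        rows, columns=["ego_id", "kind", "group", "original", "retained", "lost",
                       "new", "cumulative", "n_visits", "stability", "turnover"],
    )

    comparisons = []
    pooled = ttest == "pooled"
    for kind in KINDS:
        sub = summaries[summaries["kind"] == kind]
        for ratio in ("stability", "turnover"):
            vals = {g: sub.loc[(sub["group"] == g) & sub[ratio].notna(), ratio].to_numpy()
                    for g in GROUPS}
            t, p, flag = _welch(vals["TGW"], vals["MSM"], pooled=pooled)
            comparisons.append(RatioComparison(
                kind=kind, ratio=ratio,
                mean_tgw=float(np.mean(vals["TGW"])) if len(vals["TGW"]) else np.nan,
                mean_msm=float(np.mean(vals["MSM"])) if len(vals["MSM"]) else np.nan,
                n_tgw=len(vals["TGW"]), n_msm=len(vals["MSM"]),
                t_statistic=t, p_value=p, flag=flag,
            ))
    comp_df = pd.DataFrame([vars(c) for c in comparisons])
    return summaries, comp_df, exclusions
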