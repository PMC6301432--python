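"""Ego-network composition covariates and comparative statistics.

Builds per-ego covariates from the resolved rosters (e.g. proportion of
transgender confidants, number of HIV-positive confidants, exchange-sex
indicators among sexual partners), and runs the cohort's comparative
analyses: baseline descriptive summaries with t-tests and chi-square /
Fisher exact tests, Welch t-tests for continuous outcomes, and
unadjusted logistic-regression odds ratios comparing TGW with MSM (the
reference group).

Missingness policy: every statistic uses pairwise-complete records —
each variable's denominator is the egos (or alters) with that variable
observed, recorded alongside the estimate. Nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from netpanel.roster import Dataset
from netpanel.simulate import GROUPS

INCOME_THRESHOLD = 20_000.0


@dataclass
class ComparisonResult:
    """One comparison row: an estimate, its 95% CI, and a two-sided p."""

    label: str
    test: str  # "welch-t", "pooled-t", "logit-or", "haldane-or", "chi2", "fisher"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int
    flag: Optional[str] = None


def dichotomize_income(amount) -> Optional[bool]:
    """True iff annual income is strictly below $20,000.

    The survey dichotomy leaves exactly $20,000 unassigned; this
    implementation deterministically maps it to not-below. Missing
    income returns None (unknown).
    """
    if amount is None or (isinstance(amount, float) and np.isnan(amount)):
        return None
    if amount < 0:
        raise ValueError(f"income must be nonnegative, got {amount!r}")
    return bool(amount < INCOME_THRESHOLD)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage as printed in summary tables (one decimal by default)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def _prop(series_bool: pd.Series):
    """(proportion, denominator) over non-missing values; NaN if none."""
    known = series_bool.dropna()
    if len(known) == 0:
        return float("nan"), 0
    return float(known.astype(float).mean()), int(len(known))


COMPOSITION_COLUMNS = [
    "ego_id", "group",
    "n_confidants", "prop_trans_confidants", "n_trans_confidants_msm",
    "prop_men_confidants", "n_men_confidants_msm", "n_hiv_pos_confidants",
    "prop_hiv_pos_confidants", "denom_hiv_confidants",
    "n_partners", "exchange_sex", "received_payment",
    "n_pref_men", "n_pref_tgw", "n_pref_cis_women",
    "prop_partners_exchange_sex", "denom_exchange_partners",
    "cis_women_partner",
]


def ego_composition(dataset: Dataset, wave: int = 1) -> pd.DataFrame:
    """Per-ego roster-composition covariates at one wave.

    Proportions are taken over alters with the attribute observed and
    the effective denominator is recorded; empty rosters yield NaN
    proportions and zero counts.
    """
    rosters = dataset.rosters[dataset.rosters["wave"] == wave]
    rows = []
    for r in dataset.respondents.itertuples(index=False):
        if not dataset.attended(r.ego_id, wave):
            continue
        mine = rosters[rosters["ego_id"] == r.ego_id]
        conf = mine[mine["kind"] == "confidant"]
        sex = mine[mine["kind"] == "sexual"]

        gender = conf["alter_gender"].replace({"unknown": None}) if len(conf) else pd.Series(dtype=object)
        is_trans = gender.map(lambda g: None if g is None else g == "transgender_woman") if len(conf) else pd.Series(dtype=object)
        is_man = gender.map(lambda g: None if g is None else g == "man") if len(conf) else pd.Series(dtype=object)
        msm_flag = conf["alter_msm"] if len(conf) else pd.Series(dtype=object)
        hiv = conf["alter_hiv"].map({"positive": True, "negative": False}) if len(conf) else pd.Series(dtype=object)

        prop_trans, _ = _prop(is_trans) if len(conf) else (float("nan"), 0)
        prop_men, _ = _prop(is_man) if len(conf) else (float("nan"), 0)
        prop_hiv, denom_hiv = _prop(hiv) if len(conf) else (float("nan"), 0)

        ex = sex["alter_exchange_sex"] if len(sex) else pd.Series(dtype=object)
        pay = sex["alter_received_payment"] if len(sex) else pd.Series(dtype=object)
        pref = sex["alter_partner_pref"] if len(sex) else pd.Series(dtype=object)
        prop_ex, denom_ex = _prop(ex) if len(sex) else (float("nan"), 0)

        ex_known = ex.dropna() if len(sex) else ex
        pay_known = pay.dropna() if len(sex) else pay
        rows.append({
            "ego_id": r.ego_id, "group": r.group,
            "n_confidants": int(len(conf)),
            "prop_trans_confidants": prop_trans,
            "n_trans_confidants_msm": int(((is_trans == True) & (msm_flag == True)).sum()) if len(conf) else 0,  # noqa: E712
            "prop_men_confidants": prop_men,
            "n_men_confidants_msm": int(((is_man == True) & (msm_flag == True)).sum()) if len(conf) else 0,  # noqa: E712
            "n_hiv_pos_confidants": int((hiv == True).sum()) if len(conf) else 0,  # noqa: E712
            "prop_hiv_pos_confidants": prop_hiv,
            "denom_hiv_confidants": denom_hiv,
            "n_partners": int(len(sex)),
            "exchange_sex": bool(ex_known.astype(bool).any()) if len(ex_known) else (None if len(sex) == 0 else False),
            "received_payment": bool(pay_known.astype(bool).any()) if len(pay_known) else (None if len(sex) == 0 else False),
            "n_pref_men": int((pref == "men").sum()) if len(sex) else 0,
            "n_pref_tgw": int((pref == "tgw").sum()) if len(sex) else 0,
            "n_pref_cis_women": int((pref == "cis_women").sum()) if len(sex) else 0,
            "prop_partners_exchange_sex": prop_ex,
            "denom_exchange_partners": denom_ex,
            "cis_women_partner": bool((sex["alter_gender"] == "cis_woman").any()) if len(sex) else None,
        })
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def welch_t_test(values_a, values_b, label: str = "", pooled: bool = False) -> ComparisonResult:
    """Two-sided independent t-test (Welch–Satterthwaite df by default).

    The estimate is mean(a) - mean(b) with its 95% CI. Degenerate input
    (zero variance in both samples) is flagged.
    """
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 finite values")
    diff = float(np.mean(a) - np.mean(b))
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return ComparisonResult(label, "welch-t", diff, np.nan, np.nan,
                                np.nan if diff == 0 else 0.0,
                                len(a), len(b), flag="degenerate")
    if pooled:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
        se = float(np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))
        kind = "pooled-t"
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        se = float(np.sqrt(va / len(a) + vb / len(b)))
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        kind = "welch-t"
    crit = float(sps.t.ppf(0.975, df))
    return ComparisonResult(label, kind, diff, diff - crit * se, diff + crit * se,
                            float(p), len(a), len(b))


def haldane_or(a: int, b: int, c: int, d: int, label: str = "") -> ComparisonResult:
    """2x2 cross-product OR with the Haldane–Anscombe 0.5 correction.

    Table layout: rows = exposure (TGW, MSM), cols = outcome (yes, no):
    ``a``=TGW yes, ``b``=TGW no, ``c``=MSM yes, ``d``=MSM no. The
    correction is applied only when a zero cell requires it.
    """
    cells = np.array([a, b, c, d], dtype=float)
    corrected = (cells == 0).any()
    if corrected:
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    se = float(np.sqrt((1 / cells).sum()))
    z = np.log(or_) / se
    p = float(2 * sps.norm.sf(abs(z)))
    return ComparisonResult(
        label, "haldane-or" if corrected else "crossproduct-or",
        float(or_), float(np.exp(np.log(or_) - 1.959963984540054 * se)),
        float(np.exp(np.log(or_) + 1.959963984540054 * se)), p,
        int(a + b), int(c + d),
        flag="haldane-anscombe" if corrected else None,
    )


def logistic_or(y, x, label: str = "") -> ComparisonResult:
    """Unadjusted logistic regression OR of y on x (Wald CI and p).

    For a binary predictor with a zero cell in the implied 2x2 table
    (perfect separation territory) the corrected cross-product fallback
    engages and is flagged.
    """
    df = pd.DataFrame({"y": y, "x": x}).dropna()
    yv = df["y"].astype(float).to_numpy()
    xv = df["x"].astype(float).to_numpy()
    if len(df) < 2 or len(np.unique(yv)) < 2:
        return ComparisonResult(label, "logit-or", np.nan, np.nan, np.nan, np.nan,
                                int((xv == 1).sum()), int((xv == 0).sum()),
                                flag="not-computable")
    binary_x = set(np.unique(xv)) <= {0.0, 1.0}
    if binary_x:
        a = int(((xv == 1) & (yv == 1)).sum())
        b = int(((xv == 1) & (yv == 0)).sum())
        c = int(((xv == 0) & (yv == 1)).sum())
        d = int(((xv == 0) & (yv == 0)).sum())
        if min(a, b, c, d) == 0:
            return haldane_or(a, b, c, d, label=label)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(yv, sm.add_constant(xv)).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        converged = False
    if not converged:
        return ComparisonResult(label, "logit-or", np.nan, np.nan, np.nan, np.nan,
                                int((xv == 1).sum()) if binary_x else len(df), 0,
                                flag="nonconvergent")
    beta, se = float(res.params[1]), float(res.bse[1])
    crit = 1.959963984540054
    return ComparisonResult(
        label, "logit-or", float(np.exp(beta)),
        float(np.exp(beta - crit * se)), float(np.exp(beta + crit * se)),
        float(res.pvalues[1]),
        int((xv == 1).sum()) if binary_x else len(df),
        int((xv == 0).sum()) if binary_x else 0,
    )


def unadjusted_or(dataset: Dataset, covariate: str, direction: str = "auto",
                  wave: int = 1, composition: Optional[pd.DataFrame] = None) -> ComparisonResult:
    """Unadjusted OR comparing TGW with MSM (reference) on one covariate.

    ``direction`` picks the model framing: "outcome-on-group" regresses
    a binary ego-level covariate on the TGW indicator (OR = odds of the
    covariate among TGW relative to MSM); "group-on-covariate"
    regresses the TGW indicator on the covariate (OR per unit, the
    natural framing for counts and proportions). "auto" selects by
    covariate type. The chosen framing is recorded in the result label.
    """
    if composition is None:
        composition = ego_composition(dataset, wave)
    if covariate in composition.columns:
        table = composition
    elif covariate in dataset.respondents.columns:
        table = composition[["ego_id", "group"]].merge(
            dataset.respondents[["ego_id", covariate]], on="ego_id", how="left"
        )
    else:
        raise KeyError(f"unknown covariate {covariate!r}")
    sub = table[["group", covariate]].dropna()
    is_tgw = (sub["group"] == "TGW").astype(float)
    values = sub[covariate]
    binary = values.map(lambda v: isinstance(v, (bool, np.bool_)) or v in (0, 1)).all()
    if direction == "auto":
        direction = "outcome-on-group" if binary else "group-on-covariate"
    if direction == "outcome-on-group":
        result = logistic_or(values.astype(float), is_tgw, label=f"{covariate} [outcome-on-group]")
    elif direction == "group-on-covariate":
        result = logistic_or(is_tgw, values.astype(float), label=f"{covariate} [group-on-covariate]")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return result


def _categorical_test(counts: pd.DataFrame):
    """Chi-square (no continuity correction); Fisher exact for sparse 2x2."""
    table = counts.to_numpy(dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, "not-computable", "not-computable"
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = sps.fisher_exact(table)
        return float(p), "fisher", None
    flag = "small-expected" if (expected < 5).any() else None
    return float(p), "chi2", flag


BASELINE_CONTINUOUS = [("Age (years)", "age_years"),
                       ("Number of partners (previous 6 months)", "n_sex_partners_6mo")]
BASELINE_BINARY = [("Has health insurance", "insured"),
                   ("HIV positive (laboratory confirmed)", "hiv_positive"),
                   ("In a romantic relationship", "in_relationship"),
                   ("Employed", "employed"),
                   ("Income <$20,000/year", "income_lt_20k"),
                   ("Stably housed", "stably_housed"),
                   ("Ever in jail", "ever_jail")]


def baseline_table(dataset: Dataset) -> pd.DataFrame:
    """Baseline sociodemographic summary by group with comparison tests.

    Continuous variables: mean (SD) and a Welch t-test. Categorical:
    count (percent over the variable's non-missing denominator) and a
    chi-square test, falling back to Fisher's exact test for sparse 2x2
    tables. Significance is marked at p <= 0.05.
    """
    resp = dataset.respondents
    by_group = {g: resp[resp["group"] == g] for g in GROUPS}
    n = {g: len(by_group[g]) for g in GROUPS}
    rows = [{
        "variable": "Enrolled", "level": "",
        "tgw_value": n["TGW"], "tgw_detail": percent(n["TGW"], len(resp)),
        "msm_value": n["MSM"], "msm_detail": percent(n["MSM"], len(resp)),
        "denom_tgw": len(resp), "denom_msm": len(resp),
        "p_value": np.nan, "test": "", "significant": False,
    }]

    def add_row(variable, level, tv, td, mv, md, dt, dm, p, test):
        rows.append({
            "variable": variable, "level": level,
            "tgw_value": tv, "tgw_detail": td, "msm_value": mv, "msm_detail": md,
            "denom_tgw": dt, "denom_msm": dm, "p_value": p, "test": test,
            "significant": bool(p <= 0.05) if p == p else False,
        })

    for label, col in BASELINE_CONTINUOUS:
        if col not in resp.columns:
            continue
        a = by_group["TGW"][col].dropna().astype(float)
        b = by_group["MSM"][col].dropna().astype(float)
        if len(a) >= 2 and len(b) >= 2:
            res = welch_t_test(a, b, label=label)
            p, test = res.p_value, res.test
        else:
            p, test = np.nan, "not-computable"
        add_row(label, "", round(float(a.mean()), 1) if len(a) else np.nan,
                round(float(a.std(ddof=1)), 1) if len(a) > 1 else np.nan,
                round(float(b.mean()), 1) if len(b) else np.nan,
                round(float(b.std(ddof=1)), 1) if len(b) > 1 else np.nan,
                len(a), len(b), p, test)

    for label, col in BASELINE_BINARY:
        if col not in resp.columns:
            continue
        known = {g: by_group[g][col].dropna() for g in GROUPS}
        counts = pd.DataFrame({
            g: [int(known[g].astype(bool).sum()), int((~known[g].astype(bool)).sum())]
            for g in GROUPS
        }).T
        if len(known["TGW"]) and len(known["MSM"]):
            p, test, flag = _categorical_test(counts)
        else:
            p, test = np.nan, "not-computable"
        add_row(label, "",
                int(known["TGW"].astype(bool).sum()) if len(known["TGW"]) else 0,
                percent(known["TGW"].astype(bool).sum(), len(known["TGW"])) if len(known["TGW"]) else np.nan,
                int(known["MSM"].astype(bool).sum()) if len(known["MSM"]) else 0,
                percent(known["MSM"].astype(bool).sum(), len(known["MSM"])) if len(known["MSM"]) else np.nan,
                len(known["TGW"]), len(known["MSM"]), p, test)

    if "orientation_w1" in resp.columns:
        levels = ["gay", "straight", "bisexual", "other"]
        known = {g: by_group[g]["orientation_w1"].dropna() for g in GROUPS}
        counts = pd.DataFrame({g: [int((known[g] == lv).sum()) for lv in levels]
                               for g in GROUPS}).T
        p, test, flag = (_categorical_test(counts)
                         if len(known["TGW"]) and len(known["MSM"])
                         else (np.nan, "not-computable", None))
        add_row("Sexual orientation", "", np.nan, np.nan, np.nan, np.nan,
                len(known["TGW"]), len(known["MSM"]), p, test)
        for lv in levels:
            add_row("Sexual orientation", lv,
                    int((known["TGW"] == lv).sum()),
                    percent((known["TGW"] == lv).sum(), len(known["TGW"])) if len(known["TGW"]) else np.nan,
                    int((known["MSM"] == lv).sum()),
                    percent((known["MSM"] == lv).sum(), len(known["MSM"])) if len(known["MSM"]) else np.nan,
                    len(known["TGW"]), len(known["MSM"]), np.nan, "")
    return pd.DataFrame(rows)


# Table-3-style covariate panel: label, composition column, default framing
NETWORK_OR_PANEL = [
    ("Proportion of transgender confidants", "prop_trans_confidants", "group-on-covariate"),
    ("Number of transgender confidants who have sex with men", "n_trans_confidants_msm", "group-on-covariate"),
    ("Proportion of men confidants", "prop_men_confidants", "group-on-covariate"),
    ("Number of men confidants who have sex with men", "n_men_confidants_msm", "group-on-covariate"),
    ("Number of HIV positive confidants", "n_hiv_pos_confidants", "group-on-covariate"),
    ("Exchange sex", "exchange_sex", "outcome-on-group"),
    ("Received payment for sex", "received_payment", "outcome-on-group"),
    ("Partner prefers TGW", "n_pref_tgw", "group-on-covariate"),
    ("Partner prefers cis women", "n_pref_cis_women", "group-on-covariate"),
    ("Partner prefers men", "n_pref_men", "group-on-covariate"),
    ("Proportion of partners who exchange sex for pay", "prop_partners_exchange_sex", "group-on-covariate"),
    ("Cis women partners", "cis_women_partner", "outcome-on-group"),
]


def network_or_table(dataset: Dataset, wave: int = 1,
                     direction: str = "auto") -> pd.DataFrame:
    """Unadjusted ORs for the roster-composition covariate panel."""
    composition = ego_composition(dataset, wave)
    rows = []
    for label, col, default in NETWORK_OR_PANEL:
        d = default if direction == "auto" else direction
        res = unadjusted_or(dataset, col, direction=d, wave=wave,
                            composition=composition)
        rows.append({
            "label": label, "covariate": col, "direction": d,
            "odds_ratio": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_value": res.p_value,
            "test": res.test, "flag": res.flag,
        })
    return pd.DataFrame(rows)
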