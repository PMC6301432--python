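import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netpanel.stats import (
    baseline_table,
    dichotomize_income,
    ego_composition,
    haldane_or,
    logistic_or,
    percent,
    unadjusted_or,
    welch_t_test,
)

from conftest import toy_dataset


@pytest.mark.parametrize("amount, expected", [
    (19999, True), (20000, False), (20001, False), (35000, False),
    (0, True), (None, None), (float("nan"), None),
])
def test_income_dichotomy_boundary(amount, expected):
    assert dichotomize_income(amount) is expected


def test_income_rejects_negative():
    with pytest.raises(ValueError):
        dichotomize_income(-1)


def _composition_fixture():
    conf = [
        ("c1", {"alter_gender": "transgender_woman", "alter_msm": True, "alter_hiv": "positive"}),
        ("c2", {"alter_gender": "transgender_woman", "alter_msm": False, "alter_hiv": "negative"}),
        ("c3", {"alter_gender": "man", "alter_msm": True, "alter_hiv": "unknown"}),
        ("c4", {"alter_gender": "man", "alter_msm": True, "alter_hiv": "positive"}),
        ("c5", {"alter_gender": "man", "alter_msm": False, "alter_hiv": "negative"}),
    ]
    sex = [
        ("p1", {"alter_exchange_sex": True, "alter_received_payment": False,
                "alter_partner_pref": "men"}),
        ("p2", {"alter_exchange_sex": False, "alter_received_payment": False,
                "alter_partner_pref": "tgw"}),
        ("p3", {"alter_exchange_sex": None, "alter_received_payment": None,
                "alter_partner_pref": "cis_women"}),
        ("p4", {"alter_gender": "cis_woman", "alter_exchange_sex": False,
                "alter_received_payment": False, "alter_partner_pref": "men"}),
    ]
    return toy_dataset({"A": {1: {"confidant": conf, "sexual": sex}},
                        "B": {1: {"confidant": [], "sexual": []}}},
                       groups={"A": "TGW", "B": "MSM"})


def test_composition_covariates_by_hand():
    comp = ego_composition(_composition_fixture(), wave=1).set_index("ego_id")
    a = comp.loc["A"]
    assert a["n_confidants"] == 5
    assert a["prop_trans_confidants"] == pytest.approx(0.4)
    assert a["n_trans_confidants_msm"] == 1
    assert a["prop_men_confidants"] == pytest.approx(0.6)
    assert a["n_men_confidants_msm"] == 2
    assert a["n_hiv_pos_confidants"] == 2
    assert a["denom_hiv_confidants"] == 4  # one unknown status excluded
    assert a["prop_hiv_pos_confidants"] == pytest.approx(0.5)
    assert a["n_partners"] == 4
    assert a["exchange_sex"] == True  # noqa: E712
    assert a["received_payment"] == False  # noqa: E712
    assert (a["n_pref_men"], a["n_pref_tgw"], a["n_pref_cis_women"]) == (2, 1, 1)
    assert a["prop_partners_exchange_sex"] == pytest.approx(1 / 3)
    assert a["denom_exchange_partners"] == 3
    assert a["cis_women_partner"] == True  # noqa: E712


def test_empty_roster_gives_zero_counts_and_undefined_proportions():
    comp = ego_composition(_composition_fixture(), wave=1).set_index("ego_id")
    b = comp.loc["B"]
    assert b["n_confidants"] == 0 and b["n_partners"] == 0
    assert math.isnan(b["prop_trans_confidants"])
    assert math.isnan(b["prop_partners_exchange_sex"])
    assert b["n_hiv_pos_confidants"] == 0
    assert b["exchange_sex"] is None


def test_all_missing_hiv_statuses_flagged_undefined():
    conf = [("c1", {"alter_hiv": "unknown"}), ("c2", {"alter_hiv": "unknown"})]
    ds = toy_dataset({"A": {1: {"confidant": conf}}})
    comp = ego_composition(ds, wave=1).set_index("ego_id")
    assert comp.loc["A", "n_hiv_pos_confidants"] == 0
    assert math.isnan(comp.loc["A", "prop_hiv_pos_confidants"])
    assert comp.loc["A", "denom_hiv_confidants"] == 0


def test_welch_identical_samples():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.estimate == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_welch_against_closed_form():
    """Independent recomputation of the Welch statistic and df."""
    a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    res = welch_t_test(a, b)
    assert res.p_value == pytest.approx(p, abs=1e-6)
    assert res.estimate == pytest.approx(a.mean() - b.mean())
    assert res.ci_low < res.estimate < res.ci_high


def test_welch_is_symmetric_in_its_arguments():
    a = [1.0, 4.0, 2.5, 3.0]
    b = [2.0, 6.0, 5.0, 8.0, 4.0]
    r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
    assert r1.estimate == pytest.approx(-r2.estimate)


def test_welch_null_rejection_rate_calibrated():
    """Type-I error of the Welch test near 0.05 under a simulated null."""
    rng = np.random.default_rng(0)
    n_reps, rejections = 1000, 0
    for _ in range(n_reps):
        a, b = rng.normal(size=25), rng.normal(size=40)
        if welch_t_test(a, b).p_value <= 0.05:
            rejections += 1
    rate = rejections / n_reps
    se = math.sqrt(0.05 * 0.95 / n_reps)
    assert abs(rate - 0.05) < 3 * se


def test_cross_product_oracle():
    res = haldane_or(10, 10, 5, 20)
    assert res.estimate == pytest.approx((10 * 20) / (10 * 5))
    assert res.flag is None
    assert res.ci_low < 4.0 < res.ci_high


def test_logistic_equals_cross_product_on_2x2():
    """Saturated-model identity: logit OR == cross-product OR to 1e-6."""
    rng = np.random.default_rng(1)
    for _ in range(10):
        a, b, c, d = rng.integers(3, 40, size=4)
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        res = logistic_or(y, x)
        assert res.test == "logit-or"
        assert res.estimate == pytest.approx((a * d) / (b * c), abs=1e-6)


def test_zero_cell_engages_flagged_haldane_fallback():
    x = np.repeat([1, 1, 0, 0], [8, 0, 5, 9])
    y = np.repeat([1, 0, 1, 0], [8, 0, 5, 9])
    res = logistic_or(y, x)
    assert res.flag == "haldane-anscombe"
    assert res.estimate == pytest.approx((8.5 * 9.5) / (0.5 * 5.5))


def test_or_of_complement_is_reciprocal():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, size=120)
    y = (rng.random(size=120) < 0.3 + 0.3 * x).astype(int)
    r_pos = logistic_or(y, x)
    r_neg = logistic_or(1 - y, x)
    assert r_pos.estimate * r_neg.estimate == pytest.approx(1.0, abs=1e-6)


def test_identical_covariate_distribution_gives_null_or():
    ds = toy_dataset(
        {e: {1: {"sexual": [("p", {"alter_exchange_sex": flag})]}}
         for e, flag in [("A", True), ("B", False), ("C", True), ("D", False),
                         ("E", True), ("F", False), ("G", True), ("H", False)]},
        groups={e: ("TGW" if e in "ABCD" else "MSM") for e in "ABCDEFGH"})
    res = unadjusted_or(ds, "exchange_sex")
    assert res.estimate == pytest.approx(1.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-3)


def test_unadjusted_or_direction_framings():
    ds = _composition_fixture()
    with pytest.raises(KeyError):
        unadjusted_or(ds, "no_such_covariate")
    res = unadjusted_or(ds, "n_pref_men", direction="group-on-covariate")
    assert "group-on-covariate" in res.label


def test_printed_share_arithmetic():
    assert percent(47, 618) == 7.6
    assert math.isnan(percent(1, 0))


def test_baseline_percentages_self_consistent(dataset_small):
    table = baseline_table(dataset_small)
    checked = 0
    for row in table.itertuples(index=False):
        if row.test in ("chi2", "fisher") and row.level == "" and row.tgw_value == row.tgw_value:
            assert row.tgw_detail == percent(row.tgw_value, row.denom_tgw)
            assert row.msm_detail == percent(row.msm_value, row.denom_msm)
            checked += 1
    assert checked >= 5


def test_baseline_with_one_empty_group_not_computable():
    ds = toy_dataset({"A": {1: {"confidant": ["a"]}}}, groups={"A": "MSM"})
    ds.respondents["age_years"] = [23.0]
    ds.respondents["insured"] = [True]
    table = baseline_table(ds)
    assert (table[table["variable"] != "Enrolled"]["test"]
            .isin(["not-computable", ""]).all())
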