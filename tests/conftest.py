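import pandas as pd
import pytest

from netpanel.roster import from_simulation, validate_dataset
from netpanel.simulate import ROSTER_COLUMNS, SimulationConfig, simulate_cohort

SMALL_CONFIG = dict(
    population_size=500,
    prop_tgw=0.3,
    n_seeds=10,
    coupons_per_recruit=3,
    target_sample=150,
    n_waves=3,
    mean_confidant_degree=3.0,
    mean_sexual_degree=2.5,
    rng_seed=42,
)


@pytest.fixture(scope="session")
def sim_small():
    return simulate_cohort(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def dataset_small(sim_small):
    ds = from_simulation(sim_small)
    assert not ds.violations
    return ds


_ROSTER_DEFAULTS = {
    "is_primary_partner": False,
    "window": "current",
    "alter_gender": "man",
    "alter_msm": True,
    "alter_hiv": "unknown",
    "alter_exchange_sex": None,
    "alter_received_payment": None,
    "alter_partner_pref": None,
    "also_confidant": None,
}


def toy_dataset(visits, groups=None, auto_match=True, extra_matches=(),
                drop_matches=False):
    """Build a tiny validated dataset from a nested literal description.

    ``visits``: {ego: {wave: {kind: [alter, ...]}}} where each alter is
    a name string or a (name, attribute-overrides) tuple. Every listed
    wave counts as attended. With ``auto_match`` (default) successive
    nominations of the same name by the same ego and kind are linked by
    match records, so names behave as persistent alter identities.
    """
    respondents = []
    rosters = []
    matches = []
    attendance = []
    groups = groups or {}
    for ego, by_wave in visits.items():
        respondents.append({"ego_id": ego, "group": groups.get(ego, "MSM")})
        last_nom = {}
        for wave in sorted(by_wave):
            attendance.append({"ego_id": ego, "wave": wave, "attended": True})
            for kind, alters in by_wave[wave].items():
                for pos, alter in enumerate(alters, start=1):
                    if isinstance(alter, tuple):
                        name, overrides = alter
                    else:
                        name, overrides = alter, {}
                    nom = f"W{wave}-{ego}-{kind[0].upper()}{pos}"
                    row = {"ego_id": ego, "wave": wave, "kind": kind,
                           "nomination_id": nom, "position": pos}
                    row.update(_ROSTER_DEFAULTS)
                    row.update(overrides)
                    rosters.append(row)
                    key = (kind, name)
                    if auto_match and key in last_nom:
                        matches.append({
                            "ego_id": ego, "kind": kind,
                            "nomination_id_earlier": last_nom[key][0],
                            "nomination_id_later": nom,
                            "wave_earlier": last_nom[key][1], "wave_later": wave,
                        })
                    last_nom[key] = (nom, wave)
    match_cols = ["ego_id", "kind", "nomination_id_earlier", "nomination_id_later",
                  "wave_earlier", "wave_later"]
    matches = list(matches) + list(extra_matches)
    return validate_dataset(
        pd.DataFrame(respondents, columns=["ego_id", "group"]),
        pd.DataFrame(rosters, columns=ROSTER_COLUMNS),
        pd.DataFrame(matches if not drop_matches else [], columns=match_cols),
        pd.DataFrame(attendance, columns=["ego_id", "wave", "attended"]),
    )
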