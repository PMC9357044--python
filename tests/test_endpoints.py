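"""Composite CPG3+ endpoint derivation: scenarios, ties, censoring."""

import pytest

from dynsurv import EndpointConfig, assign_entry_cpg, check_cpg3_scenarios, derive_outcome
from .conftest import make_pathway, make_static


@pytest.mark.parametrize("gg,psa,stage,expected", [
    (1, 5.2, "T1", 1),
    (2, 6.0, "T2", 2),
    (1, 12.0, "T2", 2),
    (1, 9.99, "T2", 1),
    (2, 19.0, "T1", 2),
])
def test_entry_cpg_assignment(gg, psa, stage, expected):
    static = make_static(grade_group=gg, psa_baseline=psa, mri_stage=stage)
    assert assign_entry_cpg(static) == expected


@pytest.mark.parametrize("gg,psa,stage", [(3, 5.0, "T1"), (1, 25.0, "T1"),
                                          (1, 5.0, "T3")])
def test_entry_cpg_rejects_ineligible(gg, psa, stage):
    with pytest.raises(ValueError, match="not AS-eligible"):
        assign_entry_cpg(make_static(grade_group=gg, psa_baseline=psa,
                                     mri_stage=stage))


@pytest.mark.parametrize("state,expected", [
    ({"gg": 3, "psa": 4.0, "stage": "T2"}, "i"),
    ({"gg": 2, "psa": 11.0, "stage": "T2"}, "ii"),
    ({"gg": 1, "psa": 5.0, "stage": "T3"}, "iii"),
    ({"gg": 1, "psa": 21.0, "stage": "T2"}, "iv"),
    ({"gg": 1, "psa": 9.0, "stage": "T2"}, "none"),
    # precedence: several scenarios on the same state -> lowest numeral
    ({"gg": 3, "psa": 25.0, "stage": "T3"}, "i"),
    ({"gg": 2, "psa": 21.0, "stage": "T3"}, "ii"),
    # boundaries are inclusive
    ({"gg": 2, "psa": 10.0, "stage": "T2"}, "ii"),
    ({"gg": 1, "psa": 20.0, "stage": "T2"}, "iv"),
])
def test_scenario_checks(state, expected):
    assert check_cpg3_scenarios(state, EndpointConfig()) == expected


def endpoint_fixture_set():
    """12 hand-constructed pathways with hand-derived outcomes.

    Covers all four progression scenarios, same-day ties, first-crossing
    precedence, boundary values and the three censoring reasons.
    """
    gg1 = make_static(grade_group=1, psa_baseline=5.0)
    gg2 = make_static(grade_group=2, psa_baseline=6.0, mri_stage="T2")
    cases = []

    # 1. re-biopsy upgrade to GG3
    cases.append((make_pathway("E1", gg1, [dict(t=200, psa=5.5),
                                           dict(t=400, biopsy_grade_group=3)]),
                  dict(last_investigation_day=900),
                  (True, 400, "i", "none")))
    # 2. GG2 at entry, PSA crosses 10 at day 800
    cases.append((make_pathway("E2", gg2, [dict(t=300, psa=8.0),
                                           dict(t=800, psa=10.2)]),
                  dict(last_investigation_day=1200),
                  (True, 800, "ii", "none")))
    # 3. MRI progression to T3
    cases.append((make_pathway("E3", gg1, [dict(t=650, mri_stage="T3")]),
                  dict(last_investigation_day=700),
                  (True, 650, "iii", "none")))
    # 4. PSA rise to >= 20
    cases.append((make_pathway("E4", gg1, [dict(t=250, psa=15.0),
                                           dict(t=500, psa=20.5)]),
                  dict(last_investigation_day=600),
                  (True, 500, "iv", "none")))
    # 5. same-day tie: biopsy GG3 and PSA 21 -> scenario i wins
    cases.append((make_pathway("E5", gg1, [dict(t=600, psa=21.0,
                                                biopsy_grade_group=3)]),
                  dict(last_investigation_day=900),
                  (True, 600, "i", "none")))
    # 6. same-day tie: GG2 state, PSA 11 and stage T3 -> ii over iii
    cases.append((make_pathway("E6", gg2, [dict(t=700, psa=11.0,
                                                mri_stage="T3")]),
                  dict(last_investigation_day=900),
                  (True, 700, "ii", "none")))
    # 7. first crossing wins: GG3 at 1150 before PSA 20.5 at 1300
    cases.append((make_pathway("E7", gg1, [dict(t=1150, biopsy_grade_group=3),
                                           dict(t=1300, psa=20.5)]),
                  dict(last_investigation_day=1400),
                  (True, 1150, "i", "none")))
    # 8. boundary: PSA exactly 20 fires scenario iv (19.9 does not)
    cases.append((make_pathway("E8", gg1, [dict(t=300, psa=19.9),
                                           dict(t=450, psa=20.0)]),
                  dict(last_investigation_day=600),
                  (True, 450, "iv", "none")))
    # 9. LOCF: benign upgrade to GG2 at 400, PSA 10.5 at 900 -> ii at 900
    cases.append((make_pathway("E9", gg1, [dict(t=400, biopsy_grade_group=2),
                                           dict(t=900, psa=10.5)]),
                  dict(last_investigation_day=1000),
                  (True, 900, "ii", "none")))
    # 10. no progression: treatment before last investigation
    cases.append((make_pathway("E10", gg1, [dict(t=300, psa=6.0)]),
                  dict(treatment_day=900, last_investigation_day=1200),
                  (False, 900, "none", "treatment")))
    # 11. no progression: death earliest
    cases.append((make_pathway("E11", gg2, [dict(t=300, psa=7.0)]),
                  dict(treatment_day=1100, death_day=700,
                       last_investigation_day=1300),
                  (False, 700, "none", "death")))
    # 12. no progression: censored at latest investigation
    cases.append((make_pathway("E12", gg1, [dict(t=300, psa=6.5),
                                            dict(t=1200, psa=7.0)]),
                  dict(last_investigation_day=1200),
                  (False, 1200, "none", "last_investigation")))
    return cases


@pytest.mark.parametrize("pathway,admin,expected", [
    pytest.param(*c, id=c[0].patient_id) for c in endpoint_fixture_set()])
def test_hand_derived_outcomes(pathway, admin, expected):
    out = derive_outcome(pathway, EndpointConfig(), **admin)
    assert (out.event, out.time, out.cause_scenario, out.censor_reason) == expected


def test_cannot_censor_without_administrative_days():
    p = make_pathway("X", obs=[dict(t=100, psa=5.0)])
    with pytest.raises(ValueError, match="cannot censor"):
        derive_outcome(p, EndpointConfig())


def test_outcome_time_monotone_in_thresholds():
    """Raising any endpoint threshold never produces an earlier event."""
    import numpy as np
    rng = np.random.default_rng(4)
    base = EndpointConfig()
    for _ in range(30):
        obs = []
        for t in sorted(rng.choice(np.arange(100, 2000, 50), 6, replace=False)):
            obs.append(dict(t=int(t),
                            psa=float(rng.uniform(3, 25)),
                            biopsy_grade_group=(int(rng.integers(1, 4))
                                                if rng.uniform() < 0.3 else None)))
        p = make_pathway("M", make_static(grade_group=int(rng.integers(1, 3))),
                         obs)
        out0 = derive_outcome(p, base, last_investigation_day=2100)
        raised = EndpointConfig(psa_gg2_threshold=12.0,
                                psa_absolute_threshold=24.0,
                                gg_upgrade_threshold=4)
        out1 = derive_outcome(p, raised, last_investigation_day=2100)
        assert out1.time >= out0.time


def test_cotemporal_null_permutation_invariance():
    """Null fields in a same-day observation never change the outcome."""
    from dynsurv import Observation
    p1 = make_pathway("A", make_static(grade_group=2),
                      [dict(t=500, psa=10.4, precise=None)])
    p2 = make_pathway("A", make_static(grade_group=2),
                      [Observation(t=500, psa=10.4, precise=3)])
    o1 = derive_outcome(p1, last_investigation_day=800)
    o2 = derive_outcome(p2, last_investigation_day=800)
    assert (o1.event, o1.time, o1.cause_scenario) == (o2.event, o2.time,
                                                      o2.cause_scenario)
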