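"""Composite progression endpoint (CPG3+) and censoring derivation.

Progression out of active surveillance is reached through four scenarios,
evaluated on the latest known (last-observation-carried-forward) state:

  i)   re-biopsy upgrade to grade group >= 3
  ii)  grade group 2 disease with PSA >= 10 ng/mL
  iii) progression to stage >= T3
  iv)  PSA rise to >= 20 ng/mL

Patients who never qualify are censored at the earliest of treatment,
death, or last investigation.  When several scenarios fire on the same
day the lowest-numbered one is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import ClinicalPathway, Outcome, StaticProfile

_STAGE_ORDER = {"T1": 1, "T2": 2, "T3": 3}


@dataclass
class EndpointConfig:
    psa_gg2_threshold: float = 10.0  # ng/mL, scenario ii
    psa_absolute_threshold: float = 20.0  # ng/mL, scenario iv
    gg_upgrade_threshold: int = 3  # grade group, scenario i
    stage_threshold: str = "T3"  # scenario iii

    def __post_init__(self):
        if self.psa_gg2_threshold <= 0 or self.psa_absolute_threshold <= 0:
            raise ValueError("PSA thresholds must be positive")
        if not 2 <= self.gg_upgrade_threshold <= 5:
            raise ValueError("gg_upgrade_threshold must be in 2..5")


def assign_entry_cpg(static: StaticProfile) -> int:
    """Entry Cambridge Prognostic Group (1 or 2) from the baseline profile.

    CPG1 = grade group 1, PSA < 10 and stage <= T2; everything else that
    still meets the surveillance entry criteria is CPG2.
    """
    gg, psa, stage = static.grade_group, static.psa_baseline, static.mri_stage
    if gg not in (1, 2) or psa >= 20 or _STAGE_ORDER.get(stage, 3) >= 3:
        raise ValueError(
            f"not AS-eligible: grade_group={gg}, psa={psa}, stage={stage}")
    if gg == 1 and psa < 10:
        return 1
    return 2


def check_cpg3_scenarios(state: dict, cfg: Optional[EndpointConfig] = None) -> str:
    """Return the lowest-numbered progression scenario satisfied by ``state``.

    ``state`` holds the LOCF-resolved latest values {gg, psa, stage}; the
    return value is one of "i", "ii", "iii", "iv", "none".
    """
    cfg = cfg or EndpointConfig()
    gg = state.get("gg")
    psa = state.get("psa")
    stage = state.get("stage")
    if gg is not None and gg >= cfg.gg_upgrade_threshold:
        return "i"
    if gg == 2 and psa is not None and psa >= cfg.psa_gg2_threshold:
        return "ii"
    if stage is not None and _STAGE_ORDER.get(stage, 0) >= _STAGE_ORDER[cfg.stage_threshold]:
        return "iii"
    if psa is not None and psa >= cfg.psa_absolute_threshold:
        return "iv"
    return "none"


def derive_outcome(pathway: ClinicalPathway,
                   cfg: Optional[EndpointConfig] = None,
                   treatment_day: Optional[int] = None,
                   death_day: Optional[int] = None,
                   last_investigation_day: Optional[int] = None) -> Outcome:
    """Scan a pathway in time order and derive its event/censoring outcome.

    The event day is the day of the first qualifying observation; if no
    scenario ever fires, the patient is censored at the earliest provided
    administrative day.
    """
    if not pathway.observations and pathway.static is None:
        raise ValueError("pathway has no observations")
    cfg = cfg or EndpointConfig()

    state = {
        "gg": pathway.static.grade_group,
        "psa": pathway.static.psa_baseline,
        "stage": pathway.static.mri_stage,
    }
    for obs in pathway.observations:
        if obs.biopsy_grade_group is not None:
            state["gg"] = obs.biopsy_grade_group
        if obs.psa is not None:
            state["psa"] = obs.psa
        if obs.mri_stage is not None:
            state["stage"] = obs.mri_stage
        scenario = check_cpg3_scenarios(state, cfg)
        if scenario != "none":
            return Outcome(event=True, time=int(obs.t), cause_scenario=scenario)

    admin = [(treatment_day, "treatment"), (death_day, "death"),
             (last_investigation_day, "last_investigation")]
    admin = [(d, reason) for d, reason in admin if d is not None]
    if not admin:
        raise ValueError("cannot censor: no scenario fired and no administrative day given")
    day, reason = min(admin, key=lambda x: (x[0], _CENSOR_PRIORITY[x[1]]))
    return Outcome(event=False, time=int(day), censor_reason=reason)


_CENSOR_PRIORITY = {"treatment": 0, "death": 1, "last_investigation": 2}


def derive_outcomes(cohort, cfg: Optional[EndpointConfig] = None,
                    admin: Optional[dict] = None) -> None:
    """Derive outcomes in place for every pathway of a cohort.

    ``admin`` maps patient_id -> dict with optional keys treatment_day,
    death_day, last_investigation_day; when absent, the last observation
    day is used as the last investigation.
    """
    for p in cohort.pathways:
        a = (admin or {}).get(p.patient_id, {})
        last = a.get("last_investigation_day")
        if last is None and p.observations:
            last = p.observations[-1].t
        p.outcome = derive_outcome(
            p, cfg,
            treatment_day=a.get("treatment_day"),
            death_day=a.get("death_day"),
            last_investigation_day=last,
        )
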