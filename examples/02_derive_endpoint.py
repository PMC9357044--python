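"""Derive the composite CPG3+ endpoint for a hand-built clinical pathway.

A grade group 2 patient whose PSA crosses 10 ng/mL reaches the endpoint
through scenario (ii); without that crossing he is censored at the
earliest administrative date.
"""

from dynsurv import (ClinicalPathway, EndpointConfig, Observation,
                     StaticProfile, assign_entry_cpg, derive_outcome)

static = StaticProfile(age_at_entry=66.0, family_history=False,
                       ethnicity="white", grade_group=2, mri_stage="T2",
                       likert=3, psa_baseline=6.0, prostate_volume=48.0,
                       psa_density=0.125, core_positivity=0.2)
print("entry Cambridge Prognostic Group:", assign_entry_cpg(static))

pathway = ClinicalPathway(
    patient_id="demo", static=static,
    observations=[Observation(t=160, psa=7.1),
                  Observation(t=320, psa=8.4, precise=3),
                  Observation(t=520, psa=10.3)])
out = derive_outcome(pathway, EndpointConfig(), last_investigation_day=900)
print(f"event={out.event} at day {out.time}, scenario {out.cause_scenario}")

# remove the qualifying reading: the patient is censored instead
pathway.observations[-1].psa = 9.2
out2 = derive_outcome(pathway, EndpointConfig(), treatment_day=800,
                      last_investigation_day=900)
print(f"event={out2.event} at day {out2.time}, censored for: {out2.censor_reason}")
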