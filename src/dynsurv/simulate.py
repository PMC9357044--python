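"""Synthetic active-surveillance cohort generator with known ground truth.

Emulates the structure of a real surveillance cohort: static entry
marginals (grade group, Cambridge Prognostic Group, MRI stage, Likert),
irregular PSA visits (~150-day intervals), sparser MRI (~650 days) and
protocol biopsies (~1 and ~3 years), and Weibull progression to the
composite CPG3+ endpoint with right censoring by treatment, death or
the end of follow-up.

Each patient carries a latent risk stratum.  The true event time is
Weibull with a per-patient scale that decreases with the stratum, entry
grade group 2, PSA density and stage; longitudinal markers (PSA slope,
biopsy upgrades, PRECISE drift) reveal the stratum progressively, so
models that use follow-up data gain predictive power over baseline-only
models.  Progression becomes observable at monitoring visits only: a
per-patient detection route decides whether the first qualifying
reading arrives through PSA, re-biopsy or MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import ClinicalPathway, Cohort, Observation, StaticProfile
from .endpoints import EndpointConfig, assign_entry_cpg, check_cpg3_scenarios, derive_outcome
from .weibull import conditional_risk


@dataclass
class SimConfig:
    n_patients: int = 600
    seed: int = 0
    # visit cadence (days)
    visit_interval_mean: float = 150.0
    visit_interval_sd: float = 30.0
    mri_interval_mean: float = 650.0
    mri_interval_sd: float = 120.0
    biopsy_schedule: tuple = (365, 1095)
    biopsy_jitter: float = 60.0
    # static marginals
    p_grade_group2: float = 0.201
    p_psa_high_gg1: float = 0.149  # P(10 <= PSA < 20 | GG1) -> CPG1 = 68.0%
    p_mri_t1: float = 0.269
    likert_probs: tuple = (0.434, 0.062, 0.157, 0.198, 0.149)
    p_family_history: float = 0.135
    p_white: float = 0.952
    p_likert_missing: float = 0.10
    age_mean: float = 65.7
    age_sd: float = 7.4
    volume_meanlog: float = np.log(52.0)
    volume_sdlog: float = 0.45
    # PSA process (log scale)
    psa0_meanlog: float = np.log(5.5)
    psa0_sdlog: float = 0.4
    psa_obs_sdlog: float = 0.08
    psa_slope_base: float = 0.03  # per year on log PSA
    psa_slope_stratum: float = 0.25  # extra slope for the top stratum
    psa_slope_sd: float = 0.02
    # PRECISE ordinal drift
    precise_init: tuple = (0.01, 0.08, 0.80, 0.11, 0.0)
    p_precise_up_stratum: float = 0.25  # P(step up per MRI) for top stratum
    # optional stratum-specific PRECISE target levels (planted mode): each
    # MRI moves the score one step toward target[stratum] with prob 0.9
    precise_stratum_targets: Optional[tuple] = None
    # biopsy
    cores_total_mean: float = 18.0
    p_corepos_stratum: float = 0.06  # stratum link of per-core positivity
    p_upgrade_base: float = 0.03  # benign GG1 -> GG2 per biopsy
    p_upgrade_stratum: float = 0.20
    # event truth
    weibull_shape: float = 1.6
    log_scale0: float = np.log(12000.0)  # days; gives ~17% observed events
    stratum_separation: float = 1.2  # spread of log-scale across strata
    beta_gg2: float = 0.6
    beta_psad: float = 0.3
    beta_stage_t2: float = 0.2
    n_latent_strata: int = 3
    stratum_probs: Optional[tuple] = None  # default: uniform
    detect_route_probs: tuple = (0.41, 0.39, 0.20)  # psa, biopsy, mri
    # censoring
    admin_horizon: float = 3650.0
    # staggered end-of-follow-up profile: survival of the administrative
    # horizon at 3, 5 and 10 years (matches the cohort's observed funnel)
    admin_profile: tuple = ((1095.0, 0.65), (1825.0, 0.44), (3650.0, 0.10))
    treatment_rate: float = 0.020  # per year
    death_rate: float = 0.010  # per year

    def __post_init__(self):
        if self.n_latent_strata < 1:
            raise ValueError("n_latent_strata must be >= 1")
        if abs(sum(self.likert_probs) - 1.0) > 1e-9:
            raise ValueError("likert_probs must sum to 1")
        probs = self.stratum_probs
        if probs is not None and abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("stratum_probs must sum to 1")


@dataclass
class PatientTruth:
    stratum: int
    shape: float
    scale: float  # true per-patient Weibull scale (days)
    event_time: float  # latent progression time before censoring
    route: str


@dataclass
class GroundTruth:
    patients: dict = field(default_factory=dict)  # patient_id -> PatientTruth
    config: Optional[SimConfig] = None

    def risk(self, patient_id: str, as_of: float, horizon: float) -> float:
        return truth_risk(self, patient_id, as_of, horizon)


def truth_risk(gt: GroundTruth, patient_id: str, as_of: float,
               horizon: float) -> float:
    """The simulator's exact conditional event probability."""
    pt = gt.patients[patient_id]
    return float(conditional_risk(pt.shape, pt.scale, as_of, [horizon])[0])


def _sample_admin_day(rng: np.random.Generator, horizon: float,
                      profile) -> float:
    """Staggered end of follow-up via a piecewise-exponential profile."""
    u = rng.uniform()
    t0, s0 = 365.0, 1.0
    for t1, s1 in profile:
        if u > s1:
            frac = (np.log(s0) - np.log(u)) / (np.log(s0) - np.log(s1))
            return min(t0 + frac * (t1 - t0), horizon)
        t0, s0 = t1, s1
    return min(t0, horizon)


def _true_scale(cfg: SimConfig, stratum: int, gg2: bool, psad: float,
                stage_t2: bool) -> float:
    z = stratum / max(cfg.n_latent_strata - 1, 1)
    psad_std = np.clip((psad - 0.15) / 0.08, -2.0, 4.0)
    log_lam = (cfg.log_scale0 - cfg.stratum_separation * z
               - cfg.beta_gg2 * float(gg2) - cfg.beta_psad * psad_std
               - cfg.beta_stage_t2 * float(stage_t2))
    return float(np.exp(log_lam))


def generate_cohort(cfg: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Sample a cohort and its ground truth; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_latent_strata
    strat_probs = (np.asarray(cfg.stratum_probs) if cfg.stratum_probs
                   else np.full(K, 1.0 / K))
    pathways = []
    gt = GroundTruth(config=cfg)
    endpoint_cfg = EndpointConfig()

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        stratum = int(rng.choice(K, p=strat_probs))
        gg = 2 if rng.uniform() < cfg.p_grade_group2 else 1
        if gg == 1 and rng.uniform() < cfg.p_psa_high_gg1:
            psa0 = rng.uniform(10.0, 19.0)
        else:
            # lognormal body truncated below 10 ng/mL
            psa0 = float(np.exp(rng.normal(cfg.psa0_meanlog, cfg.psa0_sdlog)))
            while psa0 >= 10.0:
                psa0 = float(np.exp(rng.normal(cfg.psa0_meanlog, cfg.psa0_sdlog)))
        stage = "T1" if rng.uniform() < cfg.p_mri_t1 else "T2"
        likert = int(rng.choice(5, p=np.asarray(cfg.likert_probs)) + 1)
        vol = float(np.exp(rng.normal(cfg.volume_meanlog, cfg.volume_sdlog)))
        psad = psa0 / vol
        cores_total0 = max(6, int(rng.poisson(cfg.cores_total_mean)))
        # the latent stratum is a *future-trajectory* construct: diagnostic
        # cores reflect only the entry grade, while follow-up biopsies
        # progressively reveal the stratum (p_pos below)
        p_pos0 = 0.08 + 0.12 * (gg - 1)
        p_pos = p_pos0 + cfg.p_corepos_stratum * stratum / max(K - 1, 1)
        cores_pos0 = int(rng.binomial(cores_total0, p_pos0))
        static = StaticProfile(
            age_at_entry=float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 45, 85)),
            family_history=bool(rng.uniform() < cfg.p_family_history),
            ethnicity="white" if rng.uniform() < cfg.p_white else "other",
            grade_group=gg, mri_stage=stage,
            likert=None if rng.uniform() < cfg.p_likert_missing else likert,
            psa_baseline=round(psa0, 2), prostate_volume=round(vol, 1),
            psa_density=None, core_positivity=round(cores_pos0 / cores_total0, 4),
        )
        static.psa_density = static.psa_baseline / static.prostate_volume
        static.entry_cpg = assign_entry_cpg(static)

        lam = _true_scale(cfg, stratum, gg == 2, psad, stage == "T2")
        t_star = float(lam * rng.weibull(cfg.weibull_shape))
        route = str(rng.choice(["psa", "biopsy", "mri"],
                               p=np.asarray(cfg.detect_route_probs)))
        gt.patients[pid] = PatientTruth(stratum=stratum, shape=cfg.weibull_shape,
                                        scale=lam, event_time=t_star, route=route)

        # censoring draws
        admin = _sample_admin_day(rng, cfg.admin_horizon, cfg.admin_profile)
        t_treat = (max(30.0, rng.exponential(1.0 / cfg.treatment_rate) * 365.0)
                   if cfg.treatment_rate > 0 else np.inf)
        t_death = (max(30.0, rng.exponential(1.0 / cfg.death_rate) * 365.0)
                   if cfg.death_rate > 0 else np.inf)
        end_admin = min(admin, t_treat, t_death)

        # visit schedules
        z = stratum / max(K - 1, 1)
        slope = (cfg.psa_slope_base + cfg.psa_slope_stratum * z
                 + rng.normal(0.0, cfg.psa_slope_sd))
        psa_days, t = [], 0.0
        while True:
            t += max(30.0, rng.normal(cfg.visit_interval_mean, cfg.visit_interval_sd))
            if t > cfg.admin_horizon:
                break
            psa_days.append(round(t))
        mri_days, t = [], 0.0
        while True:
            t += max(90.0, rng.normal(cfg.mri_interval_mean, cfg.mri_interval_sd))
            if t > cfg.admin_horizon:
                break
            mri_days.append(round(t))
        biopsy_days = sorted(
            round(max(90.0, b + rng.normal(0.0, cfg.biopsy_jitter)))
            for b in cfg.biopsy_schedule)

        events = ([(d, "psa") for d in psa_days] + [(d, "mri") for d in mri_days]
                  + [(d, "biopsy") for d in biopsy_days])
        events.sort()

        precise = int(rng.choice(5, p=np.asarray(cfg.precise_init)) + 1)
        cur_gg = gg
        observations = []
        state = {"gg": gg, "psa": psa0, "stage": stage}
        for day, kind in events:
            if day >= end_admin:
                break
            progressed = day >= t_star
            obs = Observation(t=int(day))
            if kind == "psa":
                log_psa = (np.log(psa0) + slope * day / 365.0
                           + rng.normal(0.0, cfg.psa_obs_sdlog))
                psa = float(np.exp(log_psa))
                thresh = 10.0 if cur_gg == 2 else 20.0
                if progressed:
                    if route == "psa":
                        psa = max(psa, thresh * (1.02 + abs(rng.normal(0, 0.1))))
                    else:
                        # backup drift: PSA deteriorates after true progression
                        psa = psa * float(np.exp(1.0 * (day - t_star) / 365.0))
                else:
                    # progression-free by definition: the endpoint has not
                    # been crossed, so organic drift stays sub-threshold
                    psa = min(psa, 0.95 * thresh)
                obs.psa = round(psa, 2)
                obs.psa_density = round(psa, 2) / vol
            elif kind == "mri":
                vol_t = vol * float(np.exp(rng.normal(0.0, 0.03)))
                obs.prostate_volume = round(vol_t, 1)
                if cfg.precise_stratum_targets is not None:
                    target = int(cfg.precise_stratum_targets[
                        min(stratum, len(cfg.precise_stratum_targets) - 1)])
                    if progressed:
                        target = 5
                    if rng.uniform() < 0.9 and precise != target:
                        precise += 1 if target > precise else -1
                else:
                    p_up = cfg.p_precise_up_stratum * z + (0.3 if progressed else 0.0)
                    if rng.uniform() < p_up:
                        precise = min(5, precise + 1)
                    elif rng.uniform() < 0.05:
                        precise = max(1, precise - 1)
                obs.precise = precise
                if progressed and route == "mri":
                    obs.mri_stage = "T3"
                else:
                    obs.mri_stage = stage
            else:  # biopsy
                ct = max(6, int(rng.poisson(cfg.cores_total_mean)))
                if progressed:
                    cur_gg = 3 + int(rng.uniform() < 0.2)
                elif (cur_gg == 1 and state["psa"] < 9.5
                        and rng.uniform() < (cfg.p_upgrade_base
                                             + cfg.p_upgrade_stratum * z)):
                    # benign GG1 -> GG2 upgrade; restricted to sub-threshold
                    # PSA so that it cannot itself constitute the endpoint
                    cur_gg = 2
                obs.biopsy_grade_group = cur_gg
                obs.cores_total = ct
                obs.cores_positive = int(rng.binomial(
                    ct, min(0.9, p_pos + (0.25 if progressed else 0.0))))
            if observations and observations[-1].t == obs.t:
                # co-scheduled visits on the same day merge into one row
                prev = observations[-1]
                for f in ("psa", "psa_density", "prostate_volume", "precise",
                          "biopsy_grade_group", "cores_total",
                          "cores_positive", "mri_stage"):
                    v = getattr(obs, f)
                    if v is not None:
                        setattr(prev, f, v)
                obs = prev
            else:
                observations.append(obs)
            # stop at first qualifying observation (the event is detected)
            if obs.biopsy_grade_group is not None:
                state["gg"] = obs.biopsy_grade_group
            if obs.psa is not None:
                state["psa"] = obs.psa
            if obs.mri_stage is not None:
                state["stage"] = obs.mri_stage
            if check_cpg3_scenarios(state, endpoint_cfg) != "none":
                break

        pathway = ClinicalPathway(patient_id=pid, static=static,
                                  observations=observations)
        # the latest investigation is the last visit when follow-up simply
        # ended; when treatment/death stopped emission, censoring falls on
        # that administrative date instead (the min rule below picks it)
        admin_ended = end_admin == admin
        if observations and admin_ended:
            last_inv = observations[-1].t
        else:
            last_inv = max(1, int(admin))
        pathway.outcome = derive_outcome(
            pathway, endpoint_cfg,
            treatment_day=int(t_treat) if np.isfinite(t_treat) else None,
            death_day=int(t_death) if np.isfinite(t_death) else None,
            last_investigation_day=int(last_inv),
        )
        pathways.append(pathway)

    cohort = Cohort(pathways=pathways, provenance={"simulator_seed": cfg.seed})
    return cohort, gt


def generate_planted_clusters(cfg: SimConfig,
                              separation: float = 2.2) -> tuple[Cohort, GroundTruth]:
    """Cohort with K well-separated latent risk strata for cluster tests."""
    import dataclasses
    if cfg.n_latent_strata < 2:
        raise ValueError("planted-cluster mode needs n_latent_strata >= 2")
    # the hazard depends on the planted stratum alone (pure planted-cluster
    # design: baseline covariate effects are switched off), and follow-up
    # markers are made markedly less noisy than the realistic defaults so
    # the stratum is identifiable from the first year of follow-up
    # exponential (shape 1) progression makes the conditional risk curve
    # memoryless, so a patient's cluster identity is a function of the
    # latent stratum alone rather than of follow-up time; slopes are kept
    # gentle enough that the sub-threshold clamp rarely binds (preserving
    # the slope readout) and progression is slow enough that histories
    # reveal the stratum before the event is detected
    cfg = dataclasses.replace(cfg, stratum_separation=separation,
                              weibull_shape=1.0,
                              log_scale0=float(np.log(25000.0)),
                              beta_gg2=0.0, beta_psad=0.0, beta_stage_t2=0.0,
                              psa0_meanlog=float(np.log(3.0)),
                              psa0_sdlog=0.3,
                              p_psa_high_gg1=0.0,
                              psa_slope_base=0.0,
                              psa_slope_stratum=0.25,
                              psa_obs_sdlog=0.015,
                              psa_slope_sd=0.003,
                              p_precise_up_stratum=0.65,
                              precise_stratum_targets=(2, 3, 4, 5),
                              mri_interval_mean=380.0,
                              mri_interval_sd=40.0,
                              p_corepos_stratum=0.55,
                              p_upgrade_stratum=0.35,
                              detect_route_probs=(1.0, 0.0, 0.0),
                              admin_profile=((1095.0, 0.90),
                                             (1825.0, 0.70),
                                             (3650.0, 0.15)))
    if separation < 0.5:
        import warnings
        warnings.warn("small separation: strata may overlap entirely",
                      stacklevel=2)
    return generate_cohort(cfg)


def analytic_event_probability(gt: GroundTruth, n_grid: int = 400) -> float:
    """Mean probability that the latent progression precedes censoring.

    Integrates the true Weibull density against the treatment/death
    exponential censoring survival up to each patient's administrative
    horizon distribution (marginalized numerically).  Detection delay at
    visit cadence is ignored, so the cohort's derived event fraction sits
    slightly below this value.
    """
    cfg = gt.config
    rate = (cfg.treatment_rate + cfg.death_rate) / 365.0  # per day
    # marginal survival of the administrative horizon
    def admin_surv(t):
        pts = [(365.0, 1.0)] + [(d, s) for d, s in cfg.admin_profile]
        t = np.asarray(t, dtype=float)
        out = np.ones_like(t)
        lo_t, lo_s = 0.0, 1.0
        for hi_t, hi_s in pts:
            seg = (t > lo_t) & (t <= hi_t)
            if lo_s > 0 and hi_s > 0 and hi_t > lo_t:
                frac = (t - lo_t) / (hi_t - lo_t)
                out = np.where(seg, np.exp(np.log(lo_s) + frac
                                           * (np.log(hi_s) - np.log(lo_s))), out)
            lo_t, lo_s = hi_t, hi_s
        out = np.where(t > pts[-1][0], 0.0, out)
        return out

    ts = np.linspace(1.0, cfg.admin_horizon, n_grid)
    total = 0.0
    for pt in gt.patients.values():
        k, lam = pt.shape, pt.scale
        dens = (k / lam) * (ts / lam) ** (k - 1) * np.exp(-(ts / lam) ** k)
        integrand = dens * np.exp(-rate * ts) * admin_surv(ts)
        total += float(np.trapezoid(integrand, ts))
    return total / len(gt.patients)
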