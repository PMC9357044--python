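"""Imputation, feature encoding and model-ready sequence construction.

Static missing values are imputed with the training-cohort mode
(categorical) or mean (continuous); longitudinal missing values are
carried forward from the last observation, with leading gaps backfilled
from the baseline analogue where one exists and from the cohort
mode/mean otherwise.

Each patient history becomes a :class:`SequenceTensor`: step 0 is the
diagnostic observation, subsequent steps are follow-up visits up to an
"as-of" day.  Continuous features are standardized with statistics
frozen from the training split; ordinal/categorical features are
one-hot encoded; static features are repeated on every step.  A
missingness mask (one channel per time-varying feature) and the
inter-visit gap delta_t (days/365) are carried alongside.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import ClinicalPathway, Cohort, Observation

CONTINUOUS = ["psa", "psa_density", "volume", "core_positivity", "age"]
# right-skewed positive markers enter the model on the log scale
LOG_SCALE = {"psa", "psa_density", "volume"}
ONEHOT_LEVELS = {
    "grade_group": [1, 2, 3, 4, 5],
    "precise": [1, 2, 3, 4, 5],
    "likert": [1, 2, 3, 4, 5],
    "mri_stage": ["T1", "T2", "T3"],
}
BINARY = ["family_history"]
TIME_VARYING = ["psa", "psa_density", "volume", "core_positivity",
                "precise", "grade_group", "mri_stage"]
# time-varying features with a baseline analogue for leading-gap backfill
BASELINE_ANALOGUE = {"psa", "psa_density", "volume", "grade_group", "mri_stage"}


def feature_names() -> list[str]:
    names = list(CONTINUOUS)
    for feat, levels in ONEHOT_LEVELS.items():
        names += [f"{feat}={lv}" for lv in levels]
    names += BINARY
    return names


N_FEATURES = len(feature_names())
N_MASK = len(TIME_VARYING)


@dataclass
class FeatureSchema:
    """Frozen per-feature statistics from a training cohort."""

    cont_mean: dict = field(default_factory=dict)
    cont_sd: dict = field(default_factory=dict)
    modes: dict = field(default_factory=dict)  # categorical/ordinal modes
    baseline_means: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"cont_mean": self.cont_mean, "cont_sd": self.cont_sd,
                       "modes": self.modes,
                       "baseline_means": self.baseline_means}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def standardize(self, name: str, value: float) -> float:
        if name in LOG_SCALE:
            value = math.log(max(value, 1e-6))
        return (value - self.cont_mean[name]) / self.cont_sd[name]


def _observed_values(cohort: Cohort):
    """Collect observed (pre-imputation) values per feature."""
    vals = {c: [] for c in CONTINUOUS}
    cats = {k: [] for k in ONEHOT_LEVELS}
    for p in cohort.pathways:
        s = p.static
        vals["age"].append(s.age_at_entry)
        vals["psa"].append(s.psa_baseline)
        for name, v in (("volume", s.prostate_volume),
                        ("psa_density", s.psa_density),
                        ("core_positivity", s.core_positivity)):
            if v is not None:
                vals[name].append(v)
        cats["grade_group"].append(s.grade_group)
        cats["mri_stage"].append(s.mri_stage)
        if s.likert is not None:
            cats["likert"].append(s.likert)
        for o in p.observations:
            for name, v in (("psa", o.psa), ("psa_density", o.psa_density),
                            ("volume", o.prostate_volume)):
                if v is not None:
                    vals[name].append(v)
            if o.cores_total and o.cores_positive is not None:
                vals["core_positivity"].append(o.cores_positive / o.cores_total)
            if o.precise is not None:
                cats["precise"].append(o.precise)
            if o.biopsy_grade_group is not None:
                cats["grade_group"].append(o.biopsy_grade_group)
            if o.mri_stage is not None:
                cats["mri_stage"].append(o.mri_stage)
    return vals, cats


def fit_schema(cohort: Cohort) -> FeatureSchema:
    """Compute imputation and standardization statistics from a cohort."""
    vals, cats = _observed_values(cohort)
    schema = FeatureSchema()
    for name, v in vals.items():
        if not v:
            raise ValueError(f"feature {name!r} entirely missing in cohort")
        arr = np.asarray(v, dtype=float)
        schema.baseline_means[name] = float(arr.mean())
        if name in LOG_SCALE:
            arr = np.log(np.maximum(arr, 1e-6))
        schema.cont_mean[name] = float(arr.mean())
        sd = float(arr.std(ddof=0))
        schema.cont_sd[name] = sd if sd > 0 else 1.0
    for name, v in cats.items():
        if not v:
            if name == "precise":
                # follow-up-only score; "no change" (3) is the field default
                schema.modes[name] = 3
                continue
            raise ValueError(f"feature {name!r} entirely missing in cohort")
        levels, counts = np.unique(np.asarray(v), return_counts=True)
        mode = levels[np.argmax(counts)]
        schema.modes[name] = mode.item() if hasattr(mode, "item") else mode
    fh = [p.static.family_history for p in cohort.pathways]
    schema.modes["family_history"] = bool(sum(fh) * 2 > len(fh))
    return schema


def impute_baseline(cohort: Cohort, schema: Optional[FeatureSchema] = None) -> Cohort:
    """Fill static nulls with cohort mode (categorical) / mean (continuous).

    Returns a deep copy; imputation statistics are recorded in the copy's
    provenance.  A schema fitted on a training split may be supplied so
    that held-out cohorts reuse the training statistics.
    """
    schema = schema or fit_schema(cohort)
    out = copy.deepcopy(cohort)
    for p in out.pathways:
        s = p.static
        if s.likert is None:
            s.likert = int(schema.modes["likert"])
        if s.prostate_volume is None:
            s.prostate_volume = schema.baseline_means["volume"]
        if s.psa_density is None:
            s.psa_density = s.psa_baseline / s.prostate_volume
        if s.core_positivity is None:
            s.core_positivity = schema.baseline_means["core_positivity"]
    out.provenance = dict(out.provenance)
    out.provenance["imputation"] = {
        "means": dict(schema.cont_mean), "modes": {k: str(v) for k, v in schema.modes.items()},
    }
    return out


def _baseline_state(pathway: ClinicalPathway, schema: FeatureSchema) -> dict:
    """Step-0 resolved state: (value, observed-flag) per time-varying feature."""
    s = pathway.static
    vol = (s.prostate_volume if s.prostate_volume is not None
           else schema.baseline_means["volume"])
    psad = s.psa_density if s.psa_density is not None else s.psa_baseline / vol
    return {
        "psa": (s.psa_baseline, 1),
        "psa_density": (psad, 1 if s.psa_density is not None else 0),
        "volume": (vol, 1 if s.prostate_volume is not None else 0),
        "core_positivity": (
            s.core_positivity if s.core_positivity is not None
            else schema.baseline_means["core_positivity"],
            1 if s.core_positivity is not None else 0),
        "precise": (int(schema.modes["precise"]), 0),
        "grade_group": (s.grade_group, 1),
        "mri_stage": (s.mri_stage, 1),
    }


def _obs_updates(o: Observation) -> dict:
    upd = {}
    if o.psa is not None:
        upd["psa"] = o.psa
    if o.psa_density is not None:
        upd["psa_density"] = o.psa_density
    if o.prostate_volume is not None:
        upd["volume"] = o.prostate_volume
    if o.cores_total and o.cores_positive is not None:
        upd["core_positivity"] = o.cores_positive / o.cores_total
    if o.precise is not None:
        upd["precise"] = o.precise
    if o.biopsy_grade_group is not None:
        upd["grade_group"] = o.biopsy_grade_group
    if o.mri_stage is not None:
        upd["mri_stage"] = o.mri_stage
    return upd


def impute_longitudinal(pathway: ClinicalPathway,
                        schema: FeatureSchema) -> ClinicalPathway:
    """LOCF-impute every time-varying feature of a pathway.

    Returns a deep copy whose observations have no nulls in modelled
    fields; the copy carries an ``imputation_mask`` attribute (list of
    dicts, 1 = originally observed, 0 = imputed).
    """
    out = copy.deepcopy(pathway)
    state = _baseline_state(out, schema)
    masks = []
    for o in out.observations:
        upd = _obs_updates(o)
        mask = {}
        for feat in TIME_VARYING:
            if feat in upd:
                state[feat] = (upd[feat], 1)
                mask[feat] = 1
            else:
                state[feat] = (state[feat][0], 0)
                mask[feat] = 0
        o.psa = float(state["psa"][0])
        o.psa_density = float(state["psa_density"][0])
        o.prostate_volume = float(state["volume"][0])
        o.precise = int(state["precise"][0])
        o.biopsy_grade_group = int(state["grade_group"][0])
        o.mri_stage = str(state["mri_stage"][0])
        masks.append(mask)
    out.imputation_mask = masks  # type: ignore[attr-defined]
    return out


def encode_state(state: dict, static, schema: FeatureSchema) -> np.ndarray:
    """Encode one resolved step into the model feature vector."""
    x = np.zeros(N_FEATURES)
    cont = {
        "psa": state["psa"][0], "psa_density": state["psa_density"][0],
        "volume": state["volume"][0],
        "core_positivity": state["core_positivity"][0],
        "age": static.age_at_entry,
    }
    i = 0
    for name in CONTINUOUS:
        x[i] = schema.standardize(name, cont[name])
        i += 1
    likert = static.likert if static.likert is not None else int(schema.modes["likert"])
    cat_vals = {"grade_group": int(state["grade_group"][0]),
                "precise": int(state["precise"][0]),
                "likert": int(likert),
                "mri_stage": str(state["mri_stage"][0])}
    for feat, levels in ONEHOT_LEVELS.items():
        v = cat_vals[feat]
        for lv in levels:
            x[i] = 1.0 if v == lv else 0.0
            i += 1
    x[i] = 1.0 if static.family_history else 0.0
    return x


@dataclass
class SequenceTensor:
    """Encoded, imputed, time-stamped feature sequence."""

    values: np.ndarray  # [n_steps, N_FEATURES]
    delta_t: np.ndarray  # [n_steps], days since previous step (first = 0)
    mask: np.ndarray  # [n_steps, N_MASK], 1 = observed, 0 = imputed
    as_of: int
    times: np.ndarray = None  # [n_steps] observation days

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    def model_input(self) -> np.ndarray:
        """Concatenate values, velocity channels, mask and delta_t.

        Velocity channels are per-visit rates of change of (standardized)
        PSA and PSA density — the clinical kinetics used in surveillance —
        derived from consecutive steps so the encoder does not have to
        difference across irregular gaps itself.
        """
        dt_years = np.maximum(self.delta_t / 365.0, 1.0 / 12.0)
        vels = []
        for name in VELOCITY_FEATURES:
            col = self.values[:, CONTINUOUS.index(name)]
            vel = np.diff(col, prepend=col[0]) / dt_years
            vel[0] = 0.0
            vels.append(vel)
        return np.concatenate(
            [self.values, np.stack(vels, axis=1), self.mask,
             (self.delta_t / 365.0)[:, None]], axis=1)


VELOCITY_FEATURES = ("psa", "psa_density")
MODEL_INPUT_DIM = N_FEATURES + len(VELOCITY_FEATURES) + N_MASK + 1


def build_sequence(pathway: ClinicalPathway, as_of: int,
                   schema: FeatureSchema) -> SequenceTensor:
    """Build the model input sequence using data up to ``as_of`` days.

    Step 0 is the diagnostic observation; later steps are visits at day
    t <= as_of.  An ``as_of`` before the first visit yields the
    baseline-only single-step sequence.
    """
    if as_of < 0:
        raise ValueError("as_of must be >= 0")
    state = _baseline_state(pathway, schema)
    rows = [encode_state(state, pathway.static, schema)]
    masks = [np.array([state[f][1] for f in TIME_VARYING], dtype=float)]
    times = [0]
    for o in pathway.observations:
        if o.t > as_of:
            break
        upd = _obs_updates(o)
        for feat in TIME_VARYING:
            if feat in upd:
                state[feat] = (upd[feat], 1)
            else:
                state[feat] = (state[feat][0], 0)
        rows.append(encode_state(state, pathway.static, schema))
        masks.append(np.array([state[f][1] for f in TIME_VARYING], dtype=float))
        times.append(int(o.t))
    times_arr = np.asarray(times, dtype=float)
    delta = np.diff(times_arr, prepend=times_arr[0])
    return SequenceTensor(values=np.asarray(rows), delta_t=delta,
                          mask=np.asarray(masks), as_of=int(as_of),
                          times=times_arr.astype(int))


def truncate(pathway: ClinicalPathway, t: int) -> ClinicalPathway:
    """Copy of the pathway containing only observations at day <= t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    out = copy.deepcopy(pathway)
    out.observations = [o for o in out.observations if o.t <= t]
    return out


def resolve_state_at(pathway: ClinicalPathway, t: int,
                     schema: FeatureSchema) -> dict:
    """LOCF-resolved time-varying state at day ``t`` (for landmarking)."""
    state = _baseline_state(pathway, schema)
    for o in pathway.observations:
        if o.t > t:
            break
        upd = _obs_updates(o)
        for feat in TIME_VARYING:
            if feat in upd:
                state[feat] = (upd[feat], 1)
    return state
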