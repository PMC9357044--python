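"""Compare the recurrent model with Cox baselines on the split protocol.

Models are trained on random 80% splits and scored on the held-out 20%
with the time-dependent C-index at each (prediction time, horizon) cell;
the oracle arm predicts with the simulator's exact conditional risk and
bounds what any model could achieve.
"""

from dynsurv import EvalGrid, SimConfig, generate_planted_clusters, run_protocol
from dynsurv.ddhl import DDHLConfig
from dynsurv.evaluation import CoxArm, DDHLArm, OracleArm

cohort, truth = generate_planted_clusters(
    SimConfig(n_patients=400, seed=3, n_latent_strata=4), separation=3.0)
arms = {
    "ddhl": DDHLArm(DDHLConfig(max_epochs=80, patience=15, learning_rate=2e-3,
                               global_shape=True, ranking_loss_weight=0.2)),
    "cox": CoxArm(),
    "oracle": OracleArm(truth.risk),
}
table = run_protocol(cohort, arms, EvalGrid(), n_splits=2, seed=3)
cidx = table[table.metric == "c_index"].pivot_table(
    index=["prediction_time_days", "horizon_days"], columns="model",
    values="mean")
print("time-dependent C-index (mean over 2 splits):")
print(cidx.round(3).to_string())
# Baseline Cox sees entry covariates only, so its discrimination stays
# flat; the recurrent model improves as follow-up data accumulates and
# approaches the oracle.
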