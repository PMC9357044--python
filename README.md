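# dynsurv

Dynamic survival analysis for prostate-cancer active surveillance (AS):
live-updating progression risk from longitudinal monitoring data, plus
outcome-oriented temporal clustering of patient trajectories.

Men on AS are monitored with serial PSA, MRI (PRECISE scoring) and repeat
biopsies instead of immediate treatment. The clinical question is
dynamic: *given everything observed up to today, what is this patient's
risk of progressing to higher-risk disease (the composite CPG3+
endpoint) over the next 3-5 years?* Classical tools answer it poorly —
baseline Cox models ignore follow-up data entirely, and landmarking Cox
models see only the latest values. `dynsurv` is for biostatisticians and
methods researchers who want a fully reproducible, dependency-light
implementation of a recurrent dynamic survival model and its classical
comparators, exercisable end to end on a synthetic cohort with known
ground truth.

## The model

A patient's pathway — static entry profile plus the time-ordered sequence
of follow-up observations — is encoded by a GRU; a small head maps the
sequence summary to the shape/scale pair (k, λ) of a Weibull
time-to-event distribution, S(t) = exp(−(t/λ)^k). Risk is always
reported conditionally on being event-free at the as-of time t₀:

    F(Δt | t₀) = 1 − S(t₀ + Δt) / S(t₀)

which is a valid risk function by construction (non-decreasing in Δt,
F(0) = 0). Training maximizes the censored Weibull log-likelihood
left-truncated at the as-of time over every prefix of every patient's
history, so a single network serves predictions at any time point;
optional pairwise ranking and next-observation auxiliary losses are
available. All gradients (GRU backprop, likelihood, penalties) are
analytic and verified against finite differences in the test suite.

Around the core model the package provides:

* the CPG3+ composite endpoint engine (four progression scenarios,
  censoring at treatment/death/latest investigation);
* baseline and landmarking Cox comparators (Breslow baseline hazard);
* longitudinal metrics: time-dependent C-index, IPCW Brier score,
  Kaplan–Meier with confidence bands, and a repeated 80/20 split
  protocol over a prediction-time × horizon grid;
* actor-critic temporal predictive clustering over the frozen model,
  with data-driven cluster count, per-cluster survival curves, PCA of
  the latent embeddings and partial-dependence variable ranking;
* a synthetic AS cohort simulator with exact ground-truth risks.

## Worked example

`examples/03_fit_and_predict.py` trains the model on 320 synthetic
patients and contrasts two held-out cases:

```
trained for 34 epochs; best validation loss 3.1095

stable (stratum 0, censored), patient P00325:
  3-year risk with data to day    0: 0.730
  3-year risk with data to day  365: 0.542
  3-year risk with data to day  730: 0.202
  3-year risk with data to day 1095: 0.166

high-risk (stratum 3, progressed at day 1941), patient P00326:
  3-year risk with data to day    0: 0.592
  3-year risk with data to day  365: 0.364
  3-year risk with data to day  730: 0.328
  3-year risk with data to day 1095: 0.441
```

With baseline data alone the two patients are indistinguishable; three
years of accumulated observations separate them by a factor of ~2.7 in
predicted 3-year risk. `examples/04_compare_models.py` runs the split
protocol on the same kind of cohort and prints the time-dependent
C-index per (prediction time, horizon) cell — baseline Cox stays near
chance on this stratum-driven cohort while the recurrent model climbs
to ~0.70 with one year of data, against an oracle bound of ~0.74–0.80:

```
model                                cox   ddhl  oracle
prediction_time_days horizon_days
0                    1095          0.458  0.500   0.790
365                  1095          0.444  0.700   0.803
730                  1095          0.438  0.693   0.740
1095                 1095          0.507  0.701   0.759
```

The other examples cover cohort simulation and validation (`01`),
endpoint derivation (`02`) and temporal clustering with cluster-level
Kaplan–Meier curves and variable ranking (`05`). A thin CLI wraps the
same library calls (`dynsurv simulate | derive-endpoint | fit | predict |
fit-cox | evaluate | cluster | run`).

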