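"""Parameter recovery on synthetic tables with known truth.

Draws sparse multi-factor tables from the generative model (study-level
effects around known overall log ORs, heterogeneity, log-uniform SEs,
missing cells) and refits each one, measuring bias, RMSE and 95% CrI
coverage of the posterior medians.  A calibrated method shows bias near
zero and coverage near 95%.
"""

from mvmeta_mf import MvmaConfig, SimParams, recovery_experiment, simulate_table

params = SimParams(
    n_studies=20,
    mu_true=(0.4, 0.2, 0.0, -0.3),
    tau_true=(0.3, 0.3, 0.3, 0.3),
    se_range=(0.1, 0.8),
    report_prob=0.85,
    seed=7,
)

table, truth = simulate_table(params)
print("One synthetic draw:",
      f"{table.n_studies} studies x {table.n_factors} factors,",
      f"{int(table.mask.to_numpy().sum())} observed cells")
print("true overall log ORs:", truth["mu"], "\n")

cfg = MvmaConfig(variant="U", burn_in=2000, draws=2000, thin=1)
res = recovery_experiment(params, n_reps=50, fit_config=cfg)
print("50 simulate-and-refit replicates (Model U, short chains):")
print(res.round(3))
print("\n'bias' is the mean error of the posterior median against the")
print("generative truth; 'coverage' is the fraction of 95% credible")
print("intervals containing it (nominal 0.95).")
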