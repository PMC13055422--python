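"""The full pipeline: three correlation assumptions, one comparison.

Runs load -> filter -> univariate -> Models H, M0, U -> significance
classification -> adjusted-OR comparison for ACI, at a shortened MCMC
protocol so the example finishes in about a minute.  Model H admits both
within- and between-study correlations, M0 only between-study ones, U
none; comparing them shows how much the ACI estimate depends on the
correlation assumptions, which is the point of the three-model strategy.
"""

from mvmeta_mf import MvmaConfig, run_pipeline

profile = MvmaConfig(burn_in=5000, draws=5000, thin=1)
report = run_pipeline(profile=profile, seed=42, out_dir="scratch/report_demo")

print("Posterior median log OR (95% CrI) per factor and model:\n")
print(report.table2_like().to_string())

print("\nFactors with 95% CrI excluding zero under every model:",
      list(report.consistent_significant) or "none")

adj = report.adjusted_or
print(f"\nACI comparison (the primary factor):")
print(f"  univariate (DL) OR: {adj.univariate_or:.2f} "
      f"({adj.univariate_ci95[0]:.2f}-{adj.univariate_ci95[1]:.2f})")
for variant in ("H", "M0", "U"):
    orp, (lo, hi) = adj.adjusted[variant]
    print(f"  Model {variant:<2} adjusted OR: {orp:.2f} ({lo:.2f}-{hi:.2f})"
          f"   [adjusted/unadjusted log OR ratio {adj.attenuation[variant]:.2f}]")
print("\nAdjusted ORs close to 1 with intervals spanning 1 indicate that,")
print("once correlated co-factors are modelled, ACI carries little")
print("independent prognostic information.")
print("\nMachine-readable outputs written to scratch/report_demo/")
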