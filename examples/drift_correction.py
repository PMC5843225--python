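"""Why the drift correction matters: type-I error with and without it.

Simulates drift-correlated allele frequencies along a serial-founder chain
with NO true distance effect, then fits the distance regression with the
identity correlation (naive) and with the true drift correlation (GLS).
"""

from ooadrift.driftgls import ModelSpec, fit_model
from ooadrift.synth import DriftSimConfig, simulate_drift_frequencies

n_reps, alpha = 200, 0.05
rej_naive = rej_gls = 0
for rep in range(n_reps):
    table, truth, D2 = simulate_drift_frequencies(DriftSimConfig(beta_true=0.0, seed=rep))
    spec = ModelSpec(("sim",))
    rej_naive += fit_model(table, spec).pvalue("sim") < alpha
    rej_gls += fit_model(table, spec, R=truth.cov).pvalue("sim") < alpha

print(f"replicates: {n_reps}, true distance effect: none")
print(f"naive (identity R) rejection rate: {rej_naive / n_reps:.3f}")
print(f"drift-corrected rejection rate:    {rej_gls / n_reps:.3f}")
# Drift alone makes the naive test 'discover' distance effects far above
# the 5% nominal level; supplying the drift correlation restores it.
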