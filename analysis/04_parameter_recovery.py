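"""Parameter-recovery experiment: can the estimator find the truth back?

Generates 20 replicate synthetic studies at the reference parameters
(scaled up to 50 subjects per study for stable medians), fits each with M5,
and compares the median estimates with the generating values and with the
reported bootstrap 95% intervals of the study model.
"""

import pathlib

from piperbrain.experiments import recovery_experiment, reference_truth

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REFERENCE_CI = {"K_pb": (0.16, 0.39), "T_lag_fd": (2.21, 3.52)}

df = recovery_experiment(n_replicates=20, n_subjects=50, seed=1)
df.to_csv(OUT / "04_recovery.csv", index=False)

truth = reference_truth()
print(f"{len(df)} replicate fits, "
      f"{(df.convergence == 'converged').sum()} converged")
for name in ("K_pb", "K_bp_fd", "K_bp_md", "T_lag_fd"):
    med = df[name].median()
    true = getattr(truth, name)
    line = f"{name:10s} truth {true:6.3f}  median estimate {med:6.3f}  bias {100*(med-true)/true:+.1f}%"
    if name in REFERENCE_CI:
        lo, hi = REFERENCE_CI[name]
        line += f"  inside reported 95% CI ({lo}-{hi}): {lo <= med <= hi}"
    print(line)
print(f"wrote {OUT/'04_recovery.csv'}")
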