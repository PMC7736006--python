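"""Bootstrap precision and visual predictive check for the example-study fit.

Resamples subjects with replacement and refits (100 resamples here; the
full analysis convention is 1000 — scale with --nboot via the CLI), then
simulates 200 replicate studies under the fitted model to compare observed
and predicted percentile bands and BQL fractions per sampling hour.
"""

import pathlib

from piperbrain.core_model import BrainModelParams
from piperbrain.estimation import BQLMethod, bootstrap, fit, vpc
from piperbrain.experiments import reference_plasma
from piperbrain.io import default_config, example_dataset_path, read_dataset

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = default_config()
ds = read_dataset(example_dataset_path())
plasma = reference_plasma(cfg)
init = BrainModelParams(**{k: float(v) for k, v in cfg["init"].items()})

point = fit(ds, init, plasma, BQLMethod("M5"), n_starts=1, seed=2, compute_diagnostics=False)
print(f"point estimates (OFV {point.ofv:.2f}): "
      + ", ".join(f"{k}={v:.3g}" for k, v in point.theta.items()))

boot = bootstrap(ds, 100, seed=3, init=point.params, plasma=plasma, method=BQLMethod("M5"))
boot.summary.to_csv(OUT / "03_bootstrap_ci.csv")
print(boot.summary.round(3).to_string())
print(f"failed resamples: {boot.n_failed}/100")

check = vpc(point, ds, n_sim=200, seed=4, plasma=plasma)
check.table.to_csv(OUT / "03_vpc_table.csv", index=False)
inside = (
    (check.table["obs_p50"] >= check.table["sim_p50_lo"])
    & (check.table["obs_p50"] <= check.table["sim_p50_hi"])
).mean()
print(f"observed medians inside the simulated 95% band in {inside:.0%} of bins")
print(f"wrote {OUT/'03_bootstrap_ci.csv'} and {OUT/'03_vpc_table.csv'}")
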