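# piperbrain

Population pharmacokinetics of **piperacillin in brain extracellular fluid
(ECF)**, as measured by cerebral microdialysis in neuro-intensive-care
patients, with Monte-Carlo **probability of target attainment (PTA)**
simulation for dosing-regimen evaluation.

Piperacillin/tazobactam is a candidate for treating nosocomial CNS
infections, but in patients *without* generalised meningeal inflammation its
penetration into brain tissue is limited and delayed.  This package
implements the full analysis pipeline for that question, built for
pharmacometricians and method developers:

* a fixed two-compartment **plasma model** (analytic infusion solution with
  superposition) whose unbound concentration (FU = 0.70) drives
* a one-compartment **brain ECF model** with a transit compartment and a lag
  time: plasma-to-brain transfer rate `K_pb`, brain-to-plasma rates split by
  occasion (`K_bp,fd` after the first dose, `K_bp,md` at steady state), and a
  first-dose input lag `T_lag,fd` (the steady-state lag is fixed to 0);
* a **microdialysis observation model**: catheter dead-space correction of
  interval end times, interval-averaged concentrations (the "integrated
  approach"), probe-recovery scaling, and LLOQ censoring (0.05 mg/L);
* **nonlinear mixed-effects estimation** (Laplace approximation with
  interaction, in the FOCE-I spirit) with log-normal inter-individual
  variability on the lag time, a combined residual-error model, and both
  **M3** (censored-likelihood) and **M5** (LLOQ/2 substitution) handling of
  below-quantification-limit data, plus nonparametric bootstrap, visual
  predictive checks, shrinkage and condition-number diagnostics;
* **Monte-Carlo PTA** for the pharmacodynamic target fT>MIC ≥ 50% across
  12/16/24 g/day, intermittent/extended/continuous infusion, and a two-fold
  MIC grid, with a packaged EUCAST-derived MIC50/MIC90 table for pathogens
  relevant to CNS infection;
* a **synthetic study generator** reproducing the study design (10
  subjects, 4 g q8h by 30-min infusion, hourly sampling after the first dose
  and at steady state), so everything is testable without patient data.

No patient-level data are distributed: the packaged example dataset is
synthetic, and the plasma parameter set shipped in the default config is an
illustrative one (the analysis design takes plasma parameters as config
input).

## Worked example

```python
import numpy as np
from piperbrain import (BQLMethod, BrainModelParams, fit, read_dataset,
                        example_dataset_path)
from piperbrain.experiments import reference_plasma
from piperbrain.io import default_config

cfg = default_config()
ds = read_dataset(example_dataset_path())   # packaged synthetic study
init = BrainModelParams(**{k: float(v) for k, v in cfg["init"].items()})
res = fit(ds, init, reference_plasma(cfg), BQLMethod("M5"), n_starts=1, seed=2)
print(res.to_frame())
print(f"OFV {res.ofv:.2f} ({res.convergence})")
```

prints (10 synthetic subjects, generating values `K_pb` 0.32, `K_bp_fd`
7.31, `K_bp_md` 4.39, `T_lag_fd` 2.70):

```
   parameter  estimate  fixed
0       K_pb     0.305  False
1    K_bp_fd     7.264  False
2    K_bp_md     4.412  False
3   T_lag_fd     2.927  False
4   T_lag_md     0.000   True
5 omega_tlag     0.059  False
6  sigma_add     0.028  False
7 sigma_prop     0.296  False
OFV 0.53 (converged)
```

i.e. the estimator recovers the generating kinetics from a 10-subject study
to within sampling noise; `analysis/04_parameter_recovery.py` repeats this
over 20 replicate 50-subject studies, where the medians land within ~1% of
the generating values.

The analysis scripts under `analysis/` run the pipeline end to end
(`01` simulate → `02` fit → `03` bootstrap + VPC → `04` parameter recovery
→ `05` PTA), each writing its tables under `results/`.  The same steps are
available as a CLI:

```bash
piperbrain simulate --seed 1 --out study.csv
piperbrain fit --dataset study.csv --bql-method m5 --seed 2 --out fit.csv
piperbrain pta --seed 42 --out pta.csv
```

A typical PTA result (5000 virtual subjects, illustrative plasma model):
attainment exceeds 90% at every dose and infusion mode for MICs up to
0.5 mg/L, falls steeply beyond 1–2 mg/L, and the three infusion modes are
nearly indistinguishable — the slow plasma↔brain transfer (`K_pb` ≈ 0.32/h)
smooths plasma fluctuations so the brain effectively sees a continuous
infusion regardless of how the dose is given.

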