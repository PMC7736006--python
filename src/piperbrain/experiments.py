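"""Replicated simulation-estimation experiments.

The parameter-recovery experiment is the package's main internal validation:
generate replicate synthetic studies at the reference (bootstrap-median)
brain parameters, fit each replicate, and summarise the distribution of the
estimates.  The acceptance script and the test suite both run it through
this module so the conditions are identical everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import BrainModelParams, DosingRegimen, PlasmaModelParams
from .estimation import BQLMethod, fit
from .io import brain_params_from_config, default_config, plasma_params_from_config
from .synthetic import StudyDesign, generate_replicates

__all__ = ["recovery_experiment", "reference_truth", "reference_plasma", "reference_design"]


def reference_truth(cfg: dict | None = None) -> BrainModelParams:
    return brain_params_from_config(cfg or default_config())


def reference_plasma(cfg: dict | None = None) -> PlasmaModelParams:
    return plasma_params_from_config(cfg or default_config())


def reference_design(n_subjects: int = 10, cfg: dict | None = None, seed: int = 0) -> StudyDesign:
    d = (cfg or default_config())["design"]
    from .observation import CatheterSpec

    cat = d["catheter"]
    n_doses = int(d["ss_dose_number"])
    return StudyDesign(
        n_subjects=n_subjects,
        regimen=DosingRegimen(dose=d["dose_mg"], tau=d["tau_h"], t_inf=d["t_inf_h"],
                              n_doses=n_doses),
        samples_per_occasion=int(d["samples_per_occasion"]),
        lloq=float(d["lloq"]),
        catheter=CatheterSpec(dead_volume=cat["dead_volume_ul"],
                              flow_rate=cat["flow_rate_ul_min"],
                              recovery=cat["recovery"]),
        ss_dose_number=n_doses,
        seed=seed,
    )


def recovery_experiment(
    n_replicates: int = 20,
    n_subjects: int = 50,
    seed: int = 0,
    *,
    method: BQLMethod = BQLMethod("M5"),
    n_starts: int = 1,
    cfg: dict | None = None,
) -> pd.DataFrame:
    """Fit replicate synthetic studies generated at the reference truth.

    Returns one row per replicate with the estimated parameters, the OFV and
    the generator seed.  Initial estimates come from the config's ``init``
    section (deliberately away from the truth); each fit runs without
    per-fit diagnostics to keep the experiment tractable on one CPU.
    """
    cfg = cfg or default_config()
    truth = reference_truth(cfg)
    plasma = reference_plasma(cfg)
    design = reference_design(n_subjects, cfg)
    init = BrainModelParams(**{k: float(v) for k, v in cfg["init"].items()})

    rows = []
    reps = generate_replicates(truth, plasma, design, n_replicates, seed)
    for rep_no, (rep_seed, dataset) in enumerate(reps):
        res = fit(dataset, init, plasma, method, n_starts=n_starts,
                  seed=rep_seed, compute_diagnostics=False)
        row = dict(replicate=rep_no, seed=rep_seed, ofv=res.ofv,
                   convergence=res.convergence, omega_tlag=res.omega,
                   sigma_add=res.sigma[0], sigma_prop=res.sigma[1])
        row.update(res.theta)
        rows.append(row)
    return pd.DataFrame(rows)
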