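"""Dataset, configuration and packaged-data I/O.

The study data travel as NONMEM-style event records in a delimited text file
with header columns

    ID, OCC, EVID, TIME, TEND, AMT, RATE, DV, BQL, LLOQ

where EVID 1 rows are doses (AMT mg infused at RATE mg/h starting at TIME)
and EVID 0 rows are interval observations: the dialysate concentration DV
(mg/L) averaged over [TIME, TEND] with TEND already dead-space-corrected.
OCC 1 is the first-dose occasion, OCC 2 multiple doses at steady state.
Extra columns (e.g. TEND_NOM, TAD) are carried through untouched.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_model import BrainModelParams, PlasmaModelParams

__all__ = [
    "REQUIRED_COLUMNS",
    "MicrodialysisDataset",
    "read_dataset",
    "write_dataset",
    "load_config",
    "default_config",
    "load_mic_table",
    "plasma_params_from_config",
    "brain_params_from_config",
    "example_dataset_path",
]

REQUIRED_COLUMNS = ["ID", "OCC", "EVID", "TIME", "TEND", "AMT", "RATE", "DV", "BQL", "LLOQ"]

OCCASION_LABELS = {1: "first_dose", 2: "multiple_dose"}


@dataclass
class MicrodialysisDataset:
    """Event-record dataset: dosing rows plus interval observations.

    ``df`` holds the validated records; ``subjects`` optionally carries
    subject-level simulation truth (sampled lag times etc.) when the dataset
    was generated synthetically.
    """

    df: pd.DataFrame
    subjects: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    def observations(self, occ: int | None = None) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if occ is not None:
            obs = obs[obs["OCC"] == occ]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def bql_fraction(self) -> float:
        obs = self.observations()
        return float(obs["BQL"].mean()) if len(obs) else float("nan")

    def subset(self, ids) -> "MicrodialysisDataset":
        """Subjects re-labelled 1..n in the given (possibly repeated) order."""
        parts = []
        for new_id, old in enumerate(ids, start=1):
            part = self.df[self.df["ID"] == old].copy()
            if part.empty:
                raise KeyError(f"no such subject id {old}")
            part["ID"] = new_id
            parts.append(part)
        return MicrodialysisDataset(pd.concat(parts, ignore_index=True))


def _validate(df: pd.DataFrame) -> list[str]:
    errors = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column {col}")
    if errors:
        return errors
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["EVID"] not in (0, 1):
            errors.append(f"line {line}: EVID must be 0 or 1")
            continue
        if row["TIME"] < 0:
            errors.append(f"line {line}: negative TIME")
        if row["EVID"] == 0:
            if not np.isfinite(row["TEND"]) or not row["TIME"] < row["TEND"]:
                errors.append(f"line {line}: observation needs TIME < TEND")
            if row["BQL"] not in (0, 1):
                errors.append(f"line {line}: BQL must be 0 or 1")
            if not np.isfinite(row["LLOQ"]) or row["LLOQ"] <= 0:
                errors.append(f"line {line}: LLOQ must be > 0")
            if not np.isfinite(row["DV"]):
                errors.append(f"line {line}: observation needs numeric DV")
            if int(row["OCC"]) not in OCCASION_LABELS:
                errors.append(f"line {line}: OCC must be 1 or 2")
        else:
            if not np.isfinite(row["AMT"]) or row["AMT"] <= 0:
                errors.append(f"line {line}: dose needs AMT > 0")
            if not np.isfinite(row["RATE"]) or row["RATE"] <= 0:
                errors.append(f"line {line}: dose needs RATE > 0")
            if np.isfinite(row["DV"]):
                errors.append(f"line {line}: dose rows must have empty DV")
    for sid, grp in df.groupby("ID"):
        if np.any(np.diff(grp["TIME"].to_numpy()) < 0):
            errors.append(f"subject {sid}: TIME not non-decreasing")
    return errors


def read_dataset(path) -> MicrodialysisDataset:
    """Read and validate an event-record dataset from delimited text."""
    df = pd.read_csv(path, na_values=["."])
    errors = _validate(df)
    if errors:
        raise ValueError(
            f"invalid dataset {path}:\n  " + "\n  ".join(errors[:20])
        )
    for col in ("ID", "OCC", "EVID", "BQL"):
        df[col] = df[col].fillna(0).astype(int)
    return MicrodialysisDataset(df.reset_index(drop=True))


def write_dataset(dataset: MicrodialysisDataset, path) -> None:
    dataset.df.to_csv(path, index=False, na_rep=".")


def _data_file(name: str):
    return importlib.resources.files("piperbrain").joinpath("data", name)


def example_dataset_path():
    """Packaged example study (synthetic, generated with seed 1)."""
    return _data_file("example_study.csv")


def load_mic_table() -> pd.DataFrame:
    """Packaged MIC50/MIC90 library for pathogens common in CNS infection.

    Wild-type EUCAST piperacillin/tazobactam MIC distributions, mg/L.
    """
    with importlib.resources.as_file(_data_file("mic_table.csv")) as p:
        tab = pd.read_csv(p)
    if not (tab["MIC50"] <= tab["MIC90"]).all():
        raise ValueError("MIC table invariant violated: MIC50 must be <= MIC90")
    return tab


def load_config(path=None) -> dict:
    """Load a YAML run configuration; ``None`` loads the packaged default."""
    if path is None:
        with importlib.resources.as_file(_data_file("default_config.yaml")) as p:
            with open(p) as fh:
                return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_config() -> dict:
    return load_config(None)


def plasma_params_from_config(cfg: dict, model: str = "default") -> PlasmaModelParams:
    sec = cfg["plasma"][model]
    return PlasmaModelParams(
        CL=sec["CL"], Q=sec["Q"], Vc=sec["Vc"], Vp=sec["Vp"], FU=sec["FU"],
        iiv=dict(sec.get("iiv", {})),
    )


def brain_params_from_config(cfg: dict, section: str = "brain") -> BrainModelParams:
    sec = cfg[section]
    return BrainModelParams(
        K_pb=sec["K_pb"], K_bp_fd=sec["K_bp_fd"], K_bp_md=sec["K_bp_md"],
        T_lag_fd=sec["T_lag_fd"], T_lag_md=sec.get("T_lag_md", 0.0),
        omega_tlag=sec.get("omega_tlag", 0.0),
        sigma_add=sec.get("sigma_add", 0.0), sigma_prop=sec.get("sigma_prop", 0.0),
    )
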