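"""Delimited-text I/O for cohort tables, doses, enrichment records and DLW
results, plus YAML configuration loading.

All files are comma-delimited with an explicit header; units are embedded in
the column names (``tee_kcal_d``, ``time_days``, ...) so every file loads
directly into pandas.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import CellSpec, CohortConfig, TeeModel, CELL_ORDER
from .dlw import DlwResult, EnrichmentSample, EnrichmentSeries, IsotopeDose
from .errors import SchemaError

ENRICHMENT_COLUMNS = ["subject_id", "time_days", "isotope", "excess", "discarded"]
DOSE_COLUMNS = ["subject_id", "o18_water_g", "d2_water_g", "o18_excess_mol", "d2_excess_mol"]
RESULT_COLUMNS = [
    "subject_id", "kd_per_d", "ko_per_d", "nd_mol", "no_mol", "n_mol",
    "tbw_kg", "ffm_kg", "rco2_mol_d", "tee_kcal_d", "rq", "valid", "flags",
]


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("id", "sex", "smoking_status"):
        if col not in frame.columns:
            raise SchemaError(f"cohort file missing column '{col}'")
    return frame


def read_enrichments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ENRICHMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"enrichment file missing columns {missing}")
    if frame.empty:
        raise SchemaError("enrichment file has no data rows")
    bad_iso = ~frame["isotope"].isin(["2H", "18O"])
    if bad_iso.any():
        row = int(frame.index[bad_iso][0]) + 2  # +2: header + 1-based
        raise SchemaError(f"unknown isotope at line {row}")
    kept = frame[frame["discarded"] == 0]
    bad = kept["excess"] <= 0
    if bad.any():
        row = int(kept.index[bad][0]) + 2
        raise SchemaError(f"non-positive enrichment at line {row}")
    return frame


def enrichments_to_series(frame: pd.DataFrame) -> list[EnrichmentSeries]:
    """Pivot long-format enrichment rows into one series per subject.

    Each (subject, time) must have both isotopes; subjects keep file order.
    """
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        wide = grp.pivot_table(index=["time_days", "discarded"], columns="isotope",
                               values="excess", aggfunc="first").reset_index()
        if "2H" not in wide.columns or "18O" not in wide.columns or wide[["2H", "18O"]].isna().any().any():
            raise SchemaError(f"subject {sid}: each time point needs both isotopes")
        wide = wide.sort_values("time_days")
        samples = tuple(
            EnrichmentSample(float(r["time_days"]), float(r["2H"]),
                             float(r["18O"]), bool(r["discarded"]))
            for _, r in wide.iterrows()
        )
        out.append(EnrichmentSeries(subject_id=str(sid), samples=samples))
    return out


def read_doses(path: str | Path) -> dict[str, IsotopeDose]:
    frame = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"dose file missing columns {missing}")
    return {
        str(r.subject_id): IsotopeDose(
            float(r.o18_water_g), float(r.d2_water_g),
            float(r.o18_excess_mol), float(r.d2_excess_mol))
        for r in frame.itertuples()
    }


def results_to_frame(results: Sequence[DlwResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["valid"] = int(r.valid)
        d["flags"] = ";".join(r.flags)
        rows.append(d)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# --- configuration -----------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    return {
        "noise_cv": config.noise_cv,
        "space_ratio": config.space_ratio,
        "rq": config.rq,
        "seed": config.seed,
        "cells": {
            f"{sex}/{status}": asdict(spec)
            for (sex, status), spec in config.cells.items()
        },
        "tee_models": {sex: asdict(m) for sex, m in config.tee_models.items()},
    }


def config_from_dict(data: dict) -> CohortConfig:
    cells = {}
    for key, spec in data.get("cells", {}).items():
        sex, status = key.split("/")
        spec = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in spec.items()}
        cells[(sex, status)] = CellSpec(**spec)
    tee_models = {sex: TeeModel(**m) for sex, m in data.get("tee_models", {}).items()}
    return CohortConfig(
        cells=cells, tee_models=tee_models,
        noise_cv=float(data.get("noise_cv", 0.01)),
        space_ratio=float(data.get("space_ratio", 1.034)),
        rq=float(data.get("rq", 0.86)),
        seed=int(data.get("seed", 0)),
    )


def save_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} is not a mapping")
    return config_from_dict(data)
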