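"""CSV readers/writers, configuration loading, logging and run provenance.

Table schemas
-------------
encounters.csv : encounter_id, patient_id, age, admission_datetime,
    discharge_datetime
labs.csv : encounter_id, lab_code, lab_datetime, value

Datetimes are minute-precision strings "YYYY-MM-DD HH:MM".  Laboratory values
are unit-free numerics; unit harmonization is the caller's responsibility
(creatinine is assumed to be in mg/dL, the scale on which the AKIN thresholds
are stated).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .synthetic_ehr import BUN_CODE, CREATININE_CODE, DATETIME_FMT, GeneratorConfig

__all__ = ["PipelineConfig", "read_tables", "load_config", "dump_config",
           "write_run_manifest", "logger"]

logger = logging.getLogger("akipair")


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one pipeline run.

    ``split`` is the selection:prediction ratio written "a:b"; the prediction
    part receives b/(a+b) of each class.  The flags reproduce protocol
    variants that are deliberately not the default: ``all_inpatients_sigma``
    fits the symbol bins on selection+prediction parts pooled (at the cost of
    train/test leakage), ``resubstitution_selection`` lets a record be its own
    neighbor while scoring candidate channel subsets, ``micro_average`` pools
    confusion counts over balanced datasets instead of averaging metrics, and
    ``ratio_cap`` reads the stage-1 "150-200%" band literally, disqualifying
    relative rises above the cap.
    """

    data_dir: str = "data"
    output_dir: str = "results"
    creatinine_code: str = CREATININE_CODE
    bun_code: str = BUN_CODE
    aki_delta: float = 0.3
    aki_ratio: float = 1.5
    pair_window_hours: float = 48.0
    min_age: float = 60.0
    min_stay_days: float = 10.0
    window_days: Tuple[int, ...] = (5,)
    horizon_days: Tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    k: int = 5
    tie_vote: str = "positive"
    split: str = "8:2"
    selection_method: str = "sfs"
    seed: int = 0
    balanced: bool = True
    pairs_restrict: Optional[str] = None
    all_inpatients_sigma: bool = False
    resubstitution_selection: bool = False
    micro_average: bool = False
    ratio_cap: Optional[float] = None
    generator: Optional[GeneratorConfig] = None

    def __post_init__(self) -> None:
        for name in ("aki_delta", "aki_ratio", "pair_window_hours",
                     "min_stay_days", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.selection_method not in ("sfs", "sbs"):
            raise ValueError("selection_method must be 'sfs' or 'sbs'")
        self.prediction_fraction  # validates the split string

    @property
    def prediction_fraction(self) -> float:
        try:
            a, b = (float(x) for x in self.split.split(":"))
        except ValueError as exc:
            raise ValueError(f"split must look like '8:2', got {self.split!r}") from exc
        if a <= 0 or b <= 0:
            raise ValueError("both parts of split must be positive")
        return b / (a + b)


def _parse_datetimes(raw: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=DATETIME_FMT, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        rows = [str(i) for i in raw.index[bad][:10]]
        raise ValueError(f"malformed {what} datetime at rows {', '.join(rows)}")
    return parsed


def read_tables(
    encounters_path, labs_path
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Read and validate the encounter and laboratory tables.

    Hard errors (naming row numbers) on malformed datetimes, non-numeric
    laboratory values, and duplicate encounter ids.  Laboratory rows that
    reference no encounter, or fall outside the encounter's
    [admission, discharge] interval, are dropped with a logged count.
    Returns the two tables plus the drop counts.
    """
    enc = pd.read_csv(encounters_path, dtype={"encounter_id": str, "patient_id": str})
    labs = pd.read_csv(labs_path, dtype={"encounter_id": str, "lab_code": str})

    dup = enc["encounter_id"].duplicated()
    if dup.any():
        rows = [str(i) for i in enc.index[dup][:10]]
        raise ValueError(f"duplicate encounter_id at rows {', '.join(rows)}")
    enc = enc.assign(
        admission_datetime=_parse_datetimes(enc["admission_datetime"], "admission"),
        discharge_datetime=_parse_datetimes(enc["discharge_datetime"], "discharge"),
    )
    values = pd.to_numeric(labs["value"], errors="coerce")
    bad = values.isna() & labs["value"].notna()
    if bad.any():
        rows = [str(i) for i in labs.index[bad][:10]]
        raise ValueError(f"non-numeric laboratory value at rows {', '.join(rows)}")
    labs = labs.assign(
        value=values,
        lab_datetime=_parse_datetimes(labs["lab_datetime"], "laboratory"),
    )

    n0 = len(labs)
    merged = labs.merge(
        enc[["encounter_id", "admission_datetime", "discharge_datetime"]],
        on="encounter_id", how="left",
    )
    orphan = merged["admission_datetime"].isna()
    n_orphan = int(orphan.sum())
    inside = (~orphan
              & (merged["lab_datetime"] >= merged["admission_datetime"])
              & (merged["lab_datetime"] <= merged["discharge_datetime"]))
    n_outside = int((~orphan & ~inside).sum())
    labs = merged.loc[inside, ["encounter_id", "lab_code", "lab_datetime", "value"]]
    labs = labs.reset_index(drop=True)
    counts = {"orphan_rows_dropped": n_orphan,
              "out_of_stay_rows_dropped": n_outside,
              "rows_kept": len(labs), "rows_read": n0}
    if n_orphan or n_outside:
        logger.info("dropped %d orphan and %d out-of-stay laboratory rows",
                    n_orphan, n_outside)
    return enc, labs, counts


_TUPLE_FIELDS = {"window_days", "horizon_days"}


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) configuration file, applying defaults.

    Unknown keys and invalid ranges are rejected; an empty file yields the
    default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "generator" in raw and raw["generator"] is not None:
        gen = dict(raw["generator"])
        gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        gen_unknown = set(gen) - gen_known
        if gen_unknown:
            raise ValueError(f"unknown generator config keys: {sorted(gen_unknown)}")
        for key in ("age_range", "panel"):
            if key in gen and isinstance(gen[key], list):
                gen[key] = tuple(gen[key])
        raw["generator"] = GeneratorConfig(**gen)
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path) -> None:
    """Write the effective configuration back out as YAML (round-trips)."""
    d = dataclasses.asdict(cfg)
    for key in _TUPLE_FIELDS:
        d[key] = list(d[key])
    if d["generator"] is not None:
        d["generator"]["age_range"] = list(d["generator"]["age_range"])
        d["generator"]["panel"] = list(d["generator"]["panel"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def write_run_manifest(outdir, cfg: PipelineConfig, seed: int) -> None:
    """Record everything needed to reproduce a run bit-identically."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config.yaml")
    manifest = {
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
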