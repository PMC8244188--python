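"""Reading and writing per-patient analysis data and pipeline configuration.

The interchange format is a flat CSV with one row per patient per AE
type and header columns ``trial_id, arm, ae_type, time_days,
outcome_code``. Outcome codes are 0 = censored, 1 = AE, 2 = death before
AE, 3 = other competing event. This mirrors what a sponsor would export
from ADAE/ADSL-style analysis datasets (first AE of the type per patient,
with follow-up time and a coded end-of-observation reason) without tying
the tool to CDISC structures.

Row-level violations (non-positive times, unknown codes) are reported
with 1-based CSV line numbers and abort the read: silently dropping rows
would change denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .event_model import AnalysisSet, Outcome

__all__ = ["REQUIRED_COLUMNS", "read_analysis_sets", "write_analysis_sets", "PipelineConfig"]

REQUIRED_COLUMNS = ("trial_id", "arm", "ae_type", "time_days", "outcome_code")


def read_analysis_sets(path: str | Path) -> list[AnalysisSet]:
    """Read and validate analysis units from a flat CSV.

    Returns one AnalysisSet per (trial_id, arm, ae_type) group, in file
    order of first appearance. A ``subject_id`` column is used when
    present; otherwise ids are derived from row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trial_id": str, "arm": str, "ae_type": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    # +2: header line plus 1-based indexing
    lines = df.index.to_numpy() + 2
    times = pd.to_numeric(df["time_days"], errors="coerce").to_numpy(dtype=float)
    bad_time = ~np.isfinite(times) | (times <= 0)
    if bad_time.any():
        where = ", ".join(str(l) for l in lines[bad_time][:10])
        raise ValueError(
            f"{path}: non-positive or non-numeric time_days at line(s) {where}"
        )
    codes = pd.to_numeric(df["outcome_code"], errors="coerce").to_numpy()
    valid = {int(o) for o in Outcome}
    bad_code = ~np.isin(codes, list(valid)) | ~np.isfinite(codes.astype(float))
    if bad_code.any():
        where = ", ".join(str(l) for l in lines[bad_code][:10])
        raise ValueError(
            f"{path}: unknown outcome_code (expected {sorted(valid)}) at line(s) {where}"
        )
    df = df.assign(_time=times, _code=codes.astype(np.int64))
    if "subject_id" not in df.columns:
        df = df.assign(subject_id=[f"row{l}" for l in lines])
    sets = []
    for (trial, arm, ae), g in df.groupby(["trial_id", "arm", "ae_type"], sort=False):
        sets.append(
            AnalysisSet(
                trial_id=str(trial), arm=str(arm), ae_type=str(ae),
                subject_ids=g["subject_id"].to_numpy(dtype=object),
                times=g["_time"].to_numpy(),
                outcomes=g["_code"].to_numpy(),
            )
        )
    return sets


def write_analysis_sets(sets: list[AnalysisSet], path: str | Path) -> None:
    """Write analysis units to the flat CSV format (lossless round trip)."""
    frames = [
        pd.DataFrame(
            {
                "trial_id": s.trial_id,
                "arm": s.arm,
                "ae_type": s.ae_type,
                "subject_id": s.subject_ids,
                "time_days": s.times,
                "outcome_code": s.outcomes,
            }
        )
        for s in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Configuration of a full estimate/compare/categorise/meta run."""

    input_path: str | None = None       # CSV of analysis units; None = simulate
    output_dir: str = "aerisk-output"
    tau_rules: list[str] = field(default_factory=lambda: ["max"])
    estimators: list[str] = field(
        default_factory=lambda: [
            "ip", "ptid-ignore-ce", "1-km", "ptid-acc-ce", "aje-death-only",
        ]
    )
    n_boot: int = 1000
    seed: int = 0
    meta_method: str = "reml"
    knapp_hartung: bool = False
    covariates: list[str] = field(
        default_factory=lambda: ["pct_censoring", "pct_ce", "aje_probability", "tau_years"]
    )
    multivariable_covariates: list[str] = field(
        default_factory=lambda: ["pct_censoring", "aje_probability", "tau_years"]
    )
    # simulation block, used when input_path is None
    n_trials: int = 10
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)
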