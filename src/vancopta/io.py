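"""Dataset dialect, run configuration and manifests.

Concentration datasets use a NONMEM-convention CSV: one row per event,
columns ID, TIME (h from first dose), DV (mg/L, empty on dose rows),
AMT (mg), RATE (mg/h), EVID (0 observation / 1 dose), MDV, EGFR plus any
free covariate columns.  Units are fixed (hours, mg/L, mg) — no unit
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json

import numpy as np
import pandas as pd
import yaml

__all__ = ["DatasetError", "RunConfig", "read_dataset", "write_dataset", "validate_dataset", "write_manifest"]

REQUIRED_COLUMNS = ["ID", "TIME", "DV", "AMT", "RATE", "EVID", "MDV", "EGFR"]


class DatasetError(ValueError):
    """Schema violations, with offending row numbers."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("dataset violates the dialect:\n  " + "\n  ".join(violations))


def validate_dataset(df: pd.DataFrame) -> None:
    """Raise :class:`DatasetError` listing every violating row."""
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError([f"missing required columns: {missing}"])
    for i, row in df.iterrows():
        evid = row["EVID"]
        if evid == 1:
            if not row["AMT"] > 0:
                problems.append(f"row {i}: dose row (EVID=1) must have AMT > 0")
            if not pd.isna(row["DV"]):
                problems.append(f"row {i}: dose row (EVID=1) must not carry DV")
        elif evid == 0:
            if pd.isna(row["DV"]) and row["MDV"] == 0:
                problems.append(f"row {i}: observation row (EVID=0, MDV=0) must have DV")
        else:
            problems.append(f"row {i}: EVID must be 0 or 1, got {evid}")
    for sid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            problems.append(f"subject {sid}: TIME must be non-decreasing within ID")
    if problems:
        raise DatasetError(problems)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dialect-conformant CSV."""
    df = pd.read_csv(path)
    validate_dataset(df)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Validate and write; round-trips losslessly through read_dataset."""
    validate_dataset(df)
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """One declarative document per run (YAML)."""

    seed: int = 0
    n_subjects: int = 1000
    population: dict = field(default_factory=dict)
    regimen: dict = field(default_factory=dict)
    targets: list = field(default_factory=list)
    output_dir: str = "."

    _KNOWN = {"seed", "n_subjects", "population", "regimen", "targets", "output_dir"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "population": self.population,
            "regimen": self.regimen,
            "targets": self.targets,
            "output_dir": self.output_dir,
        }


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(path, command: str, params: dict, seed) -> dict:
    """Write a reproducibility manifest next to a run's outputs."""
    from . import __version__

    manifest = {
        "command": command,
        "config_hash": config_hash(params),
        "seed": seed,
        "package_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
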