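"""File formats and run configuration.

Canonical formats: CSV for tabular timecourses (columns ``time_h``,
``condition``, ``replicate``, ``value``), JSON for results, YAML for
configuration and treatment schedules, multi-page TIFF for image stacks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .pk import TreatmentCourse

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "write_results",
    "read_results",
    "read_course",
    "write_course",
    "RunConfig",
]

TIMECOURSE_COLUMNS = ("time_h", "condition", "replicate", "value")


def read_timecourses(path) -> pd.DataFrame:
    """Read a timecourse table, validating the documented schema.

    Raises with the offending 1-based data-row indices when numeric fields
    cannot be parsed; an empty file is a schema error, not an empty
    collection.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path.name}: no data rows")
    for col in ("time_h", "value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()] + 1
        if len(bad):
            raise ValueError(f"{path.name}: malformed {col!r} in data row(s) {list(bad)}")
        if parsed.isna().any():
            rows = list(df.index[parsed.isna()] + 1)
            raise ValueError(f"{path.name}: missing {col!r} in data row(s) {rows}")
        df[col] = parsed
    return df


def write_timecourses(df: pd.DataFrame, path) -> None:
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    df.loc[:, list(TIMECOURSE_COLUMNS)].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")


def read_results(path):
    return json.loads(Path(path).read_text())


def read_course(path) -> TreatmentCourse:
    data = yaml.safe_load(Path(path).read_text())
    return TreatmentCourse.from_dict(data)


def write_course(course: TreatmentCourse, path) -> None:
    Path(path).write_text(yaml.safe_dump(course.to_dict(), sort_keys=False))


_CONFIG_FIELDS = {
    "seed", "targets", "v_ratio", "n_starts", "lam", "surface_grid",
    "out_dir", "log_level", "design",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    targets: tuple = ("k_FE", "k_FB")
    v_ratio: float = 1.0e4
    n_starts: int = 16
    lam: float = 0.5
    surface_grid: int = 512
    out_dir: str = "results"
    log_level: str = "INFO"
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        if not targets or set(targets) - {"k_FE", "k_FB"}:
            raise ValueError("targets must be a non-empty subset of {'k_FE', 'k_FB'}")
        if self.v_ratio <= 0:
            raise ValueError("v_ratio must be positive")
        if self.n_starts < 1 or self.surface_grid < 8:
            raise ValueError("n_starts >= 1 and surface_grid >= 8 required")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "design", dict(self.design))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
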