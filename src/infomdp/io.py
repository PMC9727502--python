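"""Configuration, serialization and run reporting.

All artifacts are plain text: TSV (header row, explicit ``state`` index
column) for per-state vectors, matrices and policies, JSON for nested
reports.  A run's configuration is echoed verbatim into its output
directory so that config + seed fully determine the outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .gridworld import GridSpec, Neighborhood

__all__ = [
    "RunConfig",
    "RunReport",
    "load_config",
    "write_vectors",
    "write_matrix",
    "read_matrix",
    "write_json",
]

_CONFIG_KEYS = {
    "width",
    "height",
    "neighborhood",
    "goal",
    "betas",
    "log_base",
    "epsilon",
    "max_len",
    "start",
    "n_episodes",
    "max_steps",
    "seed",
    "inner_tol",
    "outer_tol",
    "embed_dim",
}


@dataclass
class RunConfig:
    """Fully serializable description of one run."""

    width: int = 5
    height: int = 5
    neighborhood: str = "manhattan"
    goal: int = 12
    betas: list[float] = field(default_factory=lambda: [100.0])
    log_base: float = 2.0
    epsilon: float = 0.05
    max_len: int = 3
    start: int = 0
    n_episodes: int = 10_000
    max_steps: int = 100_000
    seed: int = 0
    inner_tol: float = 1e-9
    outer_tol: float = 1e-9
    embed_dim: int = 2

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.width, self.height, Neighborhood(self.neighborhood))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Unknown keys in the file raise a schema error listing the offenders;
    overrides with value ``None`` are ignored.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        unknown = sorted(set(loaded) - _CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        data.update(loaded)
    for key, value in overrides.items():
        if value is not None:
            if key not in _CONFIG_KEYS:
                raise ValueError(f"unknown config key: {key}")
            data[key] = value
    return RunConfig(**data)


@dataclass
class RunReport:
    """Inventory of one run: config echo, diagnostics, artifacts, warnings."""

    config: dict[str, Any]
    diagnostics: dict[str, Any] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def check_artifacts(self, out_dir: Path) -> None:
        for name in self.artifacts:
            p = out_dir / name
            if not p.exists() or p.stat().st_size == 0:
                raise RuntimeError(f"artifact {name} missing or empty")

    def write(self, out_dir: Path, name: str = "report.json") -> Path:
        path = Path(out_dir) / name
        write_json(path, asdict(self))
        return path


_FLOAT_FMT = "%.12g"


def write_vectors(path: str | Path, columns: dict[str, np.ndarray]) -> Path:
    """Write named per-state vectors as TSV with a ``state`` index column."""
    frame = pd.DataFrame(columns)
    frame.insert(0, "state", np.arange(len(frame)))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)

def write_matrix(
    path: str | Path, matrix: np.ndarray, columns: list[str] | None = None
) -> Path:
    """Write a matrix as TSV, one row per state index."""
    matrix = np.asarray(matrix)
    if columns is None:
        columns = [str(j) for j in range(matrix.shape[1])]
    frame = pd.DataFrame(matrix, columns=columns)
    frame.insert(0, "state", np.arange(matrix.shape[0]))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_matrix(path: str | Path) -> np.ndarray:
    """Reload a matrix written by :func:`write_matrix` (index column dropped)."""
    frame = pd.read_csv(path, sep="\t")
    return frame.drop(columns=["state"]).to_numpy(dtype=float)


def write_json(path: str | Path, payload: dict[str, Any]) -> Path:
    def _default(obj: Any) -> Any:
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return Path(path)
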