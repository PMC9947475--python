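"""Run configuration: a small validated YAML file shared by all CLI commands.

Defaults reproduce the canonical study settings: Lasso α = 0.1, 75/25 split,
5-fold CV, the full 4 × 3 × 16 hyperparameter grid, VMD with K = 3.
Unknown keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import DatasetConfig
from .vmd import VmdParams

_TOP_KEYS = {"seed", "static_window", "simulate", "vmd", "model", "io"}
_SIM_KEYS = {f.name for f in DatasetConfig.__dataclass_fields__.values()} | {"n"}
_MODEL_KEYS = {"alpha", "frac", "folds", "max_iter", "grid", "pfi_repeats"}
_VMD_KEYS = {"alpha", "tau", "tol", "max_iter"}
_IO_KEYS = {"imu_dialect", "fp_dialect"}


@dataclass
class RunConfig:
    seed: int = 0
    static_window: tuple[float, float] = (0.1, 1.4)
    n: int = 200
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    vmd: VmdParams = field(default_factory=VmdParams)
    alpha: float = 0.1
    frac: float = 0.75
    folds: int = 5
    max_iter: int = 2000
    pfi_repeats: int = 10
    grid: dict | None = None  # None = the full 192-combination default
    imu_dialect: dict | None = None
    fp_dialect: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.frac < 1.0:
            raise ConfigError(f"split fraction {self.frac} outside (0, 1)")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.alpha < 0:
            raise ConfigError("lasso alpha must be >= 0")
        if len(self.static_window) != 2 or self.static_window[0] >= self.static_window[1]:
            raise ConfigError(f"invalid static window {self.static_window}")
        if self.n < 8:
            raise ConfigError("simulate.n must be >= 8")


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_grid(raw: dict) -> dict:
    grid = {}
    if "activation" in raw:
        grid["activation"] = list(raw["activation"])
    if "solver" in raw:
        grid["solver"] = list(raw["solver"])
    if "hidden_units" in raw:
        lo, hi = raw["hidden_units"]
        grid["hidden_layer_sizes"] = [(k,) for k in range(int(lo), int(hi) + 1)]
    return grid or None


def load_config(path=None) -> RunConfig:
    """Read and validate a YAML run configuration (``None`` → all defaults)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "static_window" in raw:
        kwargs["static_window"] = tuple(float(x) for x in raw["static_window"])
    sim = raw.get("simulate", {})
    _check_keys(sim, _SIM_KEYS, "simulate")
    if "n" in sim:
        kwargs["n"] = int(sim.pop("n"))
    if "wobble" in sim:
        sim["wobble"] = tuple(tuple(w) for w in sim["wobble"])
    if "h_range" in sim:
        sim["h_range"] = tuple(sim["h_range"])
    try:
        kwargs["dataset"] = DatasetConfig(**sim)
    except TypeError as exc:
        raise ConfigError(f"simulate section: {exc}") from exc
    vmd = raw.get("vmd", {})
    _check_keys(vmd, _VMD_KEYS, "vmd")
    kwargs["vmd"] = VmdParams(**{k: float(v) if k != "max_iter" else int(v) for k, v in vmd.items()})
    mdl = raw.get("model", {})
    _check_keys(mdl, _MODEL_KEYS, "model")
    for key in ("alpha", "frac"):
        if key in mdl:
            kwargs[key] = float(mdl[key])
    for key in ("folds", "max_iter", "pfi_repeats"):
        if key in mdl:
            kwargs[key] = int(mdl[key])
    if "grid" in mdl:
        kwargs["grid"] = _parse_grid(mdl["grid"])
    io_sec = raw.get("io", {})
    _check_keys(io_sec, _IO_KEYS, "io")
    kwargs["imu_dialect"] = io_sec.get("imu_dialect")
    kwargs["fp_dialect"] = io_sec.get("fp_dialect")
    return RunConfig(**kwargs)
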