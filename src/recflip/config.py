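"""Run configuration: YAML/JSON parsing and validation for the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import CircuitParameters, CircuitTopology
from .synth import NoiseModel, default_dose_ladder

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run configuration; the message lists the offending keys."""


_GRID_KEYS = {"start", "stop", "n", "scale"}


def _parse_grid(spec) -> np.ndarray:
    """A sweep grid: either an explicit list or {start, stop, n, scale}."""
    if isinstance(spec, (list, tuple)):
        return np.asarray(spec, dtype=float)
    if isinstance(spec, dict):
        bad = set(spec) - _GRID_KEYS
        if bad:
            raise ConfigError(f"unknown grid key(s): {sorted(bad)}")
        start, stop, n = spec["start"], spec["stop"], int(spec.get("n", 25))
        if spec.get("scale", "linear") == "log":
            return np.logspace(np.log10(start), np.log10(stop), n)
        return np.linspace(start, stop, n)
    raise ConfigError(f"cannot parse grid spec {spec!r}")


@dataclass
class RunConfig:
    params: CircuitParameters = field(default_factory=CircuitParameters)
    topology: CircuitTopology = CircuitTopology.RE_NF
    doses: np.ndarray = field(default_factory=default_dose_ladder)
    sweep_name: str | None = None
    sweep_values: np.ndarray | None = None
    ci_method: str = "pchip_fit"
    ci_grid_n: int = 201
    ci_tol: float = 0.02
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_reps: int = 3
    seed: int = 0
    outdir: Path = Path("recflip_out")
    free_names: tuple[str, ...] = ("V_off",)
    tune_name: str = "d_X"
    tune_bracket: tuple[float, float] = (1e-2, 1e2)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "topology": self.topology.value,
            "doses": list(map(float, self.doses)),
            "sweep": (
                {"name": self.sweep_name, "values": list(map(float, self.sweep_values))}
                if self.sweep_name
                else None
            ),
            "ci": {"method": self.ci_method, "grid_n": self.ci_grid_n, "tol": self.ci_tol},
            "noise": {
                "cv_mult": self.noise.cv_mult,
                "bg_mean": self.noise.bg_mean,
                "bg_sd": self.noise.bg_sd,
                "seed": self.noise.seed,
            },
            "n_reps": self.n_reps,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "fit": {"free_names": list(self.free_names)},
            "tune": {"name": self.tune_name, "bracket": list(self.tune_bracket)},
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        known = {
            "params", "topology", "doses", "sweep", "ci", "noise",
            "n_reps", "seed", "outdir", "fit", "tune",
        }
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        try:
            if "params" in raw:
                cfg.params = CircuitParameters.from_dict(raw["params"])
            if "topology" in raw:
                cfg.topology = CircuitTopology(raw["topology"])
            if "doses" in raw:
                cfg.doses = np.asarray(raw["doses"], dtype=float)
            if "sweep" in raw and raw["sweep"]:
                sw = raw["sweep"]
                name = sw.get("name")
                if name not in CircuitParameters.field_names():
                    raise ConfigError(f"sweep.name {name!r} is not a parameter field")
                cfg.sweep_name = name
                cfg.sweep_values = _parse_grid(sw.get("values", sw.get("grid")))
            if "ci" in raw:
                ci = raw["ci"]
                cfg.ci_method = ci.get("method", cfg.ci_method)
                if cfg.ci_method not in ("pchip_fit", "direct"):
                    raise ConfigError(f"ci.method must be pchip_fit or direct")
                cfg.ci_grid_n = int(ci.get("grid_n", cfg.ci_grid_n))
                cfg.ci_tol = float(ci.get("tol", cfg.ci_tol))
            if "noise" in raw:
                cfg.noise = NoiseModel(**raw["noise"])
            cfg.n_reps = int(raw.get("n_reps", cfg.n_reps))
            cfg.seed = int(raw.get("seed", cfg.seed))
            if "outdir" in raw:
                cfg.outdir = Path(raw["outdir"])
            if "fit" in raw:
                names = tuple(raw["fit"].get("free_names", cfg.free_names))
                bad_names = set(names) - set(CircuitParameters.field_names())
                if bad_names:
                    raise ConfigError(f"fit.free_names not parameter fields: {sorted(bad_names)}")
                cfg.free_names = names
            if "tune" in raw:
                tn = raw["tune"].get("name", cfg.tune_name)
                if tn not in CircuitParameters.field_names():
                    raise ConfigError(f"tune.name {tn!r} is not a parameter field")
                cfg.tune_name = tn
                if "bracket" in raw["tune"]:
                    lo, hi = raw["tune"]["bracket"]
                    cfg.tune_bracket = (float(lo), float(hi))
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as e:
            raise ConfigError(f"malformed config: {e}") from e
        return cfg
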