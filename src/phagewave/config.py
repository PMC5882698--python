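"""Run configuration: YAML schema, validation, and the shipped presets.

A configuration has sections ``model``, ``landscape``, ``grid``, ``initial``,
``solver`` and ``output``.  Two presets encode the two reference simulation
regimes of the linear landscape ``k(r) = xi*r``:

``baseline``
    xi = 0.002 ml/(cell*day): the positive equilibrium of the underlying
    three-population model is stable at the seeded fitness (R0 ~ 1.5 at
    r = 1) and the evolutionary wave advances smoothly.

``enriched``
    xi = 0.02: R0 ~ 14.8 at r = 1, beyond the Hopf threshold of the
    underlying model, so all populations undergo self-sustained
    predator-prey oscillations while the wave keeps advancing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evolution_sim import EvoParams, InitialConditionSpec
from .model_core import BKParams
from .phenotype_space import (
    FitnessLandscape,
    LinearKLandscape,
    TabulatedLandscape,
    build_grid,
)

__all__ = ["RunConfig", "load_config", "PRESETS"]

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "model": {"alpha": float, "C": float, "q": float},
    "landscape": {
        "kind": str,
        "xi": float,
        "lam": float,
        "mu": float,
        "b": float,
        "tables": dict,
    },
    "grid": {"r_end": float, "n": int},
    "initial": {"center": float, "width": float, "total_phage": float},
    "solver": {"rtol": float, "atol": float, "bc": str, "first_step": float},
    "output": {"directory": str, "cadence_days": float, "snapshot_format": str},
}

_DEFAULTS: dict = {
    "model": {"alpha": 1.5, "C": 100.0, "q": 1e-6},
    "landscape": {"kind": "linear_k", "xi": 0.002, "lam": 3.0, "mu": 20.0, "b": 149.254},
    "grid": {"r_end": 20.0, "n": 4000},
    "initial": {"center": 1.0, "width": 0.05, "total_phage": 1.0},
    "solver": {"rtol": 1e-6, "atol": 1e-9, "bc": "no-flux", "first_step": 1e-4},
    "output": {"directory": "phagewave-run", "cadence_days": 5.0, "snapshot_format": "csv"},
}

PRESETS: dict[str, dict] = {
    "baseline": {},  # the defaults above *are* the baseline regime
    "enriched": {"landscape": {"xi": 0.02}},
}


@dataclass(frozen=True, eq=False)
class RunConfig:
    """Validated, fully resolved run configuration."""

    model: dict
    landscape: dict
    grid: dict
    initial: dict
    solver: dict
    output: dict

    def as_dict(self) -> dict:
        return {
            "model": dict(self.model),
            "landscape": dict(self.landscape),
            "grid": dict(self.grid),
            "initial": dict(self.initial),
            "solver": dict(self.solver),
            "output": dict(self.output),
        }

    # -- materialization ---------------------------------------------------
    def build_landscape(self) -> FitnessLandscape:
        ls = self.landscape
        if ls["kind"] == "linear_k":
            return LinearKLandscape(xi=ls["xi"], lam=ls["lam"], mu=ls["mu"], b=ls["b"])
        if ls["kind"] == "tabulated":
            # each trait is either an inline (r, value) table or a path to a
            # two-column CSV
            tables = {
                k: (np.loadtxt(v, delimiter=",", ndmin=2) if isinstance(v, str)
                    else np.asarray(v, dtype=float))
                for k, v in ls["tables"].items()
            }
            return TabulatedLandscape(tables)
        raise ValueError(f"unknown landscape kind {ls['kind']!r}")

    def build_evo_params(self) -> EvoParams:
        return EvoParams(
            alpha=self.model["alpha"],
            C=self.model["C"],
            q=self.model["q"],
            landscape=self.build_landscape(),
            grid=build_grid(self.grid["r_end"], self.grid["n"]),
            bc=self.solver["bc"],
            rtol=self.solver["rtol"],
            atol=self.solver["atol"],
        )

    def build_initial_spec(self) -> InitialConditionSpec:
        return InitialConditionSpec(**self.initial)

    def build_bk_params(self, at_r: float = 1.0) -> BKParams:
        """Reduce to the three-population ODE model at one phenotype coordinate."""
        ls = self.build_landscape()
        k, lam, mu, b = (float(v[0]) for v in ls.traits(np.asarray([at_r])))
        return BKParams(alpha=self.model["alpha"], C=self.model["C"], k=k, lam=lam, b=b, mu=mu)


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for section, value in override.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown configuration section {section!r}")
        if not isinstance(value, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        sub = out.setdefault(section, {})
        for key, v in value.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown configuration key {section}.{key}")
            sub[key] = v
    return out


def _validate(cfg: dict) -> list[str]:
    errors = []
    for section, keys in cfg.items():
        schema = _SCHEMA.get(section)
        if schema is None:
            errors.append(f"unknown section {section!r}")
            continue
        for key, value in keys.items():
            if key not in schema:
                errors.append(f"unknown key {section}.{key}")
                continue
            want = schema[key]
            if want is float and isinstance(value, (int, float)):
                continue
            if want is int and isinstance(value, int):
                continue
            if not isinstance(value, want):
                errors.append(
                    f"{section}.{key} must be {want.__name__}, got {type(value).__name__}"
                )
    m = cfg.get("model", {})
    for name in ("alpha", "C"):
        if m.get(name, 1.0) <= 0:
            errors.append(f"model.{name} must be > 0")
    if m.get("q", 0.0) < 0:
        errors.append("model.q must be >= 0")
    ls = cfg.get("landscape", {})
    if ls.get("kind") == "linear_k":
        for name in ("xi", "lam", "mu", "b"):
            if ls.get(name, 1.0) <= 0:
                errors.append(f"landscape.{name} must be > 0")
    g = cfg.get("grid", {})
    if g.get("r_end", 1.0) <= 0:
        errors.append("grid.r_end must be > 0")
    if g.get("n", 16) < 16:
        errors.append("grid.n must be >= 16")
    ini = cfg.get("initial", {})
    for name in ("center", "width", "total_phage"):
        if ini.get(name, 1.0) <= 0:
            errors.append(f"initial.{name} must be > 0")
    sv = cfg.get("solver", {})
    if sv.get("bc", "no-flux") not in ("robin", "no-flux"):
        errors.append("solver.bc must be 'robin' or 'no-flux'")
    return errors


def load_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a configuration.

    ``source`` may be a preset name (``"baseline"`` or ``"enriched"``), a
    path to a YAML file, or an already-parsed mapping.  Every section is
    filled in from the defaults; unknown sections or keys are rejected with
    the offending key named.
    """
    if isinstance(source, dict):
        raw = source
    elif str(source) in PRESETS:
        raw = PRESETS[str(source)]
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a preset ({', '.join(PRESETS)}) nor an existing file"
            )
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"configuration file {path} must contain a mapping")
    merged = _deep_update(_DEFAULTS, raw)
    errors = _validate(merged)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**{k: merged[k] for k in _SCHEMA})
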