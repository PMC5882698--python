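"""File output of simulation runs.

A run directory contains:

``scalars.csv``
    One row per output time: ``t,S,I_total,P_total,mean_k,mean_R0,wave_pos``
    (evolution runs) or ``t,S,I,P`` (plain ODE runs).

``i_field.csv``, ``p_field.csv``
    Snapshot matrices of the phenotype-space fields: first row holds the
    grid node coordinates (first cell blank), subsequent rows start with the
    output time followed by the nodal densities.

``manifest.json``
    The fully resolved configuration and solver statistics, for
    reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution_sim import EvoTrajectory

__all__ = ["write_outputs", "read_field_matrix", "read_scalars"]

_FLOAT_FMT = "%.12g"


def _write_field_matrix(path: Path, times, nodes, matrix: np.ndarray) -> None:
    header = "," + ",".join(_FLOAT_FMT % x for x in nodes)
    body = np.column_stack([np.asarray(times), matrix])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, delimiter=",", fmt=_FLOAT_FMT)


def read_field_matrix(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a snapshot matrix; returns ``(times, nodes, matrix)``."""
    with open(path) as fh:
        nodes = np.array([float(x) for x in fh.readline().split(",")[1:]])
        body = np.loadtxt(fh, delimiter=",", ndmin=2)
    return body[:, 0], nodes, body[:, 1:]


def read_scalars(run_dir) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "scalars.csv")


def write_outputs(trajectory, config, out_dir=None) -> Path:
    """Write a run to disk; returns the run directory.

    ``trajectory`` is an :class:`~phagewave.evolution_sim.EvoTrajectory` or a
    pandas DataFrame from :func:`~phagewave.model_core.simulate_ode`;
    ``config`` a :class:`~phagewave.config.RunConfig`.
    """
    out_dir = Path(out_dir if out_dir is not None else config.output["directory"])
    if isinstance(trajectory, EvoTrajectory):
        if len(trajectory.states) == 0:
            raise ValueError("refusing to write an empty trajectory")
        out_dir.mkdir(parents=True, exist_ok=True)
        scalars = trajectory.scalar_series()
        scalars.to_csv(out_dir / "scalars.csv", index=False, float_format=_FLOAT_FMT)
        nodes = trajectory.params.grid.nodes
        for name in ("i", "p"):
            _write_field_matrix(
                out_dir / f"{name}_field.csv",
                trajectory.times,
                nodes,
                trajectory.field_matrix(name),
            )
        stats = dict(trajectory.stats)
    elif isinstance(trajectory, pd.DataFrame):
        if trajectory.empty:
            raise ValueError("refusing to write an empty trajectory")
        out_dir.mkdir(parents=True, exist_ok=True)
        trajectory.to_csv(out_dir / "scalars.csv", index=False, float_format=_FLOAT_FMT)
        stats = {}
    else:
        raise TypeError(f"unsupported trajectory type {type(trajectory).__name__}")

    manifest = {"config": config.as_dict(), "solver_stats": stats}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
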