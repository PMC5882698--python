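"""Derived quantities of an evolution run.

Totals (integrals of the phenotype-space fields), quasi-species means of the
trait ``k(r)`` and of the Darwinian fitness ``R0(r)``, the position and speed
of the travelling wave in phenotype space, and detection of self-sustained
oscillations in scalar time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend, find_peaks, peak_prominences

from .phenotype_space import FitnessLandscape, Grid, variant_r0

__all__ = [
    "total_density",
    "mean_trait",
    "wave_position",
    "wave_speed",
    "detect_oscillations",
    "OscillationReport",
    "trajectory_summary",
]


def total_density(field: np.ndarray, grid: Grid) -> float:
    """Total population carried by a density field: trapezoid integral over r."""
    return grid.integrate(field)


def mean_trait(
    state,
    landscape: FitnessLandscape,
    trait: str,
    C: float,
    grid: Grid,
    weight: str = "i",
) -> float:
    """Density-weighted quasi-species mean of ``k(r)`` or ``R0(r)``.

    ``weight`` selects the weighting field: ``"i"`` (infected bacteria, the
    field the wave is usually plotted for — the default) or ``"p"`` (free
    phage).  The two agree closely because the phage distribution is slaved
    to the infected one.
    """
    if trait not in ("k", "R0"):
        raise ValueError(f"trait must be 'k' or 'R0', got {trait!r}")
    if weight not in ("i", "p"):
        raise ValueError(f"weight must be 'i' or 'p', got {weight!r}")
    w_field = np.asarray(getattr(state, weight), dtype=float)
    mass = grid.integrate(w_field)
    if mass <= 0:
        raise ValueError(f"weighting field {weight!r} has non-positive total mass")
    if trait == "k":
        values = landscape.traits(grid.nodes)[0]
    else:
        values = variant_r0(landscape, grid.nodes, C)
    return grid.integrate(values * w_field) / mass


def wave_position(state, grid: Grid, method: str = "centroid") -> float:
    """Location of the evolutionary wave in phenotype space.

    ``"centroid"`` (default) is the i-weighted mean of r, stable even when
    the amplitude oscillates; ``"argmax"`` is the peak node refined by a
    parabolic fit through its 3-point neighborhood.
    """
    i = np.asarray(state.i, dtype=float)
    if grid.integrate(np.abs(i)) <= 0:
        raise ValueError("i-field has zero mass; wave position undefined")
    if method == "centroid":
        return grid.integrate(grid.nodes * i) / grid.integrate(i)
    if method == "argmax":
        j = int(np.argmax(i))
        if j in (0, grid.n - 1):
            return float(grid.nodes[j])
        y0, y1, y2 = i[j - 1], i[j], i[j + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        return float(grid.nodes[j] + np.clip(delta, -1, 1) * grid.dr)
    raise ValueError(f"unknown method {method!r}; expected 'centroid' or 'argmax'")


def wave_speed(positions, times) -> np.ndarray:
    """Finite-difference speed of the wave (central; one-sided at the ends)."""
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if positions.size != times.size or positions.size < 2:
        raise ValueError("need matching position/time series with >= 2 samples")
    return np.gradient(positions, times)


@dataclass(frozen=True)
class OscillationReport:
    """Outcome of peak-based oscillation detection on a scalar series."""

    sustained: bool
    peak_times: np.ndarray
    mean_period: float | None
    amplitude_trend: float | None  # slope of peak prominence vs time, per day


def detect_oscillations(
    series,
    times,
    min_prominence_frac: float = 0.05,
    sustain_ratio: float = 0.5,
) -> OscillationReport:
    """Classify a scalar time series as sustained oscillation or not.

    Peaks are detected on the linearly detrended series with a minimum
    prominence of ``min_prominence_frac`` times the series range (to ignore
    solver ripple).  The oscillation counts as *sustained* when the last half
    of the record still contains at least 3 peaks and their median prominence
    has not collapsed relative to the whole record (``sustain_ratio``); this
    separates self-sustained cycles from decaying transients while remaining
    robust to the amplitude modulation the deep predator-prey cycles exhibit.
    The mean period is the mean inter-peak interval over all detected peaks.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size != times.size or series.size < 20:
        raise ValueError("need matching series/time arrays with >= 20 samples")
    rng = float(series.max() - series.min())
    if rng == 0.0:
        return OscillationReport(False, np.array([]), None, None)
    flat = detrend(series)
    idx, _ = find_peaks(flat, prominence=min_prominence_frac * rng)
    if idx.size == 0:
        return OscillationReport(False, np.array([]), None, None)
    peak_times = times[idx]
    prominences = peak_prominences(flat, idx)[0]
    mean_period = float(np.mean(np.diff(peak_times))) if idx.size >= 2 else None
    if idx.size >= 2:
        trend = float(np.polyfit(peak_times, prominences, 1)[0])
    else:
        trend = None
    t_half = times[0] + 0.5 * (times[-1] - times[0])
    late = prominences[peak_times >= t_half]
    sustained = bool(
        late.size >= 3
        and float(np.median(late)) >= sustain_ratio * float(np.median(prominences))
    )
    return OscillationReport(sustained, peak_times, mean_period, trend)


def trajectory_summary(traj) -> pd.DataFrame:
    """Scalar time series of a run: ``t, S, I_total, P_total, mean_k, mean_R0, wave_pos``."""
    params = traj.params
    grid, ls, C = params.grid, params.landscape, params.C
    rows = []
    for t, s in zip(traj.times, traj.states):
        i_mass = grid.integrate(s.i)
        # before any infection takes hold the quasi-species lives in the
        # phage field only; weight by p there so t=0 reflects the seed pulse
        weight = "i" if i_mass > 0 else "p"
        w_field = getattr(s, weight)
        has_mass = grid.integrate(w_field) > 0
        rows.append(
            dict(
                t=float(t),
                S=s.S,
                I_total=i_mass,
                P_total=grid.integrate(s.p),
                mean_k=mean_trait(s, ls, "k", C, grid, weight=weight) if has_mass else np.nan,
                mean_R0=mean_trait(s, ls, "R0", C, grid, weight=weight) if has_mass else np.nan,
                wave_pos=(
                    grid.integrate(grid.nodes * w_field) / grid.integrate(w_field)
                    if has_mass
                    else np.nan
                ),
            )
        )
    return pd.DataFrame(rows)
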