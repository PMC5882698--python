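"""Self-sustained oscillations under an enriched fitness landscape.

With the ten-fold steeper landscape slope (xi = 0.02) the seeded variant
already sits beyond the Hopf threshold of the underlying three-population
model, so all populations oscillate while the evolutionary wave keeps
advancing.  Shortened/coarsened for a quick demonstration.
"""

import numpy as np

import phagewave as pw

cfg = pw.load_config({"landscape": {"xi": 0.02}, "grid": {"r_end": 10.0, "n": 1000}})
params = cfg.build_evo_params()
traj = pw.simulate_evolution(params, cfg.build_initial_spec(), 400.0,
                             np.arange(0.0, 401.0, 2.0))
series = traj.scalar_series()

rep = pw.detect_oscillations(series["S"].to_numpy(), series["t"].to_numpy())
print(f"S(t) oscillations sustained: {rep.sustained}")
print(f"mean inter-peak period: {rep.mean_period:.1f} days "
      f"({rep.peak_times.size} peaks detected)")
print(f"S range in the last half: {series['S'].iloc[100:].min():.2e} .. "
      f"{series['S'].iloc[100:].max():.1f} cells/ml (deep predator-prey cycles)")
print(f"mean k still advances: {series['mean_k'].iloc[0]:.4f} -> "
      f"{series['mean_k'].iloc[-1]:.4f} ml/(cell*day)")
print("The wave survives the oscillations; only its speed is affected.")
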