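"""Accuracy as a function of integrator noise and working-memory leak.

Reproduces the model's two routes to errors: (i) raising the Wiener-noise
scale c of every integrator, and (ii) raising the leak k of the
working-memory units alone (at a small fixed noise, since with zero noise
the deterministic output-layer remnant of the guided turn still rescues
the choice).  Accuracy declines monotonically along both axes.
"""

from tmaze.simulate import sweep

print("noise sweep (k = w = 0.2):")
df_c = sweep("c", [0.0001, 0.01, 0.1, 0.3], replicates=10, duration=1000.0, seed=42)
print(df_c[["value", "mean_accuracy", "sd_accuracy", "n_sessions"]].to_string(index=False))

print()
print("working-memory leak sweep (c = 0.02):")
from tmaze.lca import ModelParams

df_k = sweep(
    "k", [0.2, 0.5, 1.0], replicates=10, duration=1000.0, seed=43,
    base_params=ModelParams(c=0.02),
)
print(df_k[["value", "mean_accuracy", "sd_accuracy", "n_sessions"]].to_string(index=False))

print()
print("mean_accuracy is the across-session fraction of correct choice "
      "trials; it falls from ~1.0 toward chance (~0.5) along both grids.")
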