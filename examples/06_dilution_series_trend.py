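"""Concentration-size trend of a microparticle dilution series.

Simulates three scatterer concentrations whose speckle grain grows with
concentration, measures the size per replicate, summarizes the groups
and fits the linear concentration trend with an explicit predictor
encoding.
"""

import numpy as np

from speckleflow import (
    SimulationConfig,
    compute_autocovariance,
    estimate_speckle_size,
    fit_concentration_trend,
    generate_static_speckle,
    summarize_groups,
)

PITCH_UM = 1.625
rng = np.random.default_rng(5)

# dilution index 1/2/3 -> designed grain means (um), slight upward trend
design = {1: 24.6, 2: 25.1, 3: 25.6}
groups: dict[str, list[float]] = {}
xs, ys = [], []
for index, mean_um in design.items():
    values = []
    for _ in range(5):
        grain_px = rng.normal(mean_um, 0.35) / PITCH_UM
        cfg = SimulationConfig(image_shape=(512, 512), grain_size_px=grain_px,
                               seed=int(rng.integers(2 ** 31)),
                               pixel_pitch_um=PITCH_UM)
        frame = generate_static_speckle(cfg)
        size = estimate_speckle_size(compute_autocovariance(frame), PITCH_UM)
        values.append(size.size_um)
        xs.append(index)
        ys.append(size.size_um)
    groups[f"dilution {index}"] = values

for s in summarize_groups(groups, units="um"):
    print(f"{s.label:<12} {s.mean:6.2f} +/- {s.sd:4.2f} {s.units} (n={s.n})")

fit = fit_concentration_trend(xs, ys, encoding="dilution-index")
print(f"\nlinear trend: size = {fit.slope:.2f} * x + {fit.intercept:.2f} "
      f"(x = {fit.encoding}, r = {fit.r_value:.2f})")
print()
print("Speckle size grows with particle concentration; the slope quantifies")
print("the um-per-dilution-step trend across the series.")
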