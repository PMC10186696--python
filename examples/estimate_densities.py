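"""Estimate circular activity densities with both estimators.

Fits the von Mises kernel density estimate and the AIC-selected nonnegative
trigonometric-sum density to a bimodal synthetic prey sample and reports the
activity peaks each finds.
"""

import numpy as np

from dieloverlap import (
    ScenarioConfig,
    fit_trig_sum,
    generate_observation_times,
    kde_circular,
)

sample = generate_observation_times(
    ScenarioConfig(seed=3, n_prey_obs=500), "prey"
)

for curve in (kde_circular(sample), fit_trig_sum(sample)):
    v = curve.values
    peaks = (v > np.roll(v, 1)) & (v > np.roll(v, -1))
    hours = np.sort(curve.grid[peaks] * 24 / (2 * np.pi))
    label = curve.meta["estimator"]
    print(f"{label}: integral = {curve.integral():.6f}, "
          f"activity peaks at " + ", ".join(f"{h:05.2f} h" for h in hours))
# Both estimators should integrate to 1 and place two peaks near the
# generating mixture's 07:30 and 18:30 activity modes.
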