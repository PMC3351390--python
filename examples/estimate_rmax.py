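"""Estimate the intrinsic population growth rate from a census time series.

A stochastic Ricker population (true r = 0.8, carrying capacity 100) is
simulated for 30 yearly censuses.  The estimator smooths the per-capita
growth rate against density with a cubic spline and reads it off at the
lowest observed density — the low-density limit of the R-function, which is
the population's R_max.
"""

import endopath as ep

series = ep.simulate_ricker(r=0.8, k_cap=100.0, sigma=0.1, t=30, n0=5.0, seed=4)
density, rates = ep.per_capita_rates(series)

print(f"census length: {len(series.abundance)}  density range: "
      f"{density.min():.1f}-{density.max():.1f}")
print(f"max observed per-capita rate: {rates.max():.3f} per year")

for strategy in ("low_density_spline", "max_smoothed_rate"):
    est = ep.estimate_rmax(series, strategy=strategy)
    print(f"R_max ({strategy}): {est:.3f} per year")
print("true Ricker r: 0.800 per year")
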