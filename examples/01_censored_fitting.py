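"""Fit censored distributions to an occurrence sample and select by AIC.

Builds a synthetic stand-in for a small seed-oil occurrence sample (14
samples, lognormal(-1.48, 1.20), LOD 0.035 ug/g), then fits censored
normal/lognormal/gamma/Weibull models to a larger redraw and picks the best
by AIC.
"""

import numpy as np

import oimtools as ot

fixture = ot.seed_oil_fixture(rng_seed=1)
print(f"seed-oil fixture: {fixture.n_samples} samples, "
      f"{int(fixture.data['censored'].sum())} below LOD")

# a small n=14 fit is unstable; fit a larger redraw from the same distribution
rng = np.random.default_rng(1)
values = rng.lognormal(-1.48, 1.20, 2000)
censored = values < 0.035
fits = ot.fit_all_families(values, censored, 0.035)
for fit in fits:
    print(f"  {fit.family:<10} AIC = {fit.aic:9.1f}  params = "
          + ", ".join(f"{k}={v:.3f}" for k, v in fit.params.items()))
best = ot.select_best_fit(fits)
print(f"best fit: {best.family} (lowest AIC)")
print("The lognormal should win: the data are lognormal, and its fitted "
      "(meanlog, sdlog) should sit near (-1.48, 1.20).")
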