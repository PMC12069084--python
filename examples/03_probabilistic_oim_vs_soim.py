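"""Probabilistic estimates: OIM vs sOIM confidence intervals.

On occurrence data that mix three subcategories with very different
contamination levels, stratifying the occurrence bootstrap (sOIM) leaves the
point estimate unchanged but narrows the percentile-method CI.
"""

import oimtools as ot

consumers = ot.simulate_consumers(500, rng_seed=1)
occurrence = ot.simulate_occurrence(ot.SimulationConfig(n_per_stratum=100),
                                    rng_seed=3)

for name in ("OIM", "sOIM"):
    est = ot.probabilistic_estimate(
        consumers, occurrence, ot.MethodSpec(name),
        B=1000, probs=(0.95,), seeds=(10, 20),
    )
    lo, hi = est.ci[0.95]
    print(f"{name:>4}: UTP DE = {est.de[0.95]:.3f} ug/kg bw/day, "
          f"95% CI = ({lo:.3f}, {hi:.3f}), width = {hi - lo:.3f}")
print("Same DE (both use the pooled mean of the original data); the "
      "stratified bootstrap removes between-stratum resampling noise, so "
      "the sOIM interval is the narrower one.")
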