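"""The full simulation-study grid with TDI risk characterization.

Runs OIM, sOIM, wsOIM* and the three wsOIM° sensitivity scenarios on
simulated occurrence datasets (scaled to 100 bootstrap replicates), then
compares each primary method's 95th-percentile exposure CI with the
Tolerable Daily Intake of 2 ug/kg bw/day and assesses robustness with the
tipping-point rule.
"""

import oimtools as ot

config = ot.SimulationConfig()  # B = 1000; scale 0.1 -> 100 replicates
consumers = ot.simulate_consumers(2830, rng_seed=1)

result = ot.run_study(config, consumers, scale=0.1, seed=42)
print(f"{result.n_replicates} bootstrap replicates per cell\n")
for label, cell in result.cells.items():
    est = cell.estimate
    lo, hi = est.ci[0.95]
    print(f"{label:<15} UTP = {est.utp:6.3f}  95% CI = ({lo:.3f}, {hi:.3f})")

print("\nrisk characterization vs TDI = 2 ug/kg bw/day:")
for method, verdict in ot.characterize_study(result).items():
    tip = f", tipped by {list(verdict.tipping_schemes)}" if not verdict.robust else ""
    print(f"  {method:<7} -> {verdict.verdict} "
          f"(robust: {verdict.robust}{tip})")
print("\nA conclusion of non-exceedance is 'not robust' when some "
      "sensitivity weighting (here the OO-dominated one) points to higher "
      "risk than the primary analysis showed.")
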