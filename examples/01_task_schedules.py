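"""Simulate the stable/volatile association task and check its contingencies.

Builds the default 180-trial design (80 stable trials at 75/25, then 100
volatile trials at 80/20 with a reversal every 20), prints where the
contingency reverses, and verifies the realized reward rates by Monte Carlo.
"""

import numpy as np

import revlearn as rl

design = rl.TaskDesign()
schedule = rl.make_schedule(design, seed=1)
print(f"trials: {len(schedule)} "
      f"(stable {np.sum(schedule.block == 'stable')}, "
      f"volatile {np.sum(schedule.block == 'volatile')})")
print("reversal trials:", rl.reversal_points(schedule))

hits = {"stable": 0, "volatile": 0}
totals = {"stable": 0, "volatile": 0}
for seed in range(500):
    s = rl.make_schedule(design, seed=seed)
    for block in hits:
        m = s.block == block
        hits[block] += int((s.rewarded_shape[m] == s.high_shape[m]).sum())
        totals[block] += int(m.sum())
for block in hits:
    print(f"{block} block: high shape rewarded on {100 * hits[block] / totals[block]:.2f}% "
          "of trials (design: 75% stable / 80% volatile)")
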