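"""Inject ERP components into noisy epochs and recover them.

Builds synthetic epochs for a small cohort (white noise at 1 µV plus
Gaussian-bump components), then extracts ERN, FRN, P300 and N2pc with the
standard recipe: baseline correction, ±80 µV artifact rejection, per-
condition averaging, windowed signed peak.  Extracted group means should
track the injected ones: P300 smaller and N2pc more negative under OT.
"""

import revlearn as rl

spec = rl.CohortSpec(n_ot=15, n_plc=15, erp=rl.ErpSpec(noise_sd=1.0, n_per_condition=60))
study = rl.draw_cohort(spec, seed=5)
bundle = rl.generate_epochs(study)

scores = bundle.score_table()
print("group-mean extracted amplitudes (µV):")
print(scores.groupby("group")[["ERN", "FRN", "P300", "N2PC"]].mean().round(2).to_string())
print("\ninjected group means: P300 3.75 (OT) vs 5.57 (PLC); N2pc -0.29 vs 0.18")

merged = scores.merge(bundle.amplitudes, on=["subject", "group"], suffixes=("_ext", "_inj"))
for comp in ("ERN", "FRN", "P300", "N2PC"):
    err = (merged[f"{comp}_ext"] - merged[f"{comp}_inj"]).abs().mean()
    print(f"{comp}: mean |extracted - injected| = {err:.2f} µV")

es = bundle.epochs(bundle.subjects()[0], "N2PC")
res = rl.n2pc_score(es)
print(f"\none subject's N2pc: peak {res.score:.2f} µV at {res.latency_ms:.0f} ms "
      "(contra minus ipsi, 200-252 ms)")
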