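"""Simulate RP-model agents and score their optimal-choice accuracy.

An agent with high learning rates and high choice consistency (inverse
temperature beta) tracks the high-reward shape well; a beta = 0 agent
chooses at random.  Accuracy counts choices of the currently optimal shape,
not rewarded trials.
"""

import numpy as np

import revlearn as rl

schedule = rl.make_schedule(rl.TaskDesign(), seed=3)

agents = {
    "sharp (a+=.8, a-=.7, beta=8)": rl.RLParams(0.8, 0.7, 8.0),
    "typical (a+=.4, a-=.3, beta=3)": rl.RLParams(0.4, 0.3, 3.0),
    "random (beta=0)": rl.RLParams(0.4, 0.3, 0.0),
}
for label, params in agents.items():
    accs = []
    for seed in range(100):
        trials = rl.simulate_choices(schedule, params, "RP", seed=seed)
        accs.append(rl.choice_accuracy(trials, schedule))
    print(f"{label:34s} accuracy = {np.mean(accs):.3f}")

trials = rl.simulate_choices(schedule, agents["typical (a+=.4, a-=.3, beta=3)"], seed=0)
nll = rl.negative_log_likelihood(trials, rl.RLParams(0.4, 0.3, 3.0))
print(f"\nNLL of the generating parameters on one run: {nll:.2f} "
      f"(chance level {len(trials) * np.log(2):.2f})")
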