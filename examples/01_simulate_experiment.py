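"""Simulate a formant-perturbation session and inspect its structure.

Generates one study (8 speakers, 120 trials each, 50% perturbed with
~115-mel F1 shifts), writes the long-format trial table, and tallies the
analysis roles: perturbed trials carry the shift, trials directly after
them carry one-shot adaptation, and unperturbed-after-unperturbed trials
form the baseline.
"""

from collections import Counter

from f1adapt import Role, SimConfig, generate_experiment, label_trials, write_trials

cfg = SimConfig(n_participants=8, n_trials=120, seed=1)
trials, truth = generate_experiment(cfg)
write_trials(trials, "simulated_trials.csv")

labels = label_trials(trials)
counts = Counter(role.value for roles in labels.values() for role in roles)
print(f"{len(trials)} trials from {cfg.n_participants} participants")
for role in ("perturbed_up", "perturbed_down", "post_up", "post_down",
             "baseline_comp", "baseline_adapt"):
    print(f"  {role:16s} {counts[role]:4d}")
print("\nper-participant ground truth (first rows):")
print(truth.participants.head(3).round(4).to_string(index=False))
# comp_gain ~ 0.04 means the speaker opposes ~4% of the applied shift
# within the trial; adapt_gain is the fraction opposed at the start of
# the *next* trial.
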