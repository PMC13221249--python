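"""Simulate a small cohort and inspect its ground truth.

Builds two synthetic participants for the 2x2x2 prosocial reward design and
prints the injected versus realized reward-magnitude effect on the reward
positivity.
"""

import numpy as np

import prosorew as pr

design = pr.DesignSpec(n_participants=2, n_trials_per_cell=8,
                       sampling_rate=250.0)
effects = pr.default_effects()
noise = pr.NoiseSpec()

cohort = pr.simulate_cohort(design, effects, noise, master_seed=7)

print(f"{len(cohort)} participants, {cohort[0].epochs.n_trials} trials each, "
      f"{cohort[0].epochs.n_channels} channels at "
      f"{cohort[0].epochs.sfreq:.0f} Hz")

injected = effects.families["rewp"].coeffs["magnitude"]
print(f"population magnitude coefficient on the RewP: {injected:+.2f} uV")
for b in cohort:
    realized = b.truth.participant_coeffs["rewp"][2]  # magnitude term
    print(f"  {b.epochs.participant_id}: realized coefficient "
          f"{realized:+.2f} uV (population value plus this participant's "
          "random slope)")
print("ratings (1-9 liking scale), participant 0:")
print(cohort[0].ratings[["beneficiary", "magnitude", "time", "rating"]]
      .to_string(index=False))
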