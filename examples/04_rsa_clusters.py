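"""Time-resolved RSA with cluster permutation inference.

Simulates a cohort whose beneficiary signal exists only on immediate
trials, runs the split-design RSA (4x4 Mahalanobis RDMs within each reward
time level, regression on z-scored model RDMs), and tests the coefficient
time series against zero with the sign-flip cluster permutation test.
"""

import numpy as np

import prosorew as pr

A = 2.5
effects = pr.EffectSpec(families={
    "rewp": pr.synth.FamilyEffect(
        coeffs={"intercept": 6.0, "beneficiary": A,
                "beneficiary:time": -2.0 * A},   # effect only when immediate
        participant_sd={"intercept": 1.0},
        trial_noise_sd=3.0,
        shape=pr.synth.ComponentShape(peak_ms=318.0, fwhm_ms=100.0,
                                      channel="FCz")),
})
design = pr.DesignSpec(n_participants=16, n_trials_per_cell=12,
                       sampling_rate=250.0, epoch_window=(-200.0, 1000.0))
cohort = pr.simulate_cohort(design, effects,
                            pr.NoiseSpec(pink_amplitude=8.0), master_seed=21)
epochs = [pr.baseline_subtract(b.epochs, (-200, 0)) for b in cohort]

split = pr.rsa_by_time_condition(epochs)
times = epochs[0].times
for level in ("immediate", "delayed"):
    res = pr.cluster_permutation(split[level]["beneficiary"], times,
                                 n_perm=1000, seed=1)
    sig = res.significant(0.05)
    if sig:
        for c in sig:
            print(f"{level}: beneficiary coding cluster "
                  f"{c.start_ms:.0f}-{c.end_ms:.0f} ms, p = {c.p:.3f}")
    else:
        print(f"{level}: no significant beneficiary coding cluster")
print("interpretation: the neural geometry separates self from other only "
      "while rewards are immediate - the injected pattern.")
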