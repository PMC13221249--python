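"""Morlet power with welding-baseline normalization.

Decomposes one participant's epochs at the two band-power ROI channels,
pools the -500..-300 ms baseline power of all trials into the welding
reference, and scores single-trial delta (1-3 Hz, 200-500 ms, CPz) and
theta (4-7 Hz, 150-450 ms, FCz) power in welded-z units.
"""

import numpy as np

import prosorew as pr

design = pr.DesignSpec(n_participants=1, n_trials_per_cell=8,
                       sampling_rate=250.0)
bundle = pr.simulate_participant(design, pr.default_effects(), pr.NoiseSpec(),
                                 seed=11)

raw = pr.morlet_transform(bundle.epochs, channels=["FCz", "CPz"])
print(f"raw power array: trials x channels x freqs x times = "
      f"{raw.power.shape}")

z = pr.weld_baseline(raw, (-500, -300))
for name, band, window, roi in (pr.tfr.DELTA_MEASURE, pr.tfr.THETA_MEASURE):
    s = pr.score_band_power(z, band, window, roi, name=name)
    by_mag = s.table.groupby("magnitude")["value"].mean()
    print(f"{name} ({band[0]:g}-{band[1]:g} Hz at {roi[0]}): "
          f"large {by_mag['large']:+.2f} z, small {by_mag['small']:+.2f} z")
print("welded-z units: SDs of the trial-pooled baseline power distribution; "
      "positive values mean power above the pre-feedback level.")
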