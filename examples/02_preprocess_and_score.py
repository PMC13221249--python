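"""Preprocess one participant and score single-trial ERP amplitudes.

Re-references to the averaged mastoids, screens artifacts with the
four-rule detector, band-pass filters, subtracts the prestimulus baseline,
and reads out single-trial RewP (260-360 ms, Fz/FCz) and P3 (320-420 ms,
CPz/Pz) amplitudes.
"""

import numpy as np

import prosorew as pr

design = pr.DesignSpec(n_participants=1, n_trials_per_cell=8,
                       sampling_rate=250.0)
noise = pr.NoiseSpec(artifact_rates={"step": 0.05, "drift": 0.05})
bundle = pr.simulate_participant(design, pr.default_effects(), noise, seed=3)

e = pr.rereference_mastoids(bundle.epochs)
clean, report = pr.reject_artifacts(e)
print(f"artifact screen kept {report.retained_fraction:.1%} of "
      f"{e.n_trials} trials")
for i, rules in enumerate(report.rules_fired):
    if rules:
        print(f"  trial {i} rejected by: {', '.join(rules)}")

clean = pr.filter_bandpass(clean, 0.1, 35.0)
clean = pr.baseline_subtract(clean, (-200, 0))

for measure in (pr.REWP, pr.P3):
    scores = pr.score_single_trial(clean, measure)
    by_mag = scores.table.groupby("magnitude")["value"].mean()
    print(f"{measure.name}: mean {by_mag['large']:+.2f} uV (large) vs "
          f"{by_mag['small']:+.2f} uV (small) -> reward effect "
          f"{by_mag['large'] - by_mag['small']:+.2f} uV")
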