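"""Synthetic cohort generation and growth-rate recovery.

Draws patients whose two exam diameters follow the exponential growth
law with multiplicative lognormal measurement noise, then re-estimates
each TVDT and checks how often the drawn subtype band is recovered.
"""

import warnings

import numpy as np

from compas_bc import BandRegistry, CompasError, synth_cohort, tvdt_from_measurements

registry = BandRegistry.default()
records, truth = synth_cohort(n=500, seed=42, sigma=0.05)

recovered, unestimable, errors = 0, 0, []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for rec, t in zip(records, truth):
        try:
            rate = tvdt_from_measurements(rec.first_exam, rec.second_exam)
        except CompasError:
            unestimable += 1
            continue
        errors.append(abs(rate.tvdt_days - t["tvdt_days"]))
        if registry.band_for_tvdt(rate).band_id == t["band_id"]:
            recovered += 1

print(f"cohort:            {len(records)} records, diameter noise sigma = 0.05")
print(f"band recovered:    {recovered}/{len(records)} ({recovered / len(records):.1%})")
print(f"not estimable:     {unestimable} (noise masked the growth)")
print(f"median |TVDT err|: {np.median(errors):.1f} days")

noiseless, truth0 = synth_cohort(n=200, seed=7, sigma=0.0)
max_rel = max(
    abs(tvdt_from_measurements(r.first_exam, r.second_exam).tvdt_days - t["tvdt_days"])
    / t["tvdt_days"]
    for r, t in zip(noiseless, truth0)
)
print(f"noiseless recovery: max relative TVDT error {max_rel:.2e}")
print(
    "\nReading: without noise the Schwartz estimator inverts the growth law"
    "\nexactly. With 5% diameter noise and 60-365 day exam gaps the TVDT"
    "\nsampling error often exceeds the 30-40 day width of the slow bands,"
    "\nso band recovery sits near 50% - two well-separated exams matter more"
    "\nthan measurement precision."
)
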