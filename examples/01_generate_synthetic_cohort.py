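"""Generate a small synthetic cohort and inspect its respiratory content.

Builds six respiratory-modulated PPG records (two per breathing group),
verifies that the band-passed signal peaks at each subject's breathing
frequency, and writes the cohort to disk in the BIDMC CSV dialect.
"""

import numpy as np

from ppgrr import FilterSpec, make_cohort
from ppgrr.io import write_bidmc_record
from ppgrr.preprocess import apply_filter, design_bandpass

records = make_cohort(n_subjects=6, group_mix=(1 / 3, 1 / 3, 1 / 3),
                      duration_s=120.0, fs=125.0, seed=0)
coeffs = design_bandpass(FilterSpec(), 125.0)

print("subject      true RR   spectral peak of band-passed PPG")
for rec in records:
    filtered = apply_filter(rec.ppg, coeffs)
    freqs = np.fft.rfftfreq(filtered.size, 1 / 125.0)
    peak_hz = freqs[np.argmax(np.abs(np.fft.rfft(filtered - filtered.mean())) ** 2)]
    rr = rec.demographics["rr_brpm"]
    print(f"{rec.subject_id}    {rr:6.2f} brpm   {peak_hz * 60:6.2f} brpm")
    write_bidmc_record(rec, "scratch/example_cohort")

print("\nEach spectral peak should sit near the configured RR: the generator's")
print("baseline wander and amplitude modulation place respiratory energy at")
print("RR/60 Hz, which the 0.1-0.4 Hz band-pass isolates.")
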