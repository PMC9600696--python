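"""Generate a small synthetic EEG dataset and inspect its spectral contrast.

Builds 60 records (two classes, six subjects each, 14 channels x 512
samples at 128 Hz), writes them as plain-text matrices plus a CSV
manifest, and prints the per-class theta and beta band powers that carry
the class signal.
"""

import numpy as np
from scipy.signal import welch

from eegmotif import SynthConfig, generate_dataset

cfg = SynthConfig(n_subjects_per_class=6, records_per_subject=5, seed=42)
records, manifest = generate_dataset(cfg, out_dir="scratch/example_dataset")
print(f"wrote {len(records)} records, manifest at {manifest}")


def band_power(x, fs, lo, hi):
    f, p = welch(x, fs=fs, nperseg=256)
    mask = (f >= lo) & (f <= hi)
    return np.trapezoid(p[mask], f[mask])


for band, (lo, hi) in {"theta": (4, 8), "beta": (13, 30)}.items():
    for label, name in ((1, "healthy"), (2, "adhd-like")):
        powers = [
            band_power(r.data[0], r.sample_rate, lo, hi)
            for r in records
            if r.label == label
        ]
        print(f"{band:5s} {name:10s} median power {np.median(powers):8.2f} uV^2")

print(
    "\nThe adhd-like class carries ~1.8x theta and ~0.6x beta power, the\n"
    "spectral contrast the downstream feature pipeline must pick up."
)
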