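"""Detect an adapter-dimer peak in a cDNA-library electropherogram.

Simulates an Ion Torrent-style trace with the library peak near 110 bp and
a contamination peak near 88 bp, then calls both peaks and reports the
dimer-to-library signal ratio — the pre-sequencing warning that a library
should be cleaned up before it is run.
"""

import numpy as np

from dimerqc import DEFAULT_WINDOWS, detect_dimer_peak, simulate_trace

x = np.arange(50.0, 200.0, 0.25)
trace = simulate_trace(
    peaks=[(88.0, 2.5, 120.0), (110.0, 3.0, 300.0)],
    noise_sd=0.5, x_grid=x, seed=5,
)

windows = DEFAULT_WINDOWS["iontorrent"]
dimer, library, ratio = detect_dimer_peak(
    trace, windows["dimer"], windows["library"]
)

print(f"dimer peak  : center {dimer.center:.2f} bp, area {dimer.area:.1f}")
print(f"library peak: center {library.center:.2f} bp, area {library.area:.1f}")
print(f"dimer ratio : {ratio:.3f}")
print(
    "\nAbout a quarter of the callable signal sits in the dimer peak: this "
    "library would waste a corresponding share of sequencing capacity on "
    "adapter dimers unless size-selected again."
)
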