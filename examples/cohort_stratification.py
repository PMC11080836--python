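"""Stratify a cohort by read loss and decompose the loss by cause.

Builds a 40-sample cohort whose ordered read-loss profile has two regimes
(a shallow slope of ~1%/rank for most samples, ~6%/rank for a contaminated
tail), fits exhaustive piecewise OLS with BIC model selection, and prints
the recovered segments plus each sample's dominant loss cause.
"""

import numpy as np
import pandas as pd

from dimerqc import CohortTable, decompose_loss, segment_by_read_loss

rng = np.random.default_rng(11)
ranks = np.arange(1, 41)
loss = np.where(ranks <= 33, 5 + 1.0 * ranks, 38 + 6.0 * (ranks - 33))
loss = np.sort(np.clip(loss + rng.normal(0, 1, 40), 0, 100))
# contaminated tail is dimer-driven, the rest mostly short reads
dimer_share = np.where(loss > 40, 0.85, 0.3)
table = CohortTable(pd.DataFrame({
    "sample_id": [f"s{i:02d}" for i in range(40)],
    "pct_read_loss": loss,
    "pct_dimer": loss * dimer_share,
    "pct_short": loss * (1 - dimer_share),
    "pct_lowq": 0.0,
}))

seg = segment_by_read_loss(table)
print(f"segments selected by BIC: {len(seg.segments)}")
for i, s in enumerate(seg.segments, 1):
    print(f"  segment {i}: ranks {s.start + 1}-{s.stop}, "
          f"slope {s.slope:.3f} %/rank, R^2 {s.r_squared:.3f}")

decomp = decompose_loss(table)
tail = decomp.iloc[-5:]
print("\ndominant loss cause, highest-loss samples:")
for _, r in tail.iterrows():
    print(f"  {r.sample_id}: {r.dominant} "
          f"(dimer fraction of loss {r.frac_dimer:.2f})")

print(
    "\nThe steep segment isolates the contaminated subgroup: its read loss "
    "grows several-fold faster per rank and is dominated by adapter dimers."
)
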