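"""Cohort-style statistics: summaries, paired tests, frequency tables.

Builds a small paired dataset (band thickness per biopsy under H&E vs a
connective stain), reports the frequency-table convention with
not-assessed denominators, runs the exact Wilcoxon-Pratt signed-rank
pairwise comparison, and shows the Bonferroni reporting threshold.
"""

import numpy as np
import pandas as pd

from ielquant import (
    PairedSample,
    bonferroni,
    frequency_table,
    paired_t,
    pairwise_comparison_report,
    summarize,
)

rng = np.random.default_rng(3)

# paired IEL counts: H&E reading vs CD3 reading per subject
he = rng.poisson(3.0, size=30).astype(float)
cd3 = he + rng.poisson(2.0, size=30)
s = summarize(cd3)
print(f"CD3 IELs/100: mean {s.mean:.1f} (95% CI {s.ci_low:.1f}-{s.ci_high:.1f}, range {s.min:.0f}-{s.max:.0f})")
t = paired_t(PairedSample(range(30), cd3, he))
print(f"paired t-test CD3 vs H&E: t={t.statistic:.2f}, p={t.p_value:.2g} (n={t.n_used})")

# band thickness frequency table with a not-assessed biopsy
band_um = [1] * 24 + [2] * 5 + [0] * 1 + ["NOT_ASSESSED"]
table = frequency_table(band_um, categories=[0, 1, 2, 3])
print("\nband thickness n (%) — denominator excludes not-assessed:")
print(table.to_string(index=False), f"\nnot assessed: {table.attrs['not_assessed_n']}")

# pairwise stain comparison, Wilcoxon-Pratt, Bonferroni-adjusted
rows = []
for i in range(30):
    rows.append({"subject": i, "condition": "HE", "value": 0.0})
    rows.append({"subject": i, "condition": "VG", "value": float(rng.integers(1, 3))})
report = pairwise_comparison_report(pd.DataFrame(rows), [("HE", "VG")])
print(f"\nHE vs VG band thickness: p = {report.p_values.iloc[0, 0]:.2g} "
      f"({report.methods.iloc[0, 0]}), significant at {bonferroni(0.05, 6)}")
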