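"""Apply an exclusion rule to an empirical-style RT table.

Builds a small two-condition RT table (as an experiment would export:
identifier, condition, RT in ms) with a handful of implausible trials,
applies the mean +/- 2 SD rule within each condition, and prints the
per-condition report a study should include when describing its outlier
handling.
"""

import numpy as np
import pandas as pd

from rtexclude import exclude_table

rng = np.random.default_rng(3)
rows = []
for cond, mu in (("congruent", 420.0), ("incongruent", 470.0)):
    rts = rng.normal(mu, 35.0, 48) + rng.exponential(160.0, 48)
    rts = np.r_[rts, [2950.0, 3400.0, 95.0]]  # slow lapses and a fast guess
    rows.append(pd.DataFrame({"identifier": "s01", "condition": cond, "rt": rts}))
table = pd.concat(rows, ignore_index=True)

annotated, report = exclude_table(table, "2sd")
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
excluded = annotated[~annotated["kept"]]
print("\nexcluded trials:")
print(excluded[["condition", "rt", "tail"]].to_string(index=False))
print("\nReport the low/high-tail shares per condition alongside the rule used;")
print("that is what makes the outlier handling of a study reproducible.")
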