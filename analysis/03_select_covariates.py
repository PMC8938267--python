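"""High-dimensional covariate screen: rank sparse diagnosis/medication/
laboratory codes by univariate relative risk against exposure.

Finding to expect: the age-linked codes (the generator ties ~20% of codes
to age, which is exposure-shifted) dominate the top of the ranking.
"""

import pandas as pd
from common import RESULTS, SPEC, load_cohort

from postacute.config import RunConfig
from postacute.covariates import rank_high_dim
from postacute.pipeline import prepare_persons

K, MIN_COUNT = 40, 50  # scaled to the demonstration cohort's size

tables = load_cohort()
prepared = prepare_persons(tables, RunConfig(seed=1), SPEC)
comp = prepared[prepared["group"].isin(["exposed", "contemporary"])]
labels = pd.Series((comp["group"] == "exposed").to_numpy(),
                   index=comp["person_id"])

sel = rank_high_dim(tables.codes, labels, min_count=MIN_COUNT, k=K)
report = sel.candidates.assign(rank=range(1, len(sel.candidates) + 1),
                               selected=lambda d: d["code"].isin(sel.selected))
report.to_csv(RESULTS / "covariate_selection.csv", index=False)

print(f"{len(report)} candidate codes met the min-count threshold "
      f"({MIN_COUNT}/group); selected top {len(sel.selected)} by |log RR|")
print(report.head(10).to_string(index=False))
print(f"wrote {RESULTS / 'covariate_selection.csv'}")
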