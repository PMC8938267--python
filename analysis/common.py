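"""Shared study definition for the demonstration analysis.

One synthetic world is used by every numbered driver: three groups of
12,000, a care-setting-graded stroke effect, two further cardiovascular
outcomes with known hazard ratios, a positive outcome control (fatigue,
HR 1.5), two designed-null outcomes for the negative-control battery, and a
long enough pre-enrollment hazard runway to populate the
difference-in-differences pre-period.  Baseline event rates are arbitrary
defaults in a plausible range for an older, comorbid population.
"""

from pathlib import Path

import numpy as np

from postacute import CohortSpec, SimConfig, generate_cohort
from postacute.simulate import CohortTables

RESULTS = Path(__file__).resolve().parent.parent / "results"
#: raw simulated tables are bulky scratch artifacts, regenerated on demand;
#: only the summary tables under results/ are kept
COHORT_DIR = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 20_220_207

STUDY = SimConfig(
    n_exposed=12_000, n_contemporary=12_000, n_historical=12_000,
    n_noise_codes_per_domain=(60, 60, 20),
    true_log_hr={
        "stroke": {"non_hospitalized": float(np.log(1.3)),
                   "hospitalized": float(np.log(1.9)),
                   "icu": float(np.log(2.6))},
        "mi": float(np.log(1.6)),
        "heart_failure": float(np.log(1.7)),
        "fatigue": float(np.log(1.5)),
        "neg_control_a": 0.0,
        "neg_control_b": 0.0,
    },
    baseline_hazard={
        "stroke": 2.0e-4, "mi": 1.5e-4, "heart_failure": 2.5e-4,
        "fatigue": 4.0e-4, "neg_control_a": 1.5e-4, "neg_control_b": 1.5e-4,
    },
    clock_back_days=1100,
    seed=SEED,
)

SPEC = CohortSpec()
OUTCOMES = ["stroke", "mi", "heart_failure"]


def load_cohort() -> CohortTables:
    """Read the simulated tables, generating them if 01 has not run yet."""
    if (COHORT_DIR / "persons.csv").exists():
        return CohortTables.read(COHORT_DIR)
    tables = generate_cohort(STUDY)
    tables.write(COHORT_DIR)
    return tables
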