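"""Control batteries: negative outcomes, a positive outcome (fatigue), and
the influenza-vaccination calendar-parity negative exposure.

Finding to expect: both designed-null outcomes non-significant, fatigue
clearly detected, and no significant association in the parity split.
"""

from common import RESULTS, SPEC, load_cohort

from postacute.config import RunConfig
from postacute.controls import ControlSpec, run_battery

tables = load_cohort()
specs = [
    ControlSpec("negative_outcome", "neg:neg_control_a", "nonsignificant",
                outcome="neg_control_a"),
    ControlSpec("negative_outcome", "neg:neg_control_b", "nonsignificant",
                outcome="neg_control_b"),
    ControlSpec("positive_outcome", "pos:fatigue", "significant_gt1",
                outcome="fatigue"),
    ControlSpec("negative_exposure", "flu-parity", "nonsignificant"),
]
report = run_battery(specs, tables, RunConfig(k_highdim=0, seed=1), SPEC,
                     outcomes_for_exposure_controls=["neg_control_a",
                                                     "neg_control_b"])
report.to_csv(RESULTS / "controls.csv", index=False)
print(report.round(3).to_string(index=False))
met = report["met"].all()
print(f"all a-priori expectations met: {met}")
print(f"wrote {RESULTS / 'controls.csv'}")
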