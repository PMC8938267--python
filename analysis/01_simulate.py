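"""Generate the demonstration cohort and report its shape.

Writes persons/events/codes tables plus the generating configuration under
results/cohort/ so every later step runs off the same frozen tables.
"""

from common import COHORT_DIR, STUDY

from postacute import generate_cohort

tables = generate_cohort(STUDY)
tables.write(COHORT_DIR)

persons = tables.persons
print(f"wrote {COHORT_DIR}")
print(f"persons: {len(persons)} "
      f"({(persons['group'] == 'exposed').sum()} exposed / "
      f"{(persons['group'] == 'contemporary').sum()} contemporary / "
      f"{(persons['group'] == 'historical').sum()} historical)")
print(f"event records: {len(tables.events)}; "
      f"code occurrences: {len(tables.codes)}")
print("care settings among exposed:")
print(persons.loc[persons['group'] == 'exposed', 'care_setting']
      .value_counts().to_string())
print(f"deaths recorded: {persons['death_date'].notna().sum()}; "
      f"vaccinated: {persons['vaccination_date'].notna().sum()}")
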