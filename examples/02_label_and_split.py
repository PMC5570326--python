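"""From raw observations to labeled time-point samples.

Every (patient, date) laboratory panel within a year of death becomes one
sample; for a horizon of n months it is an event if death occurred within
n months of the draw, a control otherwise.  Patients are split 50/50 into
training and test cohorts so no patient leaks across the boundary.
"""

import sapmodels as sm

patients, observations = sm.generate_cohort(sm.default_config(
    n_patients=200, n_items=12, seed=42))

panel = sm.filter_items(observations, min_coverage=0.5)
print(f"retained panel ({len(panel.retained_items)} items): "
      f"{', '.join(panel.retained_items)}")

samples = sm.assemble_time_points(
    sm.filter_to_panel(observations, panel), patients)
print(f"{len(samples)} time-point samples from {len(patients)} patients")

train_ids, test_ids = sm.split_patients(patients, test_fraction=0.5, seed=42)
print(f"train {len(train_ids)} / test {len(test_ids)} patients")

days = samples["days_to_death"].to_numpy()
print("\nhorizon  events  controls   (event = death within n months of draw)")
for n in range(1, 7):
    labels = sm.label_for_horizon(days, n)
    print(f"   {n} mo  {(labels == 'event').sum():6d}  "
          f"{(labels == 'control').sum():8d}")
# Event counts grow with the horizon because the event window widens while
# the total window stays fixed at one year.
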