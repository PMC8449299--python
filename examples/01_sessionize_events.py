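"""Turn raw audit-log events into work intervals.

Uses the bundled 12-event example (two HCWs, two patients) with a 120 s gap
cutoff, then shows automatic cutoff estimation on a synthetic log: the knee
of the interval-count-versus-cutoff curve separates within-task gaps
(seconds) from between-task gaps (tens of minutes).
"""

from ehrcollab import datasets, sessionize, simulate

events = datasets.example_audit_events()
intervals = sessionize.build_intervals(events, cutoff_s=120)
print("Intervals at a 120 s cutoff:")
print(intervals[["hcw_id", "patient_id", "start", "stop", "duration_s", "n_events"]])
# HCW A's 203 s pause splits their six events in two; HCW B's evenly spaced
# events stay one 480 s interval.

sim = simulate.generate(simulate.SimConfig(seed=0))
curve = sessionize.cutoff_curve(sim.events)
print(f"\nSynthetic log: {len(sim.events)} events")
print(f"Estimated gap cutoff (knee point): {curve.knee:.0f} s")
print("The knee sits between the generator's 30 s within-burst and 1200 s "
      "between-burst gap scales, where the interval count stops falling steeply.")

workdays = sessionize.flag_workdays(
    sessionize.build_intervals(sim.events, curve.knee), workday_cutoff_min=15
)
print(f"HCW-days with any activity: {len(workdays)}; "
      f"active (>=15 min in the EHR): {int(workdays['active'].sum())}")
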