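"""Detect concurrent sessions: overlapping intervals on a shared patient.

Two or more HCWs whose intervals on the same patient's record positively
overlap form a concurrent session — the unit of latent collaboration.
"""

from ehrcollab import concurrency, sessionize, simulate

sim = simulate.generate(simulate.SimConfig(seed=0))
intervals = sessionize.build_intervals(sim.events, cutoff_s=120)
pairs = concurrency.find_overlap_pairs(intervals)
sessions, membership = concurrency.assemble_sessions(intervals, pairs)
labeled, counts = concurrency.label_intervals(intervals, membership)

print(f"{len(intervals)} intervals -> {len(pairs)} overlapping pairs -> "
      f"{len(sessions)} concurrent sessions")
print(f"concurrent intervals: {counts['concurrent']}, "
      f"individual: {counts['individual']}")
print("\nLargest sessions (most member intervals):")
print(sessions.nlargest(3, "n_intervals")[
    ["session_id", "patient_id", "n_intervals", "n_hcws"]
])

mats = concurrency.build_matrices(labeled, sessions)
print(f"\nIntermediate matrices over {len(mats.interval_ids)} concurrent "
      f"intervals: interval x action {mats.interval_action.shape}, "
      f"HCW x session {mats.hcw_session.shape}")
# Each interval-x-session row sums to 1 (membership is a partition) and each
# HCW-x-session column has >=2 entries (a session needs two HCWs).
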