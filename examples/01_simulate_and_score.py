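"""Generate one synthetic night and score its CAP structure from the truth.

Builds a 10-minute, single-channel synthetic EEG record with known A-phase
events and macrostructure, rasterizes the ground truth onto the 1 s epoch
grid, and runs the CAP scoring FSM on the true labels. The printed CAP rate
is total CAP time over total NREM time — the sleep-quality metric the
pipeline ultimately estimates.
"""

from capsleep import cap_scoring, synthetic

config = synthetic.SyntheticConfig(duration_s=600, n_subjects=1, seed=7)
record, truth = synthetic.generate_record(config, 0)
labels = synthetic.truth_to_labels(truth, int(config.duration_s))

print(f"record: {record.n_samples} samples at {record.fs:g} Hz "
      f"({record.duration_s:.0f} s), channel {record.channel}")
print(f"A-phase events: {len(truth.a_intervals)} "
      f"({labels.a_phase.sum()} epochs labeled A)")
print(f"NREM epochs: {labels.nrem.sum()} / {labels.n_epochs}")

result = cap_scoring.score_cap(labels.a_phase, labels.nrem)
print(f"CAP cycles: {len(result.cycles)} in {len(result.sequences)} "
      f"sequence(s); CAP epochs: {result.cap_labels.sum()}")
print(f"CAP rate: {result.cap_rate:.3f}  "
      "(CAP seconds / NREM seconds; higher = less stable sleep)")
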