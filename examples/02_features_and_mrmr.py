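"""Compute the 20-feature set for one record and rank it with mRMR.

Shows the per-epoch feature table (symbolic-dynamics counts A1..A9, the
amplitude-variation metric A, five Welch band powers, five amplitude/power
ratios) and the minimal-redundancy-maximal-relevance ordering of the
features against the A-phase labels. Delta-band power and amplitude
features should dominate, since most synthetic events are slow-wave A1.
"""

from capsleep import features, mrmr, pipeline, synthetic

config = synthetic.SyntheticConfig(duration_s=600, n_subjects=1, seed=3)
record, truth = synthetic.generate_record(config, 0)
prepared = pipeline.prepare_record(record)
labels = synthetic.truth_to_labels(truth, int(config.duration_s))

table = features.feature_matrix(prepared)
print(f"feature matrix: {table.shape[0]} epochs x {table.shape[1]} features")
print(table.head(3).round(2).to_string())

ranking = mrmr.rank_features(table, labels.a_phase)
print("\nmRMR ordering (most to least relevant for A-phase detection):")
print("  " + ", ".join(ranking.ordering))
print(f"first nested candidate sets: {mrmr.nested_feature_sets(ranking)[:3]}")
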