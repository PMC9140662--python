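"""Full pipeline run: feature-based FFNN on a 5-subject synthetic cohort.

Trains the A-phase and NREM classifiers on a subject-disjoint split,
post-processes the per-second outputs (isolated-epoch correction, NREM
masking), scores CAP cycles with the FSM, and compares each subject's
predicted CAP rate with its ground truth.
"""

from capsleep import pipeline

report = pipeline.run_pipeline(pipeline.RunConfig(preset="ffnn", seed=1))

print(f"preset: {report['preset']}")
print(f"train subjects {report['subjects']['train']}, "
      f"eval subjects {report['subjects']['eval']}")
print(f"A phase: AUC {report['a_phase']['auc']:.3f}, "
      f"Acc {report['a_phase']['acc']:.3f}, Sen {report['a_phase']['sen']:.3f}")
print(f"NREM   : AUC {report['nrem']['auc']:.3f}, "
      f"Acc {report['nrem']['acc']:.3f}")
print(f"selected features: {report['selected_features']}")
print("\nper-subject CAP rate (predicted vs truth, % error):")
for entry in report["cap_rate"]["per_subject"]:
    print(f"  subject {entry['subject']} ({entry['role']}): "
          f"{entry['cap_rate_predicted']:.3f} vs "
          f"{entry['cap_rate_reference']:.3f} "
          f"({entry['cap_rate_pct_error']:.1f}%)")
print(f"median CAP-rate percentage error: "
      f"{report['cap_rate']['median_pct_error']:.1f}%")
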