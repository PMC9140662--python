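"""Heuristic architecture search (HOSA) over a toy 1D-CNN space.

Enumerates GofLayer stacks level by level (level = number of
convolution+pool+dropout groups), trains each candidate once on a tiny
2-subject synthetic cohort, and stops when adding a level improves the
best validation AUC by 0.01 or less. Takes a minute or two on one CPU.
"""

from capsleep import cli

trace = cli.pipeline_search(family="cnn", seed=5, toy=True)

print(f"evaluated {len(trace.evaluated)} candidate architectures")
print(f"per-level best AUC: {[round(b, 3) for b in trace.per_depth_best]}")
print(f"stopped at depth {trace.stopped_at_depth} "
      "(improvement <= 0.01 ends the search)")
best = trace.best_spec
print(f"best: {len(best.goflayers)} group(s), kernels {best.goflayers}, "
      f"dense {best.dense_units}, window {best.window.window_w} s "
      f"({best.window.scenario}), AUC {trace.best_auc:.3f}")
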