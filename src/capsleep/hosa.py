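"""Heuristic Oriented Search Algorithm (HOSA) over network structures.

Architectures are enumerated level by level — the level being the number of
GofLayer groups (1D-CNN) or recurrent layers (LSTM) — every candidate at a
level is trained and scored (mean validation AUC over repeats), and the
search deepens until the best AUC of the new level fails to beat the
previous level's best by more than the improvement threshold ``t_r``; the
better of the two levels' winners is then returned.

The evaluator is a pluggable callback ``spec -> mean AUC``, so the search
logic is independent of model size and training budget.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .classifiers import CnnSpec, LstmSpec, spec_from_dict, spec_to_dict
from .preprocess import WindowSpec

logger = logging.getLogger(__name__)

DEFAULT_T_R = 0.01


def _default_o_list(o_max: int = 17) -> tuple:
    """O = [0, 1, 3, 5, ...]: no overlap, then 4 s window steps (W = 2O+1)
    up to a maximum window of 35 s (O = 17)."""
    return (0,) + tuple(range(1, o_max + 1, 2))


@dataclass(frozen=True)
class CnnSearchSpace:
    g_max: int = 4
    m_start: int = 4            # first-layer kernels K = 2^M
    m_max: int = 7
    mul_max: int = 2            # per-added-group kernel multiplier ceiling
    n_start: int = 50
    n_step: int = 50
    n_max: int = 150
    o_list: tuple = field(default_factory=_default_o_list)
    t_r: float = DEFAULT_T_R

    def __post_init__(self):
        if self.o_list[0] != 0 or list(self.o_list) != sorted(set(self.o_list)):
            raise ValueError("o_list must be strictly increasing starting at 0")

    @property
    def kernel_options(self) -> tuple:
        return tuple(2 ** m for m in range(self.m_start, self.m_max + 1))

    @property
    def dense_options(self) -> tuple:
        return tuple(range(self.n_start, self.n_max + 1, self.n_step))


@dataclass(frozen=True)
class LstmSearchSpace:
    gr_max: int = 5
    t_list: tuple = (5, 15, 25, 35)
    nh_list: tuple = (100, 200, 300, 400)
    layer_types: tuple = (False, True)              # unidirectional, bidirectional
    dense_options: tuple = ("half", "same", "twice", "none")
    n_inputs: int = 20
    t_r: float = DEFAULT_T_R


@dataclass
class SearchTrace:
    evaluated: list = field(default_factory=list)   # (spec, mean AUC)
    per_depth_best: list = field(default_factory=list)
    best_spec: object = None
    best_auc: float = -np.inf
    stopped_at_depth: int = 0

    def to_json(self, path):
        payload = {
            "evaluated": [{"spec": spec_to_dict(s), "auc": a}
                          for s, a in self.evaluated],
            "per_depth_best": self.per_depth_best,
            "best_spec": spec_to_dict(self.best_spec) if self.best_spec else None,
            "best_auc": self.best_auc,
            "stopped_at_depth": self.stopped_at_depth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        trace = cls()
        trace.evaluated = [(spec_from_dict(e["spec"]), e["auc"])
                           for e in payload["evaluated"]]
        trace.per_depth_best = payload["per_depth_best"]
        if payload["best_spec"]:
            trace.best_spec = spec_from_dict(payload["best_spec"])
        trace.best_auc = payload["best_auc"]
        trace.stopped_at_depth = payload["stopped_at_depth"]
        return trace


def enumerate_cnn_level(space: CnnSearchSpace, depth_g: int) -> list:
    """All CnnSpec candidates with ``depth_g`` GofLayer groups.

    O = 0 contributes a single (degenerate) overlap scenario; O > 0
    contributes first/central/last. Added groups multiply the previous
    group's kernels by a uniform factor mul in 1..mul_max, so group z has
    K * mul^(z-1) kernels — linear growth of the candidate count.
    """
    if not (1 <= depth_g <= space.g_max):
        raise ValueError(f"depth must be in [1, {space.g_max}]")
    specs = []
    for o in space.o_list:
        scenarios = ("central",) if o == 0 else ("first", "central", "last")
        for k in space.kernel_options:
            for n in space.dense_options:
                for scenario in scenarios:
                    window = WindowSpec(o, scenario)
                    muls = (1,) if depth_g == 1 else tuple(
                        range(1, space.mul_max + 1))
                    for mul in muls:
                        layers = tuple(k * mul ** z for z in range(depth_g))
                        specs.append(CnnSpec(goflayers=layers, dense_units=n,
                                             window=window))
    return specs


def enumerate_lstm_level(space: LstmSearchSpace, depth_gr: int) -> list:
    """All LstmSpec candidates at a recurrent depth: T x Nh x L x m."""
    if not (1 <= depth_gr <= space.gr_max):
        raise ValueError(f"depth must be in [1, {space.gr_max}]")
    specs = []
    for t in space.t_list:
        for nh in space.nh_list:
            for bidir in space.layer_types:
                for dense in space.dense_options:
                    specs.append(LstmSpec(
                        n_inputs=space.n_inputs, hidden_units=nh,
                        time_steps=t, depth=depth_gr,
                        bidirectional=bidir, dense_option=dense))
    return specs


def run_hosa(enumerate_level, evaluator, t_r: float = DEFAULT_T_R,
             max_depth: int = 4, skip=None) -> SearchTrace:
    """Depth-staged search with the AUC-improvement stopping rule.

    ``enumerate_level(depth)`` yields the candidate specs of a level;
    ``evaluator(spec)`` returns its mean validation AUC. After each level
    g > 1, if best(g) - best(g-1) <= t_r the search stops and the better of
    the two levels' winners is kept. A failing evaluation skips the spec
    with a logged error. ``skip`` maps already-evaluated specs to their AUC
    (resume support).
    """
    trace = SearchTrace()
    skip = dict(skip or {})
    best_by_depth = {}
    best_spec_by_depth = {}
    for depth in range(1, max_depth + 1):
        level_best = -np.inf
        level_spec = None
        for spec in enumerate_level(depth):
            if spec in skip:
                auc = skip[spec]
            else:
                try:
                    auc = float(evaluator(spec))
                except Exception:
                    logger.exception("evaluator failed on %s; skipping", spec)
                    continue
            trace.evaluated.append((spec, auc))
            if auc > level_best:
                level_best, level_spec = auc, spec
        if level_spec is None:
            logger.error("no candidate evaluated at depth %d; stopping", depth)
            break
        best_by_depth[depth] = level_best
        best_spec_by_depth[depth] = level_spec
        trace.per_depth_best.append(level_best)
        trace.stopped_at_depth = depth
        if depth > 1 and level_best - best_by_depth[depth - 1] <= t_r:
            break
    if best_by_depth:
        winner = max(best_by_depth, key=lambda d: best_by_depth[d])
        trace.best_spec = best_spec_by_depth[winner]
        trace.best_auc = best_by_depth[winner]
    return trace
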