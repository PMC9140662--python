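"""Search-space enumeration counts and the depth-stopping rule."""

import numpy as np
import pytest

from capsleep import hosa
from capsleep.classifiers import CnnSpec, LstmSpec
from capsleep.hosa import (CnnSearchSpace, LstmSearchSpace,
                           enumerate_cnn_level, enumerate_lstm_level, run_hosa)

TOY_CNN = CnnSearchSpace(o_list=(0, 1, 3), m_start=4, m_max=5,
                         n_start=50, n_step=50, n_max=50, g_max=3)


def brute_force_cnn_count(o_list, n_kernels, n_dense, depth, mul_max):
    """Independent nested-loop enumeration of the level size."""
    count = 0
    for o in o_list:
        for _k in range(n_kernels):
            for _n in range(n_dense):
                for _a in range(1 if o == 0 else 3):
                    count += 1 if depth == 1 else mul_max
    return count


def test_toy_cnn_level1_count_is_14():
    specs = enumerate_cnn_level(TOY_CNN, 1)
    assert len(specs) == 14
    assert len(specs) == brute_force_cnn_count((0, 1, 3), 2, 1, 1, 2)


def test_single_combination_level():
    space = CnnSearchSpace(o_list=(0,), m_start=4, m_max=4,
                           n_start=50, n_step=50, n_max=50)
    assert len(enumerate_cnn_level(space, 1)) == 1


def test_cnn_depth2_kernel_doubling_rule():
    for spec in enumerate_cnn_level(TOY_CNN, 2):
        k = spec.goflayers[0]
        assert spec.goflayers[1] in (k, 2 * k)


def test_cnn_counts_match_brute_force_on_random_spaces(rng):
    for _ in range(5):
        o_list = (0,) + tuple(sorted(rng.choice(np.arange(1, 10), size=2,
                                                replace=False)))
        m_start = int(rng.integers(3, 5))
        m_max = m_start + int(rng.integers(0, 3))
        space = CnnSearchSpace(o_list=o_list, m_start=m_start, m_max=m_max,
                               n_start=50, n_step=50,
                               n_max=50 * int(rng.integers(1, 4)))
        for depth in (1, 2, 3):
            expected = brute_force_cnn_count(
                o_list, m_max - m_start + 1, len(space.dense_options),
                depth, space.mul_max)
            assert len(enumerate_cnn_level(space, depth)) == expected


def test_cnn_invalid_depth():
    with pytest.raises(ValueError):
        enumerate_cnn_level(TOY_CNN, 0)
    with pytest.raises(ValueError):
        enumerate_cnn_level(TOY_CNN, 99)


def test_lstm_level_count_is_128():
    specs = enumerate_lstm_level(LstmSearchSpace(), 1)
    assert len(specs) == 4 * 4 * 2 * 4 == 128


def test_lstm_single_element_lists():
    space = LstmSearchSpace(t_list=(25,), nh_list=(100,),
                            layer_types=(False,), dense_options=("half",))
    specs = enumerate_lstm_level(space, 1)
    assert len(specs) == 1
    assert specs[0].dense_units == 50  # floor(100/2 + 1/2)


def test_lstm_dense_option_arithmetic():
    for nh, option, expected in [(100, "half", 50), (300, "half", 150),
                                 (100, "same", 100), (100, "twice", 200),
                                 (100, "none", None)]:
        spec = LstmSpec(n_inputs=5, hidden_units=nh, time_steps=5,
                        dense_option=option)
        assert spec.dense_units == expected


def _scripted_evaluator(per_depth_auc):
    def evaluator(spec):
        depth = len(spec.goflayers) if isinstance(spec, CnnSpec) else spec.depth
        return per_depth_auc[depth - 1]
    return evaluator


def test_hosa_stops_on_small_improvement():
    """0.905 - 0.9 = 0.005 <= t_r: stop after depth 2, keep depth 2's best."""
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    trace = run_hosa(enum, _scripted_evaluator([0.9, 0.905, 0.99]),
                     t_r=0.01, max_depth=3)
    assert trace.stopped_at_depth == 2
    assert trace.best_auc == pytest.approx(0.905)
    assert len(trace.best_spec.goflayers) == 2


def test_hosa_constant_evaluator_stops_after_two_levels():
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    trace = run_hosa(enum, _scripted_evaluator([0.7, 0.7, 0.7]),
                     t_r=0.01, max_depth=3)
    assert trace.stopped_at_depth == 2
    n1 = len(enumerate_cnn_level(TOY_CNN, 1))
    n2 = len(enumerate_cnn_level(TOY_CNN, 2))
    assert len(trace.evaluated) == n1 + n2
    # ties keep the earlier depth's winner
    assert len(trace.best_spec.goflayers) == 1


def test_hosa_keeps_deepening_on_large_gains():
    """+0.02 per depth always beats t_r = 0.01: run to the depth cap."""
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    trace = run_hosa(enum, _scripted_evaluator([0.80, 0.82, 0.84]),
                     t_r=0.01, max_depth=3)
    assert trace.stopped_at_depth == 3
    assert trace.per_depth_best == pytest.approx([0.80, 0.82, 0.84])


def test_hosa_skips_failing_specs():
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    calls = {"n": 0}

    def evaluator(spec):
        calls["n"] += 1
        if spec.dense_units == 50 and spec.goflayers[0] == 16 \
                and spec.window.overlap_o == 0 and len(spec.goflayers) == 1:
            raise RuntimeError("synthetic failure")
        return 0.6

    trace = run_hosa(enum, evaluator, t_r=0.01, max_depth=2)
    n1 = len(enumerate_cnn_level(TOY_CNN, 1))
    n2 = len(enumerate_cnn_level(TOY_CNN, 2))
    assert calls["n"] == n1 + n2
    assert len(trace.evaluated) == n1 + n2 - 1


def test_hosa_per_depth_best_nondecreasing_until_stop():
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    trace = run_hosa(enum, _scripted_evaluator([0.7, 0.75, 0.8]),
                     t_r=0.01, max_depth=3)
    bests = trace.per_depth_best
    assert all(b >= a for a, b in zip(bests, bests[1:]))
    assert trace.best_auc == max(a for _, a in trace.evaluated)


def test_trace_round_trip(tmp_path):
    enum = lambda d: enumerate_cnn_level(TOY_CNN, d)
    trace = run_hosa(enum, _scripted_evaluator([0.9, 0.905]), max_depth=2)
    path = tmp_path / "trace.json"
    trace.to_json(path)
    back = hosa.SearchTrace.from_json(path)
    assert back.best_spec == trace.best_spec
    assert back.per_depth_best == trace.per_depth_best
    assert len(back.evaluated) == len(trace.evaluated)
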