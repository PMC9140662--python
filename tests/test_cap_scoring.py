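"""Correction passes and the CAP-cycle scoring FSM against rule oracles."""

import numpy as np
import pytest

from capsleep.cap_scoring import (apply_nrem_mask, cap_rate_metrics,
                                  correct_isolated, intervals_to_labels,
                                  labels_to_intervals, merge_close_phases,
                                  score_cap)
from capsleep.types import PhaseInterval


def oracle_correct_isolated(a):
    """Definition trace: evaluate every epoch against the unmodified input."""
    a = np.asarray(a).astype(bool)
    out = a.copy()
    for i in range(1, len(a) - 1):
        if a[i - 1] == a[i + 1] and a[i] != a[i - 1]:
            out[i] = a[i - 1]
    return out


def oracle_score_cap(a, nrem):
    """Independent epoch-walking implementation of the scoring rules:
    valid phases 2-60 s, B all-NREM, cycle = A + following B, sequences of
    >= 2 consecutive cycles, terminal A excluded."""
    a = np.asarray(a).astype(bool)
    nrem = np.asarray(nrem).astype(bool)
    phases = []
    i = 0
    while i < len(a):
        if a[i]:
            j = i
            while j < len(a) and a[j]:
                j += 1
            phases.append([i, j])
            i = j
        else:
            i += 1
    # merge phases separated by < 2 epochs
    merged = []
    for p in phases:
        if merged and p[0] - merged[-1][1] < 2:
            merged[-1][1] = p[1]
        else:
            merged.append(p)
    valid = [p for p in merged if 2 <= p[1] - p[0] <= 60]
    cycles = []
    for (s1, e1), (s2, _e2) in zip(valid, valid[1:]):
        gap = s2 - e1
        if 2 <= gap <= 60 and nrem[e1:s2].all():
            cycles.append((s1, s2))  # cycle spans A onset to next A onset
    # group consecutive cycles (next A is exactly where previous cycle ends)
    runs, run = [], []
    for c in cycles:
        if run and run[-1][1] != c[0]:
            runs.append(run)
            run = []
        run.append(c)
    if run:
        runs.append(run)
    cap = np.zeros(len(a), dtype=bool)
    kept = 0
    for r in runs:
        if len(r) >= 2:
            kept += len(r)
            for s, e in r:
                cap[s:e] = True
    rate = cap.sum() / nrem.sum() if nrem.sum() else None
    return cap, kept, rate


@pytest.mark.parametrize("stream, expected", [
    ([1, 0, 1], [1, 1, 1]),
    ([0, 1, 0], [0, 0, 0]),
    ([1, 0, 1, 0, 1], [1, 1, 0, 1, 1]),  # simultaneous pass, original input
])
def test_correct_isolated_examples(stream, expected):
    assert list(correct_isolated(stream).astype(int)) == expected


def test_correct_isolated_short_stream_unchanged():
    assert list(correct_isolated([1, 0])) == [True, False]


def test_correct_isolated_matches_definition_trace(rng):
    for _ in range(200):
        stream = rng.random(rng.integers(3, 60)) < 0.4
        assert np.array_equal(correct_isolated(stream),
                              oracle_correct_isolated(stream))


def test_correct_isolated_fixes_every_input_isolation(rng):
    """Every epoch isolated in the input takes its neighbors' class."""
    for _ in range(100):
        a = rng.random(50) < 0.5
        out = correct_isolated(a)
        for i in range(1, 49):
            if a[i - 1] == a[i + 1] != a[i]:
                assert out[i] == a[i - 1]


def test_apply_nrem_mask():
    a = np.array([1, 1, 0, 1], dtype=bool)
    assert not apply_nrem_mask(a, np.zeros(4, bool)).any()
    assert np.array_equal(apply_nrem_mask(a, np.ones(4, bool)), a)
    with pytest.raises(ValueError):
        apply_nrem_mask(a, np.ones(3, bool))


def test_apply_nrem_mask_elementwise_oracle(rng):
    a = rng.random(500) < 0.3
    nrem = rng.random(500) < 0.7
    out = apply_nrem_mask(a, nrem)
    assert np.array_equal(out, np.array([x and y for x, y in zip(a, nrem)]))
    assert not np.any(out & ~nrem)  # A implies NREM


def test_labels_to_intervals_run_length():
    intervals = labels_to_intervals([0, 1, 1, 0, 1, 0])
    assert [(iv.onset_epoch, iv.duration_epochs) for iv in intervals] == \
        [(1, 2), (4, 1)]
    assert labels_to_intervals(np.zeros(10)) == []


def test_intervals_round_trip(rng):
    labels = rng.random(300) < 0.3
    back = intervals_to_labels(labels_to_intervals(labels), 300)
    assert np.array_equal(back, labels)


def test_merge_close_phases_rules():
    a, b = PhaseInterval(0, 3), PhaseInterval(4, 2)
    merged = merge_close_phases([a, b])
    assert [(iv.onset_epoch, iv.duration_epochs) for iv in merged] == [(0, 6)]
    # boundary: a gap of exactly 2 epochs is kept
    c = PhaseInterval(0, 3), PhaseInterval(5, 2)
    assert len(merge_close_phases(list(c))) == 2


def test_merge_chain_reaches_fixed_point():
    chain = [PhaseInterval(0, 3), PhaseInterval(4, 2), PhaseInterval(7, 4)]
    merged = merge_close_phases(chain)
    assert [(iv.onset_epoch, iv.duration_epochs) for iv in merged] == [(0, 11)]


def test_score_cap_no_a_phases():
    result = score_cap(np.zeros(100, bool), np.ones(100, bool))
    assert result.cycles == [] and result.cap_rate == 0.0


def test_score_cap_hand_traced_example():
    """A(10,3), gap 5, A(18,4), gap 10, A(32,3), then silence: two cycles,
    CAP epochs 3+5+4+10 = 22, rate 22/120."""
    a = np.zeros(120, bool)
    a[10:13] = a[18:22] = a[32:35] = True
    result = score_cap(a, np.ones(120, bool))
    assert len(result.cycles) == 2
    assert result.cap_labels.sum() == 22
    assert result.cap_rate == pytest.approx(22 / 120)
    assert len(result.sequences) == 1


def test_score_cap_lone_cycle_is_not_a_sequence():
    a = np.zeros(160, bool)
    a[10:13] = True
    a[83:86] = True  # 70-epoch gap: B invalid
    result = score_cap(a, np.ones(160, bool))
    assert result.sequences == []
    assert result.cap_rate == 0.0


def test_score_cap_b_phase_requires_nrem_content():
    a = np.zeros(60, bool)
    a[5:8] = a[15:18] = a[25:28] = True
    nrem = np.ones(60, bool)
    nrem[10] = False  # interrupts the first B phase
    result = score_cap(a, nrem)
    # first pair broken; only one cycle remains -> no sequence
    assert result.sequences == []


def test_score_cap_zero_nrem_rejected():
    with pytest.raises(ValueError):
        score_cap(np.zeros(10, bool), np.zeros(10, bool))


def test_score_cap_matches_rule_oracle_on_constructed_streams(rng):
    """>= 10 constructed streams plus random ones against the independent
    epoch-walking FSM oracle."""
    constructed = []
    # the hand-traced example
    a = np.zeros(120, bool)
    a[10:13] = a[18:22] = a[32:35] = True
    constructed.append((a, np.ones(120, bool)))
    # overlong A phase
    a = np.zeros(200, bool)
    a[10:75] = a[80:85] = a[90:95] = True
    constructed.append((a, np.ones(200, bool)))
    # chain of many valid cycles
    a = np.zeros(200, bool)
    for start in range(10, 150, 10):
        a[start:start + 4] = True
    constructed.append((a, np.ones(200, bool)))
    # close phases that must merge first
    a = np.zeros(100, bool)
    a[10:13] = a[14:17] = a[25:28] = a[35:38] = True
    constructed.append((a, np.ones(100, bool)))
    # not-NREM holes
    for hole in (20, 30, 40):
        a = np.zeros(100, bool)
        a[10:14] = a[24:28] = a[44:48] = True
        nrem = np.ones(100, bool)
        nrem[hole] = False
        constructed.append((a, nrem))
    # single-epoch A phases (invalid duration)
    a = np.zeros(100, bool)
    a[10] = True
    a[20:23] = a[30:33] = True
    constructed.append((a, np.ones(100, bool)))
    # empty and all-A
    constructed.append((np.zeros(50, bool), np.ones(50, bool)))
    constructed.append((np.ones(50, bool), np.ones(50, bool)))
    for _ in range(30):
        n = int(rng.integers(50, 300))
        a = rng.random(n) < 0.25
        nrem = rng.random(n) < 0.9
        constructed.append((a, nrem))

    checked = 0
    for a, nrem in constructed:
        if not nrem.any():
            continue
        result = score_cap(a, nrem)
        cap, n_cycles, rate = oracle_score_cap(a, nrem)
        assert np.array_equal(result.cap_labels, cap)
        assert len(result.cycles) == n_cycles
        assert result.cap_rate == pytest.approx(rate)
        checked += 1
    assert checked >= 10


def test_scored_cycles_respect_duration_bounds(rng):
    for _ in range(20):
        n = 400
        nrem = rng.random(n) < 0.85
        a = (rng.random(n) < 0.3) & nrem  # contract: already masked
        if not nrem.any():
            continue
        result = score_cap(a, nrem)
        for a_iv, b_iv in result.cycles:
            assert 2 <= a_iv.duration_epochs <= 60
            assert 2 <= b_iv.duration_epochs <= 60
        for seq in result.sequences:
            assert len(seq) >= 2
        # CAP time lies in NREM except for sub-2 s gaps absorbed when two
        # close A phases were combined
        absorbed = np.roll(a, 1) & np.roll(a, -1)
        assert not np.any(result.cap_labels & ~(nrem | absorbed))


def test_cap_rate_metrics():
    err, pct = cap_rate_metrics(0.25, 0.20)
    assert err == pytest.approx(0.05)
    assert pct == pytest.approx(25.0)
    assert cap_rate_metrics(0.3, 0.3) == (0.0, 0.0)
    err, pct = cap_rate_metrics(0.1, 0.2)
    assert err < 0 < pct
    with pytest.raises(ValueError):
        cap_rate_metrics(0.1, 0.0)
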