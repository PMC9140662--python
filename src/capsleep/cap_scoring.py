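"""Post-processing correction and FSM scoring of CAP cycles.

The per-second A/not-A stream is first cleaned (isolated-epoch correction,
then NREM masking), then a finite-state machine applies the CAP scoring
rules: an A phase is valid if it lasts 2-60 s; the B phase between two
valid A phases is valid if it lasts 2-60 s and contains only NREM epochs; a
cycle is an A phase plus its following valid B phase; a CAP sequence is a
maximal run of at least two consecutive cycles (the closing A phase after
the final B, lacking a valid following B, is not CAP). CAP rate = CAP
epochs / NREM epochs.
"""

from __future__ import annotations

import numpy as np

from .types import CapResult, PhaseInterval

PHASE_MIN_EPOCHS = 2
PHASE_MAX_EPOCHS = 60
MIN_CYCLES_PER_SEQUENCE = 2
MERGE_GAP_EPOCHS = 2  # consecutive A phases closer than this are combined


def correct_isolated(a_labels) -> np.ndarray:
    """Flip epochs bounded by two identical opposite classes (101, 010).

    One simultaneous pass against the unmodified input; the first and last
    epochs are never changed. Streams shorter than 3 return unchanged.
    """
    a = np.asarray(a_labels).astype(bool)
    if len(a) < 3:
        return a.copy()
    out = a.copy()
    isolated = (a[:-2] == a[2:]) & (a[1:-1] != a[:-2])
    out[1:-1][isolated] = a[:-2][isolated]
    return out


def apply_nrem_mask(a_labels, nrem_labels) -> np.ndarray:
    """Reclassify "A" as "not-A" wherever the NREM stream says not-NREM."""
    a = np.asarray(a_labels).astype(bool)
    nrem = np.asarray(nrem_labels).astype(bool)
    if a.shape != nrem.shape:
        raise ValueError("label streams must have equal length")
    return a & nrem


def labels_to_intervals(a_labels, kind: str = "A") -> list:
    """Maximal runs of consecutive positive epochs as PhaseIntervals."""
    a = np.asarray(a_labels).astype(bool)
    if len(a) == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[False], a, [False]])))
    starts, ends = edges[::2], edges[1::2]
    return [PhaseInterval(int(s), int(e - s), kind) for s, e in zip(starts, ends)]


def intervals_to_labels(intervals, n_epochs: int) -> np.ndarray:
    out = np.zeros(n_epochs, dtype=bool)
    for iv in intervals:
        out[iv.onset_epoch: iv.end_epoch] = True
    return out


def merge_close_phases(intervals, min_gap: int = MERGE_GAP_EPOCHS) -> list:
    """Combine consecutive A phases separated by less than ``min_gap`` epochs.

    Applied repeatedly until stable (a chain of close phases collapses to
    one). The absorbed gap becomes part of the merged phase.
    """
    merged = list(intervals)
    changed = True
    while changed:
        changed = False
        out = []
        for iv in merged:
            if out and iv.onset_epoch - out[-1].end_epoch < min_gap:
                prev = out.pop()
                out.append(PhaseInterval(
                    prev.onset_epoch, iv.end_epoch - prev.onset_epoch, prev.kind))
                changed = True
            else:
                out.append(iv)
        merged = out
    return merged


def score_cap(a_labels, nrem_labels) -> CapResult:
    """Run the CAP scoring FSM over corrected, masked per-second labels."""
    a = np.asarray(a_labels).astype(bool)
    nrem = np.asarray(nrem_labels).astype(bool)
    if a.shape != nrem.shape:
        raise ValueError("label streams must have equal length")
    n_nrem = int(nrem.sum())
    if n_nrem == 0:
        raise ValueError("no NREM epochs; CAP rate undefined")

    phases = merge_close_phases(labels_to_intervals(a))
    # rule (i): discard A phases with invalid duration
    valid = [p for p in phases
             if PHASE_MIN_EPOCHS <= p.duration_epochs <= PHASE_MAX_EPOCHS]

    # rule (ii)-(iii): pair each A with its following B where the gap to the
    # next valid A is 2-60 epochs of uninterrupted NREM
    cycles = []
    chain_break = []  # True where cycle k+1 is NOT consecutive with cycle k
    for p, nxt in zip(valid[:-1], valid[1:]):
        gap = nxt.onset_epoch - p.end_epoch
        b_ok = (PHASE_MIN_EPOCHS <= gap <= PHASE_MAX_EPOCHS
                and bool(nrem[p.end_epoch: nxt.onset_epoch].all()))
        if b_ok:
            cycles.append((p, PhaseInterval(p.end_epoch, gap, "B")))
    # consecutiveness: cycle k+1 follows directly iff its A is the A that
    # closed cycle k's B
    for c, nxt in zip(cycles[:-1], cycles[1:]):
        chain_break.append(nxt[0].onset_epoch != c[1].end_epoch)

    # rule (iv): sequences are maximal runs of >= 2 consecutive cycles
    sequences = []
    run = []
    for k, cycle in enumerate(cycles):
        if run and chain_break[k - 1]:
            if len(run) >= MIN_CYCLES_PER_SEQUENCE:
                sequences.append(run)
            run = []
        run.append(cycle)
    if len(run) >= MIN_CYCLES_PER_SEQUENCE:
        sequences.append(run)

    scored = [cycle for seq in sequences for cycle in seq]
    cap_labels = np.zeros(len(a), dtype=bool)
    for a_iv, b_iv in scored:
        cap_labels[a_iv.onset_epoch: b_iv.end_epoch] = True
    cap_rate = float(cap_labels.sum()) / n_nrem
    return CapResult(cycles=scored, sequences=sequences,
                     cap_labels=cap_labels, cap_rate=cap_rate)


def cap_rate_metrics(predicted_rate: float, reference_rate: float):
    """Signed CAP-rate error and absolute percentage error."""
    error = predicted_rate - reference_rate
    if reference_rate == 0:
        raise ValueError("reference CAP rate is zero; percentage undefined")
    return error, abs(error) / reference_rate * 100.0
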