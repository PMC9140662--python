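"""Seeded synthetic full-night-like EEG with ground-truth CAP structure.

The generator emulates the statistical structure the pipeline assumes, not
sleep physiology: an order-2 autoregressive background with a 1/f-like
spectral tilt, a macrostructure of alternating NREM/REM/WAKE blocks, and
additive band-limited A-phase bursts placed inside NREM in CAP-like
sequences. A1 events boost the delta band (0.5-4 Hz), A3 events boost the
beta band (15-30 Hz) at reduced amplitude, and A2 mixes both. Event
durations are drawn from a truncated normal with mean ~13 s clipped to
[2, 60] s; 0.5 s cosine on/off ramps make onset/offset boundaries
deliberately ambiguous at low snr.

Ground-truth CAP intervals are derived by feeding the true per-second
labels through the same FSM used for scoring predictions, so generator and
scorer can never disagree about the rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from . import cap_scoring
from .types import GroundTruth, LabelStream, SignalRecord

#: order-2 AR denominator: poles at 0.92 and 0.35 give a low-passed,
#: roughly 1/f-tilted background spectrum
AR_COEFFS = np.array([1.0, -1.27, 0.322])

SUBTYPE_BANDS = {
    "A1": ((0.5, 4.0),),
    "A2": ((0.5, 4.0), (15.0, 30.0)),
    "A3": ((15.0, 30.0),),
}
#: amplitude multiplier per subtype relative to snr (A3 bursts are low
#: amplitude fast rhythms)
SUBTYPE_GAIN = {"A1": 1.0, "A2": 0.75, "A3": 0.5}

#: stage-dependent background: overall gain plus additive band-limited
#: activity, emulating NREM slow-wave dominance, REM theta-tinged
#: low-amplitude EEG, and wake alpha. These make the macrostructure
#: learnable from the single channel, as it is in real recordings.
STAGE_PROFILE = {
    "NREM": (1.0, ((0.5, 4.0), 1.0)),
    "REM": (0.7, ((4.0, 8.0), 0.4)),
    "WAKE": (0.6, ((8.0, 12.0), 0.6)),
}

RAMP_S = 0.5  # cosine on/off ramp duration


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the desk-scale conditions used throughout the tests:
    5 subjects x 10 min at 100 Hz, events at ~2 per NREM minute, mean
    A-phase duration ~13 s, event-to-background amplitude ratio 3.
    """

    duration_s: float = 600.0
    fs: float = 100.0
    n_subjects: int = 5
    a_event_rate: float = 2.0              # A phases per NREM minute (ceiling)
    duration_mean_s: float = 13.0          # truncated-normal location
    duration_sd_s: float = 5.0
    duration_clip: tuple = (2.0, 60.0)
    gap_mean_s: float = 10.0               # intra-sequence inter-A gap
    gap_sd_s: float = 5.0
    gap_clip: tuple = (2.0, 60.0)
    sequence_len_mean: float = 2.0         # extra cycles beyond the min 2
    inter_sequence_gap_s: tuple = (65.0, 120.0)
    subtype_mix: tuple = (0.61, 0.21, 0.18)  # A1 / A2 / A3 proportions
    snr: float = 3.0
    macro_block_s: dict = field(default_factory=lambda: {
        "WAKE": (10.0, 60.0), "NREM": (180.0, 420.0), "REM": (30.0, 120.0)})
    amplitude_uv: float = 20.0             # background RMS in microvolts
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs < 100:
            raise ValueError("sampling frequency must be >= 100 Hz")
        if abs(sum(self.subtype_mix) - 1.0) > 1e-9:
            raise ValueError("subtype mix must sum to 1")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Draw from N(mean, sd) truncated to [lo, hi] by rejection."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def sample_a_duration(rng, config: SyntheticConfig, size=None):
    lo, hi = config.duration_clip
    return _truncated_normal(rng, config.duration_mean_s, config.duration_sd_s,
                             lo, hi, size)


def _macro_structure(rng, config: SyntheticConfig) -> list:
    """Alternating WAKE -> (NREM, REM)* blocks covering the record."""
    out = []
    t = 0.0
    order = ["WAKE", "NREM", "REM"]
    k = 0
    while t < config.duration_s:
        stage = order[k % 3] if k < 3 else ("NREM" if k % 2 == 1 else "REM")
        lo, hi = config.macro_block_s[stage]
        dur = min(float(rng.uniform(lo, hi)), config.duration_s - t)
        out.append((t, dur, stage))
        t += dur
        k += 1
    return out


def _place_a_phases(rng, config: SyntheticConfig, stage_intervals) -> list:
    """CAP-like runs of A phases inside each NREM block.

    Each run holds ``n_cycles + 1`` A phases separated by valid B gaps (the
    FSM turns n+1 phases into n cycles); runs are separated by gaps longer
    than 60 s so sequences stay distinct. Placement stops once the target
    event count (a_event_rate x NREM minutes) is reached.
    """
    events = []
    if config.a_event_rate <= 0:
        return events
    total_nrem_min = sum(d for _, d, s in stage_intervals if s == "NREM") / 60.0
    budget = config.a_event_rate * total_nrem_min
    for onset, dur, stage in stage_intervals:
        if stage != "NREM" or len(events) >= budget:
            continue
        t = onset + float(rng.uniform(5.0, 20.0))
        end = onset + dur
        while t < end and len(events) < budget:
            n_phases = 3 + int(rng.poisson(config.sequence_len_mean))
            placed_any = False
            for k in range(n_phases):
                a_dur = float(sample_a_duration(rng, config))
                if t + a_dur > end or len(events) >= budget:
                    break
                subtype = ("A1", "A2", "A3")[
                    rng.choice(3, p=np.asarray(config.subtype_mix))]
                events.append((t, a_dur, subtype))
                placed_any = True
                t += a_dur
                if k < n_phases - 1:
                    lo, hi = config.gap_clip
                    t += float(_truncated_normal(
                        rng, config.gap_mean_s, config.gap_sd_s, lo, hi))
            t += float(rng.uniform(*config.inter_sequence_gap_s))
            if not placed_any:
                break
    return events


def _background(rng, n: int) -> np.ndarray:
    """Unit-RMS AR(2) noise with an approximate 1/f spectral tilt."""
    white = rng.standard_normal(n + 500)
    x = sp_signal.lfilter([1.0], AR_COEFFS, white)[500:]
    return x / np.std(x)


def _burst(rng, n: int, fs: float, bands) -> np.ndarray:
    """Unit-RMS band-limited noise burst with cosine on/off ramps."""
    parts = []
    for lo, hi in bands:
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                               output="sos")
        raw = rng.standard_normal(n + 200)
        parts.append(sp_signal.sosfilt(sos, raw)[200:])
    burst = np.sum(parts, axis=0)
    burst = burst / max(np.std(burst), 1e-12)
    ramp = int(RAMP_S * fs)
    if 2 * ramp < n and ramp > 0:
        env = np.ones(n)
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = up
        env[-ramp:] = up[::-1]
        burst = burst * env
    return burst


def generate_record(config: SyntheticConfig, subject_index: int = 0):
    """One seeded record plus its ground truth.

    Identical (config, subject_index) yields bit-identical output; the
    per-subject seed is ``config.seed + subject_index``.
    """
    rng = np.random.default_rng(config.seed + subject_index)
    n = int(round(config.duration_s * config.fs))
    stage_intervals = _macro_structure(rng, config)
    a_intervals = _place_a_phases(rng, config, stage_intervals)

    x = _background(rng, n)
    for onset, dur, stage in stage_intervals:
        gain, (band, amp) = STAGE_PROFILE[stage]
        i0 = int(round(onset * config.fs))
        i1 = min(int(round((onset + dur) * config.fs)), n)
        if i1 <= i0:
            continue
        x[i0:i1] *= gain
        x[i0:i1] += amp * _burst(rng, i1 - i0, config.fs, (band,))
    for onset, dur, subtype in a_intervals:
        i0 = int(round(onset * config.fs))
        i1 = min(int(round((onset + dur) * config.fs)), n)
        if i1 <= i0:
            continue
        gain = config.snr * SUBTYPE_GAIN[subtype]
        x[i0:i1] += gain * _burst(rng, i1 - i0, config.fs, SUBTYPE_BANDS[subtype])

    record = SignalRecord(
        samples=x * config.amplitude_uv,
        fs=config.fs,
        subject_id=f"SYN{subject_index:02d}",
        channel="C4-A1",
    )
    truth = GroundTruth(
        a_intervals=a_intervals,
        stage_intervals=stage_intervals,
    )
    truth.cap_intervals = _derive_cap_intervals(truth, int(config.duration_s))
    return record, truth


def _derive_cap_intervals(truth: GroundTruth, n_epochs: int) -> list:
    labels = truth_to_labels(truth, n_epochs, derive_cap=False)
    if not labels.nrem.any():
        return []
    result = cap_scoring.score_cap(labels.a_phase, labels.nrem)
    return [(float(iv.onset_epoch), float(iv.duration_epochs))
            for iv in cap_scoring.labels_to_intervals(result.cap_labels)]


def truth_to_labels(truth: GroundTruth, n_epochs: int,
                    derive_cap: bool = False) -> LabelStream:
    """Rasterize ground truth on the epoch grid.

    Epoch i is "A" iff [i, i+1) overlaps an A interval (any overlap);
    "NREM" iff its midpoint lies inside an NREM stage block.
    """
    a = np.zeros(n_epochs, dtype=bool)
    nrem = np.zeros(n_epochs, dtype=bool)
    for onset, dur, _subtype in truth.a_intervals:
        if onset < 0 or onset + dur > n_epochs + 1:
            raise ValueError("A interval outside the record")
        a[int(np.floor(onset)): min(int(np.ceil(onset + dur)), n_epochs)] = True
    mids = np.arange(n_epochs) + 0.5
    for onset, dur, stage in truth.stage_intervals:
        if stage == "NREM":
            nrem |= (mids >= onset) & (mids < onset + dur)
    return LabelStream(a_phase=a, nrem=nrem)


def ground_truth_cap_rate(truth: GroundTruth, n_epochs: int) -> float:
    """CAP seconds / NREM seconds from the derived CAP intervals."""
    labels = truth_to_labels(truth, n_epochs)
    n_nrem = int(labels.nrem.sum())
    if n_nrem == 0:
        raise ValueError("no NREM time in ground truth")
    cap_s = sum(dur for _, dur in truth.cap_intervals)
    return cap_s / n_nrem


def generate_cohort(config: SyntheticConfig) -> list:
    """n_subjects records with distinct derived seeds; reproducible."""
    return [generate_record(config, k) for k in range(config.n_subjects)]


def truth_to_annotation_rows(truth: GroundTruth) -> list:
    """Ground truth as annotation-table rows (for the TSV writer)."""
    stage_map = {"NREM": "NREM2", "REM": "REM", "WAKE": "WAKE"}
    rows = [(onset, dur, subtype) for onset, dur, subtype in truth.a_intervals]
    rows += [(onset, dur, stage_map[stage])
             for onset, dur, stage in truth.stage_intervals]
    return sorted(rows, key=lambda r: r[0])
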