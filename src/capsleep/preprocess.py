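"""Resampling, standardization, and segmentation.

Records of heterogeneous sampling frequency are brought to a common 100 Hz
grid by decimation (Chebyshev type I anti-aliasing filter, order 8, 0.05 dB
passband ripple, normalized cutoff 0.8/r), standardized to zero mean / unit
variance, and cut into 1 s epochs of 100 samples. For window-based
classifiers each epoch is embedded in a longer overlapping window; for
recurrent classifiers consecutive per-epoch items are stacked into
time-step sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .types import SignalRecord

logger = logging.getLogger(__name__)

TARGET_FS = 100.0
EPOCH_SAMPLES = 100

SCENARIOS = ("first", "central", "last")


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping-window geometry for the 1D-CNN.

    ``overlap_o`` seconds of context per side gives a window of
    ``W = 2*O + 1`` seconds; ``scenario`` selects which second of the window
    carries the label: its first, central, or last 100-sample block.
    """

    overlap_o: int
    scenario: str = "central"

    def __post_init__(self):
        if self.overlap_o < 0:
            raise ValueError("overlap must be >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    @property
    def window_w(self) -> int:
        return 2 * self.overlap_o + 1

    @property
    def label_position(self) -> int:
        """0-based second index of the labeled block inside the window."""
        if self.scenario == "first":
            return 0
        if self.scenario == "central":
            return self.window_w // 2
        return self.window_w - 1


@dataclass(frozen=True)
class SequenceSpec:
    """Number of time steps fed to each recurrent classification."""

    time_steps_t: int

    def __post_init__(self):
        if self.time_steps_t < 1:
            raise ValueError("time steps must be >= 1")


def decimate(record: SignalRecord, target_fs: float = TARGET_FS) -> SignalRecord:
    """Downsample to ``target_fs`` by Chebyshev-filtered decimation.

    Integer ratios use classical decimation (filter, then keep every r-th
    sample; output length ceil(N/r)). Non-integer ratios (e.g. 512 -> 100)
    fall back to polyphase rational resampling, trimmed to
    ``round(N * target_fs / fs)`` samples, with a logged notice.
    """
    if record.fs < target_fs:
        raise ValueError(
            f"cannot decimate upward: fs {record.fs} < target {target_fs}"
        )
    if record.fs == target_fs:
        return record
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        r = int(round(ratio))
        out = signal.decimate(record.samples, r, ftype="iir", zero_phase=True)
        return record.with_samples(out, fs=target_fs)
    frac = Fraction(int(round(target_fs * 1000)), int(round(record.fs * 1000)))
    up, down = frac.numerator, frac.denominator
    logger.info(
        "non-integer decimation ratio %.4f; rational resampling by %d/%d",
        ratio, up, down,
    )
    out = signal.resample_poly(record.samples, up, down)
    n_out = int(round(record.n_samples * target_fs / record.fs))
    out = out[:n_out]
    return record.with_samples(out, fs=target_fs)


def standardize(record: SignalRecord) -> SignalRecord:
    """Subtract the mean and divide by the (population) standard deviation."""
    x = record.samples
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant signal cannot be standardized")
    return record.with_samples((x - np.mean(x)) / sd, standardized=True)


def segment_epochs(record: SignalRecord) -> np.ndarray:
    """Cut a 100 Hz record into 1 s epochs: (n_epochs, 100) array.

    A trailing partial second is dropped.
    """
    if record.fs != TARGET_FS:
        raise ValueError(f"expected a {TARGET_FS:g} Hz record, got {record.fs}")
    n = record.n_samples // EPOCH_SAMPLES
    if n < 1:
        raise ValueError("record shorter than one epoch")
    return record.samples[: n * EPOCH_SAMPLES].reshape(n, EPOCH_SAMPLES)


def build_windows(record: SignalRecord, spec: WindowSpec) -> np.ndarray:
    """One overlapping window per epoch: (n_epochs, W*100) array.

    The record is zero-padded at both ends so every epoch owns a full
    window; the labeled second sits at ``spec.label_position``.
    """
    epochs = segment_epochs(record)
    n_epochs = len(epochs)
    w = spec.window_w
    pos = spec.label_position
    pad_left = pos * EPOCH_SAMPLES
    pad_right = (w - 1 - pos) * EPOCH_SAMPLES
    x = np.concatenate([
        np.zeros(pad_left),
        record.samples[: n_epochs * EPOCH_SAMPLES],
        np.zeros(pad_right),
    ])
    length = w * EPOCH_SAMPLES
    out = np.empty((n_epochs, length))
    for i in range(n_epochs):
        start = i * EPOCH_SAMPLES
        out[i] = x[start: start + length]
    return out


def build_sequences(per_epoch_items: np.ndarray, spec: SequenceSpec) -> np.ndarray:
    """Stack T consecutive items ending at each epoch: (n, T, d) array.

    The labeled epoch is the last time step (causal alignment). Epochs with
    fewer than T predecessors replicate the earliest available item on the
    left.
    """
    items = np.asarray(per_epoch_items, dtype=np.float64)
    if items.ndim == 1:
        items = items[:, None]
    n = len(items)
    if n == 0:
        raise ValueError("empty input")
    t = spec.time_steps_t
    idx = np.arange(n)[:, None] - np.arange(t - 1, -1, -1)[None, :]
    idx = np.clip(idx, 0, None)
    return items[idx]
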