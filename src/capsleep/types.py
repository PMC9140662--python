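"""Core in-memory containers shared across the pipeline.

Conventions used everywhere in this package:

* time is measured in seconds from record start, 0-based;
* intervals are half-open ``[onset, onset + duration)``;
* the scoring "epoch" is one second, so epoch ``i`` covers ``[i, i + 1)``;
* binary label streams are boolean numpy arrays with one entry per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SignalRecord",
    "LabelStream",
    "GroundTruth",
    "PhaseInterval",
    "CapResult",
]


@dataclass
class SignalRecord:
    """One channel of EEG with its sampling frequency and provenance.

    ``samples`` are in microvolts until :func:`capsleep.preprocess.standardize`
    sets the ``standardized`` flag, after which they are unitless z-scores.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "S0"
    channel: str = "C4-A1"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("SignalRecord holds a single channel (1-D array)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if len(self.samples) < self.fs:
            raise ValueError("record shorter than one epoch (1 s)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, **changes) -> "SignalRecord":
        return replace(self, samples=samples, **changes)


@dataclass
class LabelStream:
    """Per-second binary labels: A-phase vs not-A, and NREM vs not-NREM."""

    a_phase: np.ndarray
    nrem: np.ndarray

    def __post_init__(self) -> None:
        self.a_phase = np.asarray(self.a_phase, dtype=bool)
        self.nrem = np.asarray(self.nrem, dtype=bool)
        if self.a_phase.shape != self.nrem.shape:
            raise ValueError("a_phase and nrem streams must have equal length")

    @property
    def n_epochs(self) -> int:
        return len(self.a_phase)


@dataclass
class GroundTruth:
    """Generator-side truth: A-phase events, macrostructure, derived CAP time.

    ``a_intervals`` rows are ``(onset_s, duration_s, subtype)`` with subtype
    in {"A1", "A2", "A3"}; ``stage_intervals`` rows are
    ``(onset_s, duration_s, stage)`` with stage in {"NREM", "REM", "WAKE"};
    ``cap_intervals`` rows are ``(onset_s, duration_s)`` and are derived by
    the same FSM used for scoring predictions (single source of truth).
    """

    a_intervals: list = field(default_factory=list)
    stage_intervals: list = field(default_factory=list)
    cap_intervals: list = field(default_factory=list)


@dataclass(frozen=True)
class PhaseInterval:
    """A maximal run of same-kind epochs on the 1 s grid."""

    onset_epoch: int
    duration_epochs: int
    kind: str = "A"

    def __post_init__(self) -> None:
        if self.duration_epochs < 1:
            raise ValueError("interval must span at least one epoch")
        if self.kind not in ("A", "B"):
            raise ValueError(f"kind must be 'A' or 'B', got {self.kind!r}")

    @property
    def end_epoch(self) -> int:
        return self.onset_epoch + self.duration_epochs


@dataclass
class CapResult:
    """Output of the CAP scoring FSM.

    cycles      -- list of (A PhaseInterval, B PhaseInterval) pairs that were
                   accepted as CAP cycles (i.e. belong to a sequence);
    sequences   -- list of lists of cycles, each with >= 2 cycles;
    cap_labels  -- per-epoch boolean CAP membership;
    cap_rate    -- CAP epochs / NREM epochs.
    """

    cycles: list
    sequences: list
    cap_labels: np.ndarray
    cap_rate: float
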