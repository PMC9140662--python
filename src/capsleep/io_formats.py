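"""Readers and writers for the formats the pipeline touches.

Signals travel as 16-bit EDF (one channel, physical unit microvolt);
annotations as a TSV with the exact header ``onset_s  duration_s  label``;
feature matrices as CSV with named columns; reports as JSON.

EDF reading goes through :mod:`mne`; writing uses a minimal single-channel
EDF encoder implemented here (16-bit quantization over the record's physical
range), which the round-trip tests cross-check against the mne reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LabelStream, SignalRecord

logger = logging.getLogger(__name__)

#: closed vocabulary for annotation rows
A_LABELS = ("A1", "A2", "A3")
NREM_LABELS = ("NREM1", "NREM2", "NREM3", "NREM4")
OTHER_LABELS = ("REM", "WAKE")
LABEL_VOCABULARY = A_LABELS + NREM_LABELS + OTHER_LABELS

ANNOTATION_COLUMNS = ["onset_s", "duration_s", "label"]


class ChannelNotFoundError(KeyError):
    """None of the preferred channels is present in the file."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} does not fit in {width} bytes")
    return s.ljust(width).encode("ascii")


def _fixed_float(value: float, width: int) -> bytes:
    for fmt in (f"{value:.10g}", f"{value:.6g}", f"{value:.3g}", f"{value:.1f}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} bytes")


def write_signal(path, record: SignalRecord) -> None:
    """Write ``record`` as a single-channel 16-bit EDF file.

    The data-record duration is 1 s; a trailing partial second is zero-padded
    (the padding never enters the analysis because epoch segmentation drops
    partial seconds).
    """
    fs = record.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling frequency")
    fs = int(fs)
    x = np.asarray(record.samples, dtype=np.float64)
    n_rec = int(np.ceil(len(x) / fs))
    xp = np.concatenate([x, np.zeros(n_rec * fs - len(x))])

    pmin, pmax = float(xp.min()), float(xp.max())
    if pmax <= pmin:  # constant signal still needs a non-degenerate range
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((xp - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = digital.astype("<i2")

    header = b""
    header += _fixed("0", 8)                                   # version
    header += _fixed(record.subject_id, 80)                    # patient id
    header += _fixed("Startdate X", 80)                        # recording id
    header += _fixed("01.01.20", 8) + _fixed("00.00.00", 8)    # date, time
    header += _fixed(256 + 256, 8)                             # header bytes
    header += _fixed("", 44)                                   # reserved
    header += _fixed(n_rec, 8)                                 # n data records
    header += _fixed("1", 8)                                   # record duration
    header += _fixed("1", 4)                                   # n signals
    header += _fixed(record.channel, 16)                       # label
    header += _fixed("", 80)                                   # transducer
    header += _fixed("uV", 8)                                  # physical dim
    header += _fixed_float(pmin, 8) + _fixed_float(pmax, 8)
    header += _fixed(dmin, 8) + _fixed(dmax, 8)
    header += _fixed("", 80)                                   # prefiltering
    header += _fixed(fs, 8)                                    # samples/record
    header += _fixed("", 32)                                   # reserved

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_signal(path, channel_preference=("C3-A2", "C4-A1")) -> SignalRecord:
    """Read the first preferred channel found in an EDF file.

    Channel name matching ignores case and treats ``-`` and ``–`` alike,
    since databases vary in how they spell monopolar derivations.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error classes vary
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc

    def canon(name: str) -> str:
        return name.replace("–", "-").replace(" ", "").upper()

    available = {canon(name): name for name in raw.ch_names}
    for wanted in channel_preference:
        if canon(wanted) in available:
            name = available[canon(wanted)]
            idx = raw.ch_names.index(name)
            samples = raw.get_data(picks=[idx])[0] * 1e6  # volts -> microvolts
            return SignalRecord(
                samples=samples,
                fs=float(raw.info["sfreq"]),
                subject_id=str(raw.info.get("subject_info") or Path(path).stem),
                channel=name,
            )
    raise ChannelNotFoundError(
        f"none of {list(channel_preference)} present in {path}; "
        f"channels are {raw.ch_names}"
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    """Read and validate an annotation TSV (onset_s, duration_s, label)."""
    table = pd.read_csv(path, sep="\t")
    if list(table.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"annotation header must be {ANNOTATION_COLUMNS}, got {list(table.columns)}"
        )
    return validate_annotations(table)


def validate_annotations(table: pd.DataFrame) -> pd.DataFrame:
    for i, row in enumerate(table.itertuples(index=False)):
        if row.label not in LABEL_VOCABULARY:
            raise ValueError(
                f"row {i}: unknown label {row.label!r}; "
                f"vocabulary is {list(LABEL_VOCABULARY)}"
            )
        if row.onset_s < 0:
            raise ValueError(f"row {i}: negative onset {row.onset_s}")
        if row.duration_s <= 0:
            raise ValueError(f"row {i}: non-positive duration {row.duration_s}")
    return table


def write_annotations(path, table: pd.DataFrame) -> None:
    validate_annotations(table[ANNOTATION_COLUMNS])
    table[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def annotations_to_labels(table: pd.DataFrame, duration_s: float) -> LabelStream:
    """Rasterize an annotation table onto the 1 s epoch grid.

    Epoch ``i`` is "A" iff ``[i, i+1)`` overlaps any A1/A2/A3 interval
    (any-overlap rule — A phases are short events), and "NREM" iff the epoch
    midpoint ``i + 0.5`` falls inside an NREM1-4 interval (midpoint rule —
    stages are long blocks). REM and WAKE count as not-NREM.
    """
    if duration_s < 1:
        raise ValueError("record must last at least one second")
    n_epochs = int(np.floor(duration_s))
    a = np.zeros(n_epochs, dtype=bool)
    nrem = np.zeros(n_epochs, dtype=bool)
    validate_annotations(table)
    for row in table.itertuples(index=False):
        onset, dur = float(row.onset_s), float(row.duration_s)
        if onset + dur > duration_s:
            logger.warning(
                "interval (%s, %s, %s) extends past record end %.1f s; clipping",
                onset, dur, row.label, duration_s,
            )
            dur = max(0.0, duration_s - onset)
            if dur == 0:
                continue
        if row.label in A_LABELS:
            first = int(np.floor(onset))
            last = int(np.ceil(onset + dur))  # exclusive
            a[max(first, 0):min(last, n_epochs)] = True
        elif row.label in NREM_LABELS:
            mids = np.arange(n_epochs) + 0.5
            nrem |= (mids >= onset) & (mids < onset + dur)
    return LabelStream(a_phase=a, nrem=nrem)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_features(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)
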