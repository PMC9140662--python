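"""The 20-feature set computed per 1 s epoch.

Three categories:

1. symbolic dynamics — each standardized sample is binned against amplitude
   thresholds that are multiples of the record standard deviation sigma
   (-5s, -4s, -3s, -2s, -s, 2s, 3s, 4s), emitting symbols 1..9 by first
   match; the per-epoch symbol counts are features A1..A9 — plus the
   amplitude-variation metric A(E) = max(E) + max(E-2) - max(E-1);
2. Welch band powers in the five classic sleep-EEG bands
   (delta, theta, alpha, sigma, beta);
3. the ratio of the epoch's maximum amplitude to each band power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EPOCH_SAMPLES, TARGET_FS, segment_epochs
from .types import SignalRecord

logger = logging.getLogger(__name__)

#: thresholds in units of sigma, ascending; first-match binning yields 9 symbols
SYMBOL_THRESHOLDS = np.array([-5.0, -4.0, -3.0, -2.0, -1.0, 2.0, 3.0, 4.0])

#: conventional sleep-EEG band edges in Hz, half-open [lo, hi)
DEFAULT_BANDS = {
    "D": (0.5, 4.0),    # delta
    "T": (4.0, 8.0),    # theta
    "A": (8.0, 12.0),   # alpha
    "S": (12.0, 15.0),  # sigma (spindle band)
    "B": (15.0, 30.0),  # beta
}

FEATURE_NAMES = (
    [f"A{i}" for i in range(1, 10)]
    + ["A"]
    + [f"PSD_{b}" for b in DEFAULT_BANDS]
    + [f"APSD_{b}" for b in DEFAULT_BANDS]
)

#: guard against division by a vanishing band power in the ratio features
PSD_FLOOR = 1e-12


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings for one 100-sample epoch.

    With M = 50 and 50% overlap an epoch of P = 100 samples yields
    floor((P - phi*M) / ((1 - phi)*M)) = 3 Hann-windowed segments.
    """

    segment_len_m: int = 50
    overlap_phi: float = 0.5
    epoch_len_p: int = EPOCH_SAMPLES

    def __post_init__(self):
        if not (0 <= self.overlap_phi < 1):
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.segment_len_m > self.epoch_len_p:
            raise ValueError("segment length cannot exceed epoch length")

    @property
    def n_segments(self) -> int:
        m, phi, p = self.segment_len_m, self.overlap_phi, self.epoch_len_p
        return int(np.floor((p - phi * m) / ((1 - phi) * m)))


def symbolic_counts(epoch: np.ndarray, sigma: float) -> np.ndarray:
    """Counts of the nine amplitude symbols over one 100-sample epoch."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.shape != (EPOCH_SAMPLES,):
        raise ValueError(f"epoch must have {EPOCH_SAMPLES} samples")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    # symbol index = number of thresholds <= x, i.e. first strict x < thr match
    symbols = np.digitize(epoch, SYMBOL_THRESHOLDS * sigma, right=False)
    return np.bincount(symbols, minlength=9).astype(np.float64)


def amplitude_variation(max_current: float, max_prev1: float, max_prev2: float) -> float:
    """A(E) = max(E) + max(E-2) - max(E-1), as defined."""
    return max_current + max_prev2 - max_prev1


def band_psd(
    epoch: np.ndarray,
    params: WelchParams = WelchParams(),
    bands: dict = DEFAULT_BANDS,
) -> np.ndarray:
    """Welch band powers for one epoch, one value per band (sum over bins)."""
    epoch = np.asarray(epoch, dtype=np.float64)
    freqs, psd = signal.welch(
        epoch,
        fs=TARGET_FS,
        window="hann",
        nperseg=params.segment_len_m,
        noverlap=int(params.overlap_phi * params.segment_len_m),
        detrend=False,
    )
    out = np.empty(len(bands))
    for k, (lo, hi) in enumerate(bands.values()):
        out[k] = psd[(freqs >= lo) & (freqs < hi)].sum()
    return out


def amplitude_psd_ratio(epoch_max: float, band_value: float) -> float:
    """max(E) / band power, guarded against vanishing denominators."""
    if band_value < 0:
        raise ValueError("band power cannot be negative")
    return epoch_max / max(band_value, PSD_FLOOR)


def feature_matrix(
    record: SignalRecord,
    params: WelchParams = WelchParams(),
    bands: dict = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Compute the full 20-column feature table for a standardized record.

    sigma is the whole-record standard deviation (1 after standardization).
    The first two epochs replicate the earliest epoch maximum as missing
    predecessors for the amplitude-variation metric.
    """
    if not record.standardized:
        raise ValueError("feature creation expects a standardized record")
    epochs = segment_epochs(record)
    n = len(epochs)
    sigma = float(np.std(record.samples))

    counts = np.empty((n, 9))
    for i in range(n):
        counts[i] = symbolic_counts(epochs[i], sigma)

    maxima = epochs.max(axis=1)
    prev1 = maxima[np.clip(np.arange(n) - 1, 0, None)]
    prev2 = maxima[np.clip(np.arange(n) - 2, 0, None)]
    amp_var = maxima + prev2 - prev1

    psd = np.empty((n, len(bands)))
    for i in range(n):
        psd[i] = band_psd(epochs[i], params, bands)

    guarded = np.maximum(psd, PSD_FLOOR)
    if np.any(psd < PSD_FLOOR):
        logger.info("vanishing band power encountered; ratio guard active")
    ratios = maxima[:, None] / guarded
    ratios[np.abs(maxima) == 0] = 0.0

    data = np.column_stack([counts, amp_var, psd, ratios])
    return pd.DataFrame(data, columns=FEATURE_NAMES)
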