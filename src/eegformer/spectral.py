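"""Classical spectral baselines used as independent references.

These are deliberately simple, closed-form analyses (periodogram matching
and Welch band power) with no learned parameters; they serve as sanity
oracles for the synthetic generators and as baselines against which the
network can be compared.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import periodogram, welch

from .datasets import RecordingSet


def spectral_match_classify(recs: RecordingSet,
                            candidate_freqs: Sequence[float],
                            n_harmonics: int = 3,
                            channels: Sequence[int] | None = None) -> np.ndarray:
    """Classify each trial by maximum spectral power at the candidate
    fundamentals (PSDA-style matched-frequency detection).

    The spectrum is evaluated at the *exact* candidate frequencies and
    their harmonics (a DTFT projection onto complex exponentials, not a
    binned periodogram — candidates spaced 0.2 Hz apart are far closer
    than the FFT bin width of a 2 s trial); per candidate the squared
    projection magnitudes are summed over channels and the sub-Nyquist
    harmonics, and the argmax is the predicted class index.
    """
    cands = np.asarray(candidate_freqs, dtype=float)
    n = recs.trials[0].shape[1] if len(recs) else 0
    t = np.arange(n) / recs.sr
    exps = {h: np.exp(-2j * np.pi * np.outer(h * cands, t))
            for h in range(1, n_harmonics + 1)}
    keeps = {h: (h * cands) < recs.sr / 2 for h in exps}
    preds = np.empty(len(recs), dtype=np.int64)
    for i, trial in enumerate(recs.trials):
        x = trial if channels is None else trial[list(channels), :]
        if x.shape[1] != n:  # unequal trial lengths: rebuild the bases
            t = np.arange(x.shape[1]) / recs.sr
            exps = {h: np.exp(-2j * np.pi * np.outer(h * cands, t))
                    for h in exps}
            n = x.shape[1]
        scores = np.zeros(len(cands))
        for h, E in exps.items():
            proj = E @ x.T                              # (n_cands, n_ch)
            scores += keeps[h] * (np.abs(proj) ** 2).sum(axis=1)
        preds[i] = int(np.argmax(scores))
    return preds


def dominant_frequency(trial: np.ndarray, sr: float,
                       channel: int = 0) -> float:
    """Frequency of the periodogram argmax of one channel (DC excluded)."""
    f, pxx = periodogram(trial[channel], fs=sr)
    return float(f[1:][np.argmax(pxx[1:])])


def band_power(trial: np.ndarray, sr: float,
               band_hz: tuple[float, float]) -> float:
    """Welch-estimate of mean channel power inside a band (uV^2/Hz units
    are whatever the input carries; only ratios matter here)."""
    nper = min(trial.shape[-1], int(2 * sr))
    f, pxx = welch(trial, fs=sr, nperseg=nper, axis=-1)
    mask = (f >= band_hz[0]) & (f < band_hz[1])
    return float(pxx[..., mask].mean())


def relative_band_power(trial: np.ndarray, sr: float,
                        band_hz: tuple[float, float]) -> float:
    """Band power divided by total broadband power.  The ratio cancels any
    per-subject overall amplitude gain, so it isolates band-specific
    effects (the statistic a practitioner would threshold)."""
    nper = min(trial.shape[-1], int(2 * sr))
    f, pxx = welch(trial, fs=sr, nperseg=nper, axis=-1)
    mask = (f >= band_hz[0]) & (f < band_hz[1])
    total = pxx.sum(axis=-1).mean()
    return float(pxx[..., mask].sum(axis=-1).mean() / total) if total else 0.0


def band_power_classify(recs: RecordingSet, band_hz: tuple[float, float],
                        thresholds: Sequence[float]) -> np.ndarray:
    """Threshold trials into len(thresholds)+1 ordered classes by relative
    band power."""
    th = np.asarray(thresholds, dtype=float)
    powers = np.array([relative_band_power(t, recs.sr, band_hz)
                       for t in recs.trials])
    return np.searchsorted(th, powers).astype(np.int64)
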