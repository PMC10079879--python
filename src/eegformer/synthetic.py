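"""Synthetic multi-channel EEG generators.

Two families of labeled data, both deterministic given a seed:

* :func:`generate_ssvep_set` — steady-state visual evoked potential trials:
  each class is a stimulus frequency (default 8.0-15.8 Hz in 0.2 Hz steps)
  rendered as a harmonic stack whose amplitude follows an
  occipital-dominant scalp topography, on top of pink (1/f) and white noise.
  Subject-level amplitude and phase offsets are drawn once per subject so
  that cross-subject splits are genuinely harder than pooled splits.
* :func:`generate_labeled_set` — broadband 1/f EEG whose class-conditional
  band power follows a prescribed per-class gain (e.g. alpha-band power
  doubled in one class), emulating emotion/depression style datasets.

Neither generator attempts forward-modelled physiology; they exist so the
full pipeline (windowing, the convolutional front end, the three attention
stages, training and evaluation protocols) can be exercised end to end with
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import (BETA_SPECS, DEPEEG_SPEC, MONTAGE_64, SEED_SPEC,
                       DatasetSpec, RecordingSet)

#: Default stimulus frequencies: 8.0-15.8 Hz in 0.2 Hz steps (40 classes).
DEFAULT_STIMULUS_FREQS: tuple[float, ...] = tuple(
    np.round(8.0 + 0.2 * np.arange(40), 1))

# Scalp gain by 10-20 prefix: strong over occipital/parieto-occipital
# cortex, weak frontally — the usual SSVEP topography.
_REGION_GAIN = (
    ("PO", 1.0), ("CB", 0.9), ("O", 1.0), ("CP", 0.5), ("TP", 0.4),
    ("P", 0.6), ("FT", 0.15), ("FC", 0.2), ("AF", 0.15), ("Fp", 0.1),
    ("F", 0.15), ("T", 0.3), ("C", 0.3),
)


def default_channel_gain(montage: Sequence[str]) -> np.ndarray:
    """Per-channel signal gain derived from 10-20 channel-name prefixes."""
    gains = np.empty(len(montage))
    for i, name in enumerate(montage):
        for prefix, g in _REGION_GAIN:
            if name.startswith(prefix):
                gains[i] = g
                break
        else:
            gains[i] = 0.3
    return gains


@dataclass
class SimulationConfig:
    """Knobs of the SSVEP simulator; defaults emulate the 40-class benchmark.

    noise_sd scales both the white and the pink component (0 disables
    noise entirely); pink_alpha is the exponent of the 1/f^alpha amplitude
    shaping; subject_sd is the SD of the per-subject amplitude jitter.
    """

    spec: DatasetSpec
    stimulus_freqs: tuple[float, ...] = DEFAULT_STIMULUS_FREQS
    n_harmonics: int = 3
    harmonic_amps: tuple[float, ...] = (1.0, 0.5, 0.25)
    channel_gain: np.ndarray | None = None
    noise_sd: float = 0.5
    pink_alpha: float = 1.0
    subject_sd: float = 0.2
    seed: int = 0
    montage: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be >= 0")
        if self.stimulus_freqs and max(self.stimulus_freqs) >= self.spec.sr / 2:
            raise ValueError("fundamental above Nyquist")
        if not self.montage:
            if self.spec.chn == 64:
                self.montage = MONTAGE_64
            else:
                # posterior-first montage so low channel counts stay signal-rich
                self.montage = tuple(MONTAGE_64[::-1][:self.spec.chn])
        if len(self.montage) != self.spec.chn:
            raise ValueError("montage length must equal spec.chn")
        if self.channel_gain is None:
            self.channel_gain = default_channel_gain(self.montage)
        self.channel_gain = np.asarray(self.channel_gain, dtype=np.float64)


def _pink(rng: np.random.Generator, shape: tuple[int, ...], n: int,
          sr: float, alpha: float) -> np.ndarray:
    """Unit-SD 1/f^alpha noise along the last axis."""
    white = rng.standard_normal((*shape, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sr)
    w = np.zeros_like(f)
    w[1:] = f[1:] ** (-alpha)
    x = np.fft.irfft(spec * w, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_ssvep_set(cfg: SimulationConfig) -> RecordingSet:
    """Simulate one full campaign of SSVEP trials.

    Trial t of every experiment is assigned class ``t % n_freqs``, so the
    design is balanced whenever trials-per-experiment is a multiple of the
    class count.  The class-f signal on channel c of subject s is

        gain_c * amp_s * sum_h a_h sin(2*pi*h*f*t + phi_s)

    (harmonics above Nyquist are dropped) plus pink and white noise.
    """
    if not cfg.stimulus_freqs:
        raise ValueError("stimulus_freqs must be non-empty")
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(spec.tlpt * spec.sr))
    t = np.arange(n_samp) / spec.sr
    n_freqs = len(cfg.stimulus_freqs)
    gains = cfg.channel_gain

    trials, labels, subjects = [], [], []
    for s in range(spec.n_subjects):
        amp_s = max(0.0, 1.0 + cfg.subject_sd * rng.standard_normal())
        phi_s = rng.uniform(0, 2 * np.pi)
        for _e in range(spec.epp):
            lab = np.arange(spec.tpe) % n_freqs
            f = np.asarray(cfg.stimulus_freqs)[lab]          # (tpe,)
            sig = np.zeros((spec.tpe, n_samp))
            for h in range(1, cfg.n_harmonics + 1):
                a_h = (cfg.harmonic_amps[h - 1]
                       if h - 1 < len(cfg.harmonic_amps)
                       else cfg.harmonic_amps[-1])
                keep = (h * f) < spec.sr / 2                 # drop aliased
                sig += np.where(keep[:, None], 1.0, 0.0) * a_h * np.sin(
                    2 * np.pi * h * f[:, None] * t[None, :] + phi_s)
            block = amp_s * gains[None, :, None] * sig[:, None, :]
            if cfg.noise_sd > 0:
                block = block + cfg.noise_sd * _pink(
                    rng, (spec.tpe, spec.chn), n_samp, spec.sr, cfg.pink_alpha)
                block = block + cfg.noise_sd * rng.standard_normal(block.shape)
            trials.extend(block)
            labels.extend(lab)
            subjects.extend([s] * spec.tpe)
    return RecordingSet(list(trials), np.array(labels), np.array(subjects),
                        cfg.montage, spec.sr)


@dataclass(frozen=True)
class BandPowerEffect:
    """Per-class multiplicative power gain inside one frequency band."""

    band_hz: tuple[float, float] = (8.0, 13.0)
    factors: tuple[float, ...] = (1.0, 2.0)

    def __post_init__(self):
        if any(f <= 0 for f in self.factors):
            raise ValueError("band-power factors must be positive")
        if not 0 <= self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must be an increasing pair")


def generate_labeled_set(cfg: SimulationConfig, n_classes: int,
                         effect: BandPowerEffect) -> RecordingSet:
    """Broadband 1/f EEG with class-dependent band power.

    Class labels cycle through trials in generation order, so the label
    histogram is uniform whenever the trial count divides evenly.  The
    class-k trial has its amplitude spectrum inside ``effect.band_hz``
    multiplied by sqrt(factors[k]) (a pure power gain; phases untouched).
    """
    if len(effect.factors) != n_classes:
        raise ValueError("effect must list one factor per class")
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(spec.tlpt * spec.sr))
    f = np.fft.rfftfreq(n_samp, 1.0 / spec.sr)
    in_band = (f >= effect.band_hz[0]) & (f < effect.band_hz[1])

    trials, labels, subjects = [], [], []
    k = 0
    for s in range(spec.n_subjects):
        amp_s = max(0.0, 1.0 + cfg.subject_sd * rng.standard_normal())
        for _e in range(spec.epp):
            for _t in range(spec.tpe):
                lab = k % n_classes
                k += 1
                base = _pink(rng, (spec.chn,), n_samp, spec.sr, cfg.pink_alpha)
                sp = np.fft.rfft(base, axis=-1)
                sp[:, in_band] *= np.sqrt(effect.factors[lab])
                x = amp_s * np.fft.irfft(sp, n=n_samp, axis=-1)
                if cfg.noise_sd > 0:
                    x = x + cfg.noise_sd * rng.standard_normal(x.shape)
                trials.append(x)
                labels.append(lab)
                subjects.append(s)
    return RecordingSet(trials, np.array(labels), np.array(subjects),
                        cfg.montage, spec.sr)


# -- presets -----------------------------------------------------------------

#: Desk-scale versions of the three benchmark designs (full channel counts
#: and sampling rates; reduced subject/trial counts and trial lengths so a
#: preset generates in seconds on one CPU).
PRESETS: dict[str, DatasetSpec] = {
    "beta": DatasetSpec(5, 1, 40, 64, 250.0, 2.0,
                        tuple(str(f) for f in DEFAULT_STIMULUS_FREQS)),
    "seed": DatasetSpec(5, 1, 15, 62, 200.0, 10.0,
                        ("positive", "neutral", "negative")),
    "depeeg": DatasetSpec(8, 1, 4, 6, 500.0, 10.0,
                          ("control", "depressive")),
}

#: Full-size design parameters, for the sample-count arithmetic.
FULL_SPECS = {
    "beta": list(BETA_SPECS),
    "seed": [SEED_SPEC],
    "depeeg": [DEPEEG_SPEC],
}


def generate_preset(name: str, seed: int = 0) -> RecordingSet:
    """Generate a desk-scale synthetic stand-in for one benchmark design."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(PRESETS)}") from None
    cfg = SimulationConfig(spec=spec, seed=seed)
    if name == "beta":
        return generate_ssvep_set(cfg)
    if name == "seed":
        return generate_labeled_set(
            cfg, 3, BandPowerEffect(factors=(1.0, 1.6, 2.4)))
    return generate_labeled_set(cfg, 2, BandPowerEffect(factors=(1.0, 2.0)))
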