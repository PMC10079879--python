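"""EEG recording containers, preprocessing and windowing.

A :class:`RecordingSet` holds continuous multi-channel trials with per-trial
class labels and subject ids.  Trials are windowed into fixed-length,
non-overlapping segments (the model's input unit); each segment is linearly
detrended and z-scored per channel.  The module also carries the design
arithmetic that relates a dataset layout (subjects x experiments x trials x
trial length) to the number of windows a given window ratio produces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

# Standard 10-20 names for the default 64-channel cap.  Ordered roughly
# front-to-back; contains every channel the named occipital/parietal subsets
# below refer to.
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "CB1", "CB2",
)
assert len(MONTAGE_64) == 64

_CP32 = (
    ("O1", "Oz", "O2")
    + ("PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8")
    + ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8")
    + ("CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6")
    + ("C3", "C1", "Cz", "C2", "C4", "FCz")
)

#: Named channel subsets used in the channel-count experiments: three
#: occipital electrodes, six/nine occipito-parietal ones, a 32-channel
#: posterior+central selection, and the full cap.
NAMED_SUBSETS: dict[str, tuple[str, ...]] = {
    "occ3": ("O1", "Oz", "O2"),
    "occ6": ("O1", "Oz", "O2", "POz", "PO3", "PO4"),
    "occ9": ("O1", "Oz", "O2", "Pz", "PO3", "PO5", "PO4", "PO6", "POz"),
    "cp32": _CP32,
    "all64": MONTAGE_64,
}
assert len(NAMED_SUBSETS["cp32"]) == 32


@dataclass(frozen=True)
class DatasetSpec:
    """Design parameters of an EEG data-collection campaign.

    Parameters
    ----------
    n_subjects : participants in the campaign.
    epp : experiments (sessions) per participant.
    tpe : trials per experiment.
    chn : EEG channel count.
    sr : sampling rate in Hz.
    tlpt : trial length in seconds.
    class_labels : label vocabulary (class names or stimulus frequencies).
    """

    n_subjects: int
    epp: int
    tpe: int
    chn: int
    sr: float
    tlpt: float
    class_labels: tuple = ()

    def __post_init__(self):
        for name in ("n_subjects", "epp", "tpe", "chn"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sr <= 0:
            raise ValueError("sr must be positive")
        if self.tlpt <= 0:
            raise ValueError("tlpt must be positive")


@dataclass
class RecordingSet:
    """Continuous EEG trials with aligned labels and subject ids."""

    trials: list[np.ndarray]
    labels: np.ndarray
    subject_ids: np.ndarray
    montage: tuple[str, ...]
    sr: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        n = len(self.trials)
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels and subject_ids must align 1:1 with trials")
        chn = len(self.montage)
        for i, t in enumerate(self.trials):
            if t.ndim != 2 or t.shape[0] != chn:
                raise ValueError(
                    f"trial {i} has shape {t.shape}; expected ({chn}, n_samples)")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return len(self.montage)


@dataclass
class SegmentBatch:
    """Fixed-length windows (segments) cut from trials.

    ``segments`` has shape (n_segments, S, L) with L = round(ratio * sr);
    every segment inherits its parent trial's label and subject id.
    """

    segments: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    ratio: float
    sr: float
    montage: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n, S, L)")
        L = int(round(self.ratio * self.sr))
        if self.segments.shape[0] and self.segments.shape[2] != L:
            raise ValueError(
                f"segment length {self.segments.shape[2]} != round(ratio*sr)={L}")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def window_length(self) -> int:
        return int(round(self.ratio * self.sr))


def detrend_normalize(segment: np.ndarray) -> np.ndarray:
    """Remove each channel's least-squares linear trend, then z-score it.

    Channels with zero residual variance (e.g. a pure ramp) come out
    all-zero.  Input shape (S, L) is preserved.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim != 2 or seg.shape[1] < 2:
        raise ValueError("segment must be (S, L) with L >= 2")
    if not np.all(np.isfinite(seg)):
        bad = np.argwhere(~np.isfinite(seg))[0]
        raise ValueError(
            f"non-finite value at channel {bad[0]}, sample {bad[1]}")
    L = seg.shape[1]
    t = np.arange(L, dtype=np.float64)
    t_c = t - t.mean()
    denom = (t_c ** 2).sum()
    slope = (seg * t_c).sum(axis=1) / denom
    detr = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t_c
    sd = detr.std(axis=1)
    out = np.zeros_like(detr)
    nz = sd > 0
    out[nz] = detr[nz] / sd[nz, None]
    return out


def segment_trials(recs: RecordingSet, ratio: float,
                   preprocess: bool = True) -> SegmentBatch:
    """Cut every trial into non-overlapping windows of round(ratio*sr) samples.

    Windows are taken left to right; a trailing remainder shorter than one
    window is dropped.  Trials shorter than one window contribute nothing
    (logged as a warning).  Each window inherits its trial's label and
    subject id and, by default, is detrended and z-scored per channel.
    """
    window = int(round(ratio * recs.sr))
    if window < 10:
        raise ValueError(f"window of {window} samples is too short "
                         "(ratio * sr must be >= 10)")
    segs, labels, subjects = [], [], []
    for trial, lab, sub in zip(recs.trials, recs.labels, recs.subject_ids):
        n_win = trial.shape[1] // window
        if n_win == 0:
            logger.warning(
                "trial with %d samples shorter than window %d: skipped",
                trial.shape[1], window)
            continue
        for w in range(n_win):
            seg = trial[:, w * window:(w + 1) * window]
            segs.append(detrend_normalize(seg) if preprocess else seg)
            labels.append(lab)
            subjects.append(sub)
    if segs:
        arr = np.stack(segs)
    else:
        arr = np.empty((0, recs.n_channels, window))
    return SegmentBatch(arr, np.array(labels, dtype=np.int64),
                        np.array(subjects, dtype=np.int64),
                        ratio=ratio, sr=recs.sr, montage=recs.montage)


def expected_sample_count(spec: DatasetSpec | Iterable[DatasetSpec],
                          ratio: float) -> int:
    """Total window count implied by the design arithmetic.

    N = sum over sub-populations of n_subjects * epp * tpe * tlpt / ratio,
    truncated to an integer.  Designs whose subjects have different trial
    lengths (e.g. a cohort split between 2 s and 3 s stimulation) are passed
    as an iterable of one spec per sub-population.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    specs = [spec] if isinstance(spec, DatasetSpec) else list(spec)
    total = 0.0
    for s in specs:
        total += s.n_subjects * s.epp * s.tpe * s.tlpt / ratio
    return int(total)  # truncate toward zero


def count_trials(spec: DatasetSpec) -> int:
    """Number of trials in the design: subjects x experiments x trials."""
    return spec.n_subjects * spec.epp * spec.tpe


def crop_trials(recs: RecordingSet, pre_s: float = 0.5,
                post_s: float = 0.5) -> RecordingSet:
    """Trim a cue interval from the start and an offset from the end of every
    trial (gaze-shift removal for cued SSVEP recordings)."""
    pre = int(round(pre_s * recs.sr))
    post = int(round(post_s * recs.sr))
    trials = []
    for t in recs.trials:
        if t.shape[1] <= pre + post:
            raise ValueError("trial too short for requested crop")
        trials.append(t[:, pre:t.shape[1] - post])
    return RecordingSet(trials, recs.labels.copy(), recs.subject_ids.copy(),
                        recs.montage, recs.sr)


def select_channels(recs: RecordingSet,
                    subset: str | Sequence[str]) -> RecordingSet:
    """Restrict (and reorder) a recording set to a channel subset.

    `subset` is either a registered name ("occ3", "occ6", "occ9", "cp32",
    "all64") or an explicit list of channel names; output rows follow the
    subset's order.
    """
    if isinstance(subset, str):
        try:
            names: Sequence[str] = NAMED_SUBSETS[subset]
        except KeyError:
            raise KeyError(
                f"unknown subset {subset!r}; registered: "
                f"{sorted(NAMED_SUBSETS)}") from None
    else:
        names = tuple(subset)
    index = {ch: i for i, ch in enumerate(recs.montage)}
    missing = [ch for ch in names if ch not in index]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    rows = [index[ch] for ch in names]
    trials = [t[rows, :] for t in recs.trials]
    return RecordingSet(trials, recs.labels.copy(), recs.subject_ids.copy(),
                        tuple(names), recs.sr)


# -- on-disk fixtures and EDF -----------------------------------------------

def save_recording_set(recs: RecordingSet, path) -> None:
    """Write a RecordingSet to an HDF5 container (bit-exact round-trip)."""
    with h5py.File(path, "w", track_order=False) as f:
        g = f.create_group("trials")
        for i, t in enumerate(recs.trials):
            g.create_dataset(f"{i:06d}", data=t, track_times=False)
        f.create_dataset("labels", data=recs.labels, track_times=False)
        f.create_dataset("subjects", data=recs.subject_ids, track_times=False)
        f.attrs["sr"] = recs.sr
        f.attrs["montage"] = list(recs.montage)


def load_recording_set(path) -> RecordingSet:
    with h5py.File(path, "r") as f:
        keys = sorted(f["trials"].keys())
        trials = [f["trials"][k][()] for k in keys]
        labels = f["labels"][()]
        subjects = f["subjects"][()]
        sr = float(f.attrs["sr"])
        montage = tuple(str(c) for c in f.attrs["montage"])
    return RecordingSet(trials, labels, subjects, montage, sr)


def read_edf(path, label: int = 0, subject_id: int = 0) -> RecordingSet:
    """Read one EDF recording as a single-trial RecordingSet (requires mne)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF files requires the 'mne' package") from e
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    return RecordingSet([np.asarray(data, dtype=np.float64)],
                        np.array([label]), np.array([subject_id]),
                        tuple(raw.ch_names), float(raw.info["sfreq"]))


# -- reference designs -------------------------------------------------------

#: The three benchmark designs the synthetic generators emulate.  The SSVEP
#: benchmark ("beta") splits its cohort between 2 s and 3 s stimulation, so
#: it is a list of two sub-population specs.
BETA_SPECS: tuple[DatasetSpec, DatasetSpec] = (
    DatasetSpec(15, 4, 40, 64, 250.0, 2.0),
    DatasetSpec(55, 4, 40, 64, 250.0, 3.0),
)
BETA_SPEC_TOTAL = DatasetSpec(70, 4, 40, 64, 250.0, 3.0)  # trial count only
SEED_SPEC = DatasetSpec(15, 3, 15, 62, 200.0, 305.0,
                        ("positive", "neutral", "negative"))
DEPEEG_SPEC = DatasetSpec(35, 1, 1, 6, 500.0, 480.0,
                          ("control", "depressive"))
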