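"""Cue-aligned epoch extraction and resampling for continuous EEG.

The decoder's only preprocessing is data segmentation: epochs are integer
slices of the raw recording (no filtering, no artifact handling), aligned to
cue events.  Windows are specified in seconds relative to the cue onset and
interpreted half-open, ``[start, end)``, with 0-based sample indexing, so a
window of length L seconds at sampling rate fs yields exactly
``round(L * fs)`` samples — e.g. [1.5 s, 6 s] at 250 Hz gives 1,125 samples
and [0 s, 4 s] gives 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .synthetic import TrialSet

__all__ = [
    "ContinuousRecording",
    "EventList",
    "SegmentWindow",
    "segment_trials",
    "resample_recording",
    "dataset_window",
    "load_real_dataset",
    "DATASET_WINDOWS",
    "ExternalDataMissing",
]


class ExternalDataMissing(FileNotFoundError):
    """Raised when an optional real-EEG dataset is not on disk."""


@dataclass
class ContinuousRecording:
    """A continuous multi-channel recording."""

    data: np.ndarray          # (n_electrodes, n_samples)
    fs: float
    electrode_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"data must be (electrodes, samples), "
                             f"got {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in recording")
        if not self.electrode_names:
            self.electrode_names = [f"E{i:02d}" for i in
                                    range(self.data.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventList:
    """Cue onsets (0-based sample indices) with integer class labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.onsets.shape != self.labels.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and labels must be 1-D and equal length")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class SegmentWindow:
    """Epoch window in seconds relative to cue onset, half-open [start, end)."""

    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must exceed start {self.start}")

    def n_samples(self, fs: float) -> int:
        return int(round((self.end - self.start) * fs))


DATASET_WINDOWS = {
    "bci2a": SegmentWindow(1.5, 6.0),
    "bci2b": SegmentWindow(0.0, 4.0),
    "hgd": SegmentWindow(0.0, 4.0),
}


def dataset_window(dataset_name: str) -> SegmentWindow:
    """The published epoching window for a supported dataset."""
    try:
        return DATASET_WINDOWS[dataset_name]
    except KeyError:
        raise ValueError(
            f"unknown dataset {dataset_name!r}; "
            f"known: {sorted(DATASET_WINDOWS)}") from None


def segment_trials(rec: ContinuousRecording, events: EventList,
                   window: SegmentWindow,
                   subject: int = 0, session: int = 0) -> TrialSet:
    """Cut one epoch per event; each epoch is an exact slice of the recording.

    Epoch sample j equals recording sample ``onset + round(start*fs) + j``.
    Raises if any epoch would leave the recording, naming the event.
    """
    fs = rec.fs
    offset = int(round(window.start * fs))
    length = window.n_samples(fs)
    n_ev = len(events)
    epochs = np.empty((n_ev, rec.data.shape[0], length), dtype=np.float32)
    for i, onset in enumerate(events.onsets):
        lo = int(onset) + offset
        hi = lo + length
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"event {i} (onset sample {onset}): window "
                f"[{lo}, {hi}) exceeds recording bounds [0, {rec.n_samples})")
        epochs[i] = rec.data[:, lo:hi]
    return TrialSet(epochs, events.labels,
                    np.full(n_ev, subject), np.full(n_ev, session),
                    fs, list(rec.electrode_names))


def resample_recording(rec: ContinuousRecording,
                       target_fs: float) -> ContinuousRecording:
    """Anti-aliased polyphase resampling to ``target_fs``.

    Output length is ``round(n_samples * target_fs / fs)``.  Upsampling is
    allowed (flagged via a warning); equal rates return the data unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.fs:
        return ContinuousRecording(rec.data.copy(), rec.fs,
                                   list(rec.electrode_names))
    if target_fs > rec.fs:
        import warnings
        warnings.warn(f"upsampling from {rec.fs} Hz to {target_fs} Hz",
                      stacklevel=2)
    from fractions import Fraction
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = scipy.signal.resample_poly(rec.data.astype(np.float64), up, down,
                                     axis=-1)
    n_expect = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_expect]
    if out.shape[1] < n_expect:     # resample_poly may round the other way
        pad = n_expect - out.shape[1]
        out = np.pad(out, ((0, 0), (0, pad)), mode="edge")
    return ContinuousRecording(out.astype(np.float32), target_fs,
                               list(rec.electrode_names))


_DATASET_ELECTRODES = {"bci2a": 22, "bci2b": 3, "hgd": 44}

# standard cue event codes in the BCI Competition IV GDF annotations
_GDF_CUE_CODES = {
    "bci2a": {"769": 0, "770": 1, "771": 2, "772": 3},
    "bci2b": {"769": 0, "770": 1},
}


def load_real_dataset(path, dataset_name: str):
    """Load one session of a published MI dataset as (recording, events).

    Optional: requires the dataset files on disk and the ``mne`` reader.
    Missing files raise :class:`ExternalDataMissing` (never a parse error),
    so pipelines can cleanly skip external data that is not present.
    """
    import os

    if dataset_name not in _DATASET_ELECTRODES:
        raise ValueError(f"unknown dataset {dataset_name!r}")
    if not os.path.exists(path):
        raise ExternalDataMissing(
            f"external data not present at {path!r}; download the "
            f"{dataset_name} files to use the real-data loader")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is normally present
        raise RuntimeError("loading real datasets requires mne") from exc

    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True, eog=False, stim=False)
    n_expect = _DATASET_ELECTRODES[dataset_name]
    picks = picks[:n_expect]
    data = raw.get_data(picks=picks)
    rec = ContinuousRecording(data, float(raw.info["sfreq"]),
                              [raw.ch_names[i] for i in picks])
    ann = raw.annotations
    code_map = _GDF_CUE_CODES.get(dataset_name, {})
    onsets, labels = [], []
    for onset_s, desc in zip(ann.onset, ann.description):
        if desc in code_map:
            onsets.append(int(round(onset_s * rec.fs)))
            labels.append(code_map[desc])
    return rec, EventList(np.asarray(onsets), np.asarray(labels))
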