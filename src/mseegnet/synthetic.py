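"""Synthetic motor-imagery EEG trials with controllable class separability.

The generator emulates the physiology that motor-imagery decoders exploit:
event-related desynchronization (ERD), i.e. class-dependent attenuation of
band-limited oscillatory power over lateralized electrode groups.  Each trial
is a sum of three zero-mean processes per electrode,

    x_c(t) = g_s * [ pink_c(t) + a_alpha * m_alpha(y, c) * s_alpha(t)
                                + a_beta  * m_beta(y, c)  * s_beta(t) ],

where ``pink_c`` is independent 1/f-shaped background noise, ``s_alpha`` and
``s_beta`` are common-mode narrowband rhythms (8-12 Hz and 13-30 Hz), and the
modulation gains ``m`` attenuate the class's suppressed electrode group by
(1 - modulation_depth).  ``g_s`` is a per-subject multiplicative gain drawn
once per subject.  Class layout (contralateral ERD analogue):

    0 "left hand"  -> alpha suppressed on the right-lateral group
    1 "right hand" -> alpha suppressed on the left-lateral group
    2 "feet"       -> beta suppressed on the midline group
    3 "tongue"     -> weak symmetric alpha suppression on both lateral groups

Electrode groups are index-based: the first C//3 electrodes are
"left-lateral", the last C//3 "right-lateral", the rest "midline".
Amplitudes are in arbitrary units (unit-variance noise); only relative
contrasts matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "SyntheticConfig",
    "TrialSet",
    "generate_trial_set",
    "band_power",
    "split_by_session",
    "electrode_groups",
    "ALPHA_BAND",
    "BETA_BAND",
]

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)

# oscillation amplitudes relative to the unit-variance 1/f background, and
# the fraction of modulation_depth applied for the weakly-modulated class
ALPHA_AMP = 1.0
BETA_AMP = 0.8
WEAK_FACTOR = 0.3


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording campaign.

    ``n_trials_per_class`` counts trials per class, per subject, per session.
    """

    n_subjects: int = 1
    n_trials_per_class: int = 50
    n_classes: int = 4
    n_electrodes: int = 22
    fs: float = 250.0
    duration: float = 4.5
    modulation_depth: float = 0.5
    noise_exponent: float = 1.0
    subject_gain_sd: float = 0.1
    n_sessions: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_electrodes < 4:
            raise ValueError(
                "need at least 4 electrodes to form two lateral groups "
                "and a midline")
        if min(self.n_subjects, self.n_trials_per_class, self.n_sessions) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_timesamples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class TrialSet:
    """Epoched multi-channel trials with labels and subject/session ids."""

    data: np.ndarray          # (n_trials, n_electrodes, n_timesamples)
    labels: np.ndarray        # (n_trials,) int
    subject_id: np.ndarray    # (n_trials,) int
    session_id: np.ndarray    # (n_trials,) int
    fs: float
    electrode_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_id = np.asarray(self.subject_id, dtype=np.int64)
        self.session_id = np.asarray(self.session_id, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (trials, electrodes, samples), "
                             f"got {self.data.shape}")
        n = self.data.shape[0]
        for name, arr in (("labels", self.labels),
                          ("subject_id", self.subject_id),
                          ("session_id", self.session_id)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in trial data")
        if not self.electrode_names:
            self.electrode_names = [f"E{i:02d}" for i in
                                    range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timesamples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "TrialSet":
        """Subset by boolean mask or index array, preserving metadata."""
        return TrialSet(self.data[mask], self.labels[mask],
                        self.subject_id[mask], self.session_id[mask],
                        self.fs, list(self.electrode_names))


def electrode_groups(n_electrodes: int) -> dict[str, np.ndarray]:
    """Index-based left-lateral / midline / right-lateral electrode groups."""
    third = n_electrodes // 3
    if third < 1:
        raise ValueError("need at least 3 electrodes for groups")
    return {
        "left": np.arange(0, third),
        "mid": np.arange(third, n_electrodes - third),
        "right": np.arange(n_electrodes - third, n_electrodes),
    }


def _band_noise(rng: np.random.Generator, n_samples: int, fs: float,
                f_lo: float, f_hi: float, size: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [f_lo, f_hi] Hz.

    Spectral synthesis: complex-Gaussian coefficients on the in-band rFFT
    bins, zero elsewhere, scaled so the expected time-domain variance is 1.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    n_bins = freqs.size
    z = np.zeros((size, n_bins), dtype=np.complex128)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("band contains no FFT bins at this length")
    z[:, mask] = rng.standard_normal((size, k)) + 1j * rng.standard_normal((size, k))
    # var(irfft) = 2*sum|z_k|^2 / T^2 in expectation (interior bins)
    scale = n_samples / np.sqrt(2.0 * 2.0 * k)
    x = np.fft.irfft(z, n=n_samples, axis=-1) * scale
    return x.astype(np.float32)


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
                exponent: float, size: int = 1) -> np.ndarray:
    """Unit-variance 1/f**exponent (power) noise via spectral synthesis."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    z = (rng.standard_normal((size, freqs.size))
         + 1j * rng.standard_normal((size, freqs.size))) * amp
    scale = n_samples / np.sqrt(2.0 * 2.0 * np.sum(amp ** 2))
    x = np.fft.irfft(z, n=n_samples, axis=-1) * scale
    return x.astype(np.float32)


def _modulation_profiles(n_classes: int, n_electrodes: int,
                         depth: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-class per-electrode gains (m_alpha, m_beta), each (K, C)."""
    g = electrode_groups(n_electrodes)
    m_alpha = np.ones((n_classes, n_electrodes), dtype=np.float32)
    m_beta = np.ones((n_classes, n_electrodes), dtype=np.float32)
    m_alpha[0, g["right"]] = 1.0 - depth          # left hand: contralateral
    m_alpha[1, g["left"]] = 1.0 - depth           # right hand
    if n_classes == 4:
        m_beta[2, g["mid"]] = 1.0 - depth         # feet: midline beta ERD
        weak = 1.0 - WEAK_FACTOR * depth          # tongue: weak, symmetric
        m_alpha[3, g["left"]] = weak
        m_alpha[3, g["right"]] = weak
    return m_alpha, m_beta


def generate_trial_set(config: SyntheticConfig) -> TrialSet:
    """Draw a full labelled trial set; bit-identical for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timesamples
    C = cfg.n_electrodes
    m_alpha, m_beta = _modulation_profiles(cfg.n_classes, C,
                                           cfg.modulation_depth)
    gains = np.exp(rng.normal(0.0, cfg.subject_gain_sd, cfg.n_subjects))

    n_total = cfg.n_subjects * cfg.n_sessions * cfg.n_classes * cfg.n_trials_per_class
    data = np.empty((n_total, C, T), dtype=np.float32)
    labels = np.empty(n_total, dtype=np.int64)
    subject_id = np.empty(n_total, dtype=np.int64)
    session_id = np.empty(n_total, dtype=np.int64)

    i = 0
    for s in range(cfg.n_subjects):
        for sess in range(cfg.n_sessions):
            for y in range(cfg.n_classes):
                for _ in range(cfg.n_trials_per_class):
                    pink = _pink_noise(rng, T, cfg.fs, cfg.noise_exponent,
                                       size=C)
                    s_alpha = _band_noise(rng, T, cfg.fs, *ALPHA_BAND)[0]
                    s_beta = _band_noise(rng, T, cfg.fs, *BETA_BAND)[0]
                    trial = (pink
                             + ALPHA_AMP * m_alpha[y][:, None] * s_alpha[None, :]
                             + BETA_AMP * m_beta[y][:, None] * s_beta[None, :])
                    data[i] = gains[s] * trial
                    labels[i] = y
                    subject_id[i] = s
                    session_id[i] = sess
                    i += 1
    return TrialSet(data, labels, subject_id, session_id, cfg.fs)


def band_power(trials: TrialSet, band: tuple[float, float],
               electrodes) -> np.ndarray:
    """Per-trial mean Welch power in ``band`` over the named electrodes."""
    electrodes = np.asarray(electrodes)
    if electrodes.size == 0:
        raise ValueError("empty electrode list")
    lo, hi = band
    nyq = trials.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, fs/2) = (0, {nyq})")
    x = trials.data[:, electrodes, :]
    nperseg = min(256, trials.n_timesamples)
    freqs, psd = scipy.signal.welch(x, fs=trials.fs, nperseg=nperseg, axis=-1)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError("band contains no Welch frequency bins")
    return psd[..., sel].mean(axis=(1, 2))


def split_by_session(trials: TrialSet, train_sessions,
                     test_sessions) -> tuple[TrialSet, TrialSet]:
    """Partition trials by session id; the two lists must be disjoint."""
    train_sessions = set(int(s) for s in np.atleast_1d(train_sessions))
    test_sessions = set(int(s) for s in np.atleast_1d(test_sessions))
    if train_sessions & test_sessions:
        raise ValueError(f"overlapping session lists: "
                         f"{sorted(train_sessions & test_sessions)}")
    known = set(np.unique(trials.session_id).tolist())
    unknown = (train_sessions | test_sessions) - known
    if unknown:
        raise ValueError(f"unknown session id(s): {sorted(unknown)}")
    tr_mask = np.isin(trials.session_id, sorted(train_sessions))
    te_mask = np.isin(trials.session_id, sorted(test_sessions))
    return trials.select(tr_mask), trials.select(te_mask)
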