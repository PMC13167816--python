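"""Synthetic multichannel EEG-like data with class and subject structure.

The generator produces two-class datasets shaped like a clinical
multichannel recording campaign: several subjects per class, several
fixed-length segments per subject, 35 channels at 500 Hz by default
(15-second segments of 7500 samples).  Class 1 ("epileptic") segments carry
additive 3 Hz spike-wave-like oscillatory bursts on a fixed subset of
channels, so that during a burst those channels transiently dominate the
amplitude ranking — exactly the statistic the channel-identity transform
measures.  Each subject has a private per-channel gain vector shared by all
of that subject's segments, creating the subject-level signature that makes
leave-one-subject-out evaluation harder than segment-level k-fold.

The baseline is per-channel AR(1) noise; no claim of physiological realism
is made beyond the transient channel-dominance structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = ["SimConfig", "EegSegment", "generate_dataset", "write_dataset"]

AR_COEFF = 0.9  # baseline AR(1) coefficient
BURST_FREQ_HZ = 3.0  # spike-wave-like fundamental
BURST_DURATION_S = (0.5, 2.0)  # uniform burst-duration range


def _default_burst_channels(n_channels: int) -> tuple[int, ...]:
    # For the canonical 35-channel montage, burst on the temporal-lobe
    # positions of the default LUT; otherwise on the leading quarter of
    # the channels.
    if n_channels == 35:
        return (16, 17, 18, 19, 34, 35)
    return tuple(range(1, max(2, n_channels // 4) + 1))


@dataclass(frozen=True)
class EegSegment:
    """One multichannel recording window.

    ``data`` is (n_samples, n_channels); ``label`` follows the 1 = epilepsy,
    2 = control convention; ``sampling_rate`` is metadata only.
    """

    data: np.ndarray
    subject_id: str
    label: int
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2 or d.shape[0] < 2 or d.shape[1] < 2:
            raise ValueError("segment data must be (n_samples >= 2, n_channels >= 2)")
        if not np.all(np.isfinite(d)):
            raise ValueError("segment data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic dataset generator.

    Defaults emulate the shape of a 35-channel, 500 Hz recording cut into
    15-second segments.

    Parameters
    ----------
    n_subjects_per_class, segments_per_subject
        Dataset bookkeeping; total segment count is
        ``2 * n_subjects_per_class * segments_per_subject``.
    burst_rate
        Expected number of burst events per class-1 segment (Poisson).
        Zero disables bursts, making the two classes exchangeable.
    burst_channels
        1-based channel indices receiving bursts.
    burst_amplitude
        Peak amplitude of a burst, in units of the baseline noise scale;
        the default 6.0 makes burst channels clearly dominant while active.
    subject_gain_sd
        Standard deviation of per-subject, per-channel multiplicative
        gains (mean 1).  Zero removes subject structure.
    noise_sd
        Innovation scale of the AR(1) baseline.
    """

    n_subjects_per_class: int = 10
    segments_per_subject: int = 4
    n_channels: int = 35
    n_samples: int = 7500
    sampling_rate: float = 500.0
    burst_rate: float = 3.0
    burst_channels: tuple[int, ...] | None = None
    burst_amplitude: float = 6.0
    subject_gain_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_class, self.segments_per_subject) < 1:
            raise ValueError("subject and segment counts must be >= 1")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.burst_rate < 0 or self.noise_sd < 0 or self.subject_gain_sd < 0:
            raise ValueError("rates and scales must be non-negative")
        ch = self.resolved_burst_channels()
        if any(c < 1 or c > self.n_channels for c in ch):
            raise ValueError("burst_channels must lie in 1..n_channels")

    def resolved_burst_channels(self) -> tuple[int, ...]:
        if self.burst_channels is not None:
            return tuple(self.burst_channels)
        return _default_burst_channels(self.n_channels)


def _ar1_baseline(rng: np.random.Generator, n: int, cn: int, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=(n, cn))
    return lfilter([1.0], [1.0, -AR_COEFF], eps, axis=0)


def _burst_waveform(n: int, fs: float, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * BURST_FREQ_HZ * t + phase) + 0.6 * np.sin(
        2 * np.pi * 2 * BURST_FREQ_HZ * t + 2 * phase
    )
    window = np.hanning(n) if n > 2 else np.ones(n)
    return amplitude * window * wave


def generate_dataset(cfg: SimConfig) -> list[EegSegment]:
    """Generate the full labelled segment collection.

    Deterministic given the config (including seed).  Subject gains are
    drawn first for all subjects, then segment noise and bursts in a fixed
    order, so increasing ``segments_per_subject`` never perturbs the gain
    vectors of already-generated subjects.
    """
    rng = np.random.default_rng(cfg.seed)
    cn, n = cfg.n_channels, cfg.n_samples
    burst_cols = np.array(cfg.resolved_burst_channels()) - 1

    # Class 1 = epilepsy, class 2 = control.
    subjects = [(f"S{c}{s:02d}", c) for c in (1, 2) for s in range(1, cfg.n_subjects_per_class + 1)]
    gains = {
        sid: 1.0 + cfg.subject_gain_sd * rng.standard_normal(cn) for sid, _ in subjects
    }

    segments: list[EegSegment] = []
    for sid, label in subjects:
        gain = np.abs(gains[sid])  # keep multipliers positive
        for _ in range(cfg.segments_per_subject):
            data = _ar1_baseline(rng, n, cn, cfg.noise_sd)
            if label == 1 and cfg.burst_rate > 0:
                for _ in range(rng.poisson(cfg.burst_rate)):
                    dur = int(rng.uniform(*BURST_DURATION_S) * cfg.sampling_rate)
                    dur = max(2, min(dur, n))
                    start = int(rng.integers(0, n - dur + 1))
                    wave = _burst_waveform(dur, cfg.sampling_rate, rng, cfg.burst_amplitude * cfg.noise_sd)
                    data[start : start + dur, burst_cols] += wave[:, None]
            data *= gain[None, :]
            segments.append(
                EegSegment(data=data, subject_id=sid, label=label, sampling_rate=cfg.sampling_rate)
            )
    return segments


def write_dataset(segments: list[EegSegment], out_dir: str | Path) -> Path:
    """Persist segments as one CSV per segment plus a manifest CSV.

    Returns the manifest path.  Channel columns are named ``ch1..chN``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments, start=1):
        fname = f"segment_{i:04d}.csv"
        cols = [f"ch{j}" for j in range(1, seg.n_channels + 1)]
        pd.DataFrame(seg.data, columns=cols).to_csv(out_dir / fname, index=False)
        rows.append({"segment_file": fname, "subject_id": seg.subject_id, "label": seg.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
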