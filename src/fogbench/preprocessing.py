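"""Resampling, windowing, window labelling and per-channel normalization.

The evaluation protocol operates on fixed-length overlapping windows
(default 2 s with 50% overlap, i.e. 256 samples at 128 Hz). Recordings at a
lower rate are upsampled by an integer factor first so both regimes share a
common window shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fogbench.cohort import SensorRecording

__all__ = [
    "WindowSet",
    "NormalizerStats",
    "PreprocessConfig",
    "upsample",
    "segment",
    "window_label",
    "fit_normalizer",
    "apply_normalizer",
    "concat_windowsets",
    "preprocess_recording",
]

_SD_FLOOR = 1e-8


@dataclass
class WindowSet:
    """Segmented fixed-length windows with window-level labels."""

    windows: np.ndarray  # (N, L, C)
    labels: np.ndarray  # (N,) in {0, 1}
    subject_ids: np.ndarray  # (N,) str
    window_s: float
    overlap_frac: float
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (N, L, C)")
        n = self.windows.shape[0]
        if not (self.labels.shape[0] == n == self.subject_ids.shape[0]):
            raise ValueError("windows, labels and subject_ids must agree in N")
        L = int(round(self.window_s * self.sample_rate_hz))
        if self.windows.shape[1] != L:
            raise ValueError(
                f"window length {self.windows.shape[1]} != "
                f"round(window_s * rate) = {L}"
            )
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean()) if self.n_windows else 0.0

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            window_s=self.window_s,
            overlap_frac=self.overlap_frac,
            sample_rate_hz=self.sample_rate_hz,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Windowing pipeline settings shared by every training run."""

    target_rate_hz: int = 128
    window_s: float = 2.0
    overlap_frac: float = 0.5
    label_threshold: float = 0.5


@dataclass(frozen=True)
class NormalizerStats:
    """Per-channel standardization statistics with fit provenance.

    ``provenance`` records the subject ids whose windows the statistics were
    fit on, so leakage of test-fold subjects is checkable at run time.
    """

    mean: np.ndarray  # (C,)
    sd: np.ndarray  # (C,)
    provenance: tuple[str, ...]


def upsample(recording: SensorRecording, target_rate_hz: int) -> SensorRecording:
    """Upsample by an integer factor with linear interpolation.

    The signal is linearly interpolated between consecutive samples with the
    final sample held (there is no successor to interpolate toward); labels
    are carried by nearest neighbour. ``target_rate_hz`` must be an integer
    multiple of the recording rate; the identity factor returns the
    recording unchanged.
    """
    src = recording.sample_rate_hz
    if target_rate_hz < src:
        raise ValueError("target rate must be >= source rate")
    if target_rate_hz % src != 0:
        raise ValueError(
            f"target rate {target_rate_hz} is not an integer multiple of "
            f"source rate {src}"
        )
    factor = target_rate_hz // src
    if factor == 1:
        return recording
    T = recording.n_samples
    t_out = np.arange(T * factor) / factor
    t_src = np.arange(T, dtype=float)
    signal = np.column_stack(
        [np.interp(t_out, t_src, recording.signal[:, c]) for c in range(recording.n_channels)]
    )
    nearest = np.minimum(np.floor(t_out + 0.5).astype(int), T - 1)
    return SensorRecording(
        subject_id=recording.subject_id,
        sample_rate_hz=target_rate_hz,
        signal=signal,
        labels=recording.labels[nearest],
        channel_names=recording.channel_names,
    )


def window_label(sample_labels: np.ndarray, threshold: float = 0.5) -> int:
    """Majority-style window label: 1 iff the freeze fraction strictly exceeds ``threshold``."""
    sample_labels = np.asarray(sample_labels)
    if sample_labels.size == 0:
        raise ValueError("window_label requires at least one sample")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return int(sample_labels.mean() > threshold)


def segment(
    recording: SensorRecording,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    label_threshold: float = 0.5,
) -> WindowSet:
    """Cut a recording into overlapping fixed-length windows.

    Window length L = round(window_s * rate); stride = L * (1 - overlap);
    trailing samples that do not fill a window are discarded. Each window's
    label comes from :func:`window_label` over its sample labels.
    """
    rate = recording.sample_rate_hz
    L = int(round(window_s * rate))
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must be in [0, 1)")
    T = recording.n_samples
    if T < L:
        raise ValueError(
            f"recording has {T} samples but one window requires at least {L}"
        )
    stride = max(1, int(round(L * (1.0 - overlap_frac))))
    n = (T - L) // stride + 1
    starts = np.arange(n) * stride
    windows = np.stack([recording.signal[s : s + L] for s in starts])
    labels = np.fromiter(
        (window_label(recording.labels[s : s + L], label_threshold) for s in starts),
        dtype=np.int8,
        count=n,
    )
    return WindowSet(
        windows=windows,
        labels=labels,
        subject_ids=np.full(n, recording.subject_id, dtype=object),
        window_s=window_s,
        overlap_frac=overlap_frac,
        sample_rate_hz=rate,
    )


def fit_normalizer(train_windows: WindowSet) -> NormalizerStats:
    """Per-channel mean/sd over all training samples; sd floored at 1e-8."""
    x = train_windows.windows.astype(np.float64)
    mean = x.mean(axis=(0, 1))
    sd = np.maximum(x.std(axis=(0, 1)), _SD_FLOOR)
    return NormalizerStats(
        mean=mean,
        sd=sd,
        provenance=tuple(sorted(set(train_windows.subject_ids.tolist()))),
    )


def apply_normalizer(windows: WindowSet, stats: NormalizerStats) -> WindowSet:
    if stats.mean.shape[0] != windows.n_channels:
        raise ValueError(
            f"normalizer was fit on {stats.mean.shape[0]} channels but windows "
            f"have {windows.n_channels}"
        )
    out = windows.subset(np.arange(windows.n_windows))
    out.windows = ((windows.windows - stats.mean) / stats.sd).astype(np.float32)
    return out


def concat_windowsets(parts: list[WindowSet]) -> WindowSet:
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if (p.window_s, p.overlap_frac, p.sample_rate_hz) != (
            first.window_s,
            first.overlap_frac,
            first.sample_rate_hz,
        ):
            raise ValueError("window sets have incompatible segmentation settings")
    return WindowSet(
        windows=np.concatenate([p.windows for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        window_s=first.window_s,
        overlap_frac=first.overlap_frac,
        sample_rate_hz=first.sample_rate_hz,
    )


def preprocess_recording(
    recording: SensorRecording, config: PreprocessConfig
) -> WindowSet:
    """Upsample to the common rate then segment — one subject's windows."""
    rec = upsample(recording, config.target_rate_hz)
    return segment(
        rec,
        window_s=config.window_s,
        overlap_frac=config.overlap_frac,
        label_threshold=config.label_threshold,
    )
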