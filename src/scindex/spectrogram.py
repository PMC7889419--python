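"""STFT spectrogram patches: one 124 x 124 image per 10-s PPG window.

A 5-minute recording is cut into thirty non-overlapping 10-s windows.
Within each window, 6.3-s segments taken every 0.03 s (6.27-s overlap)
are Hamming-windowed and Fourier-transformed; at 300 Hz this is a
1890-sample segment advancing 9 samples per frame, giving exactly
floor((3000 - 1890) / 9) + 1 = 124 time frames.  The FFT is zero-padded
to 3690 points so the bin spacing is 300 / 3690 ~ 0.0813 Hz and bins
0..123 tile 0-10 Hz: a 124 x 124 frequency-by-time patch.

Magnitudes are compressed as log(1 + |S|) by default and each patch is
min-max scaled to [0, 1] before it reaches the network; both steps are
configurable.  Any parameter set whose geometry does not reproduce the
configured patch shape is rejected eagerly rather than resized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hamming

from .errors import ConfigError, TooShortError
from .synth import PPGRecording

__all__ = [
    "SpectrogramParams",
    "SpectrogramPatch",
    "segment_windows",
    "stft_patch",
    "make_patches",
    "patches_to_arrays",
    "save_patches_h5",
    "load_patches_h5",
]


@dataclass(frozen=True)
class SpectrogramParams:
    """Geometry and scaling of the time-frequency patches."""

    patch_window_s: float = 10.0
    patch_hop_s: float = 10.0
    segment_len_s: float = 6.3
    segment_overlap_s: float = 6.27
    window_fn: str = "hamming"
    freq_min: float = 0.0
    freq_max: float = 10.0
    n_freq_bins: int = 124
    n_time_frames: int = 124
    fft_len: int = 3690
    magnitude_scale: str = "log"
    minmax_scale: bool = True

    def __post_init__(self):
        if not 0 < self.segment_overlap_s < self.segment_len_s < self.patch_window_s:
            raise ConfigError("need 0 < segment_overlap_s < segment_len_s < patch_window_s")
        if self.magnitude_scale not in ("linear", "log"):
            raise ConfigError(f"unknown magnitude_scale {self.magnitude_scale!r}")
        if self.window_fn != "hamming":
            raise ConfigError(f"unsupported window_fn {self.window_fn!r}")

    # -- geometry in samples, at a given sampling rate ------------------
    def patch_len(self, fs: float) -> int:
        return int(round(self.patch_window_s * fs))

    def segment_len(self, fs: float) -> int:
        return int(round(self.segment_len_s * fs))

    def hop(self, fs: float) -> int:
        h = int(round((self.segment_len_s - self.segment_overlap_s) * fs))
        return max(h, 1)

    def freq_bins(self, fs: float) -> np.ndarray:
        """Indices of FFT bins whose centre lies in [freq_min, freq_max],
        with a half-spacing tolerance at the top edge."""
        freqs = np.fft.rfftfreq(self.fft_len, 1.0 / fs)
        df = fs / self.fft_len
        mask = (freqs >= self.freq_min - df / 2) & (freqs <= self.freq_max + df / 2)
        return np.nonzero(mask)[0]

    def validate(self, fs: float) -> None:
        """Reject geometries that do not yield the configured patch shape."""
        n_frames = (self.patch_len(fs) - self.segment_len(fs)) // self.hop(fs) + 1
        if n_frames != self.n_time_frames:
            raise ConfigError(
                f"frame geometry yields {n_frames} time frames per patch, "
                f"expected {self.n_time_frames} (patch {self.patch_len(fs)} samples, "
                f"segment {self.segment_len(fs)}, hop {self.hop(fs)})")
        n_bins = self.freq_bins(fs).size
        if n_bins != self.n_freq_bins:
            raise ConfigError(
                f"fft_len {self.fft_len} at fs {fs} gives {n_bins} bins in "
                f"[{self.freq_min}, {self.freq_max}] Hz, expected {self.n_freq_bins}")
        if self.fft_len < self.segment_len(fs):
            raise ConfigError("fft_len must be >= the segment length in samples")


@dataclass(frozen=True)
class SpectrogramPatch:
    """One 124 x 124 non-negative frequency-by-time image with provenance."""

    matrix: np.ndarray
    patch_index: int
    start_time_s: float
    subject_id: str = "S000"
    condition: str = "baseline"
    vas: int | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ConfigError("patch matrix must be 2-D")
        if not np.all(np.isfinite(m)):
            raise ConfigError("patch matrix contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def label(self) -> int | None:
        if self.vas is None:
            return None
        return 1 if self.vas > 0 else 0


def segment_windows(rec: PPGRecording,
                    params: SpectrogramParams = SpectrogramParams()) -> list[np.ndarray]:
    """Consecutive non-overlapping 10-s windows; the trailing remainder
    shorter than one window is dropped."""
    plen = params.patch_len(rec.fs)
    if rec.samples.size < plen:
        raise TooShortError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{params.patch_window_s:.0f}-s patch window")
    n = rec.samples.size // plen
    return [rec.samples[k * plen:(k + 1) * plen] for k in range(n)]


def _stft_magnitude(window_signal: np.ndarray, fs: float,
                    params: SpectrogramParams) -> np.ndarray:
    seg = params.segment_len(fs)
    hop = params.hop(fs)
    win = hamming(seg, sym=True)
    frames = sliding_window_view(window_signal, seg)[::hop][:params.n_time_frames]
    spec = np.abs(np.fft.rfft(frames * win, n=params.fft_len, axis=1))
    return spec[:, params.freq_bins(fs)].T  # (freq, time)


def stft_patch(window_signal: np.ndarray, fs: float,
               params: SpectrogramParams = SpectrogramParams(), *,
               patch_index: int = 0, start_time_s: float = 0.0,
               subject_id: str = "S000", condition: str = "baseline",
               vas: int | None = None) -> SpectrogramPatch:
    """Transform one 10-s signal into a spectrogram patch."""
    params.validate(fs)
    window_signal = np.asarray(window_signal, dtype=np.float64)
    if window_signal.size != params.patch_len(fs):
        raise ConfigError(
            f"window has {window_signal.size} samples, expected {params.patch_len(fs)}")
    mat = _stft_magnitude(window_signal, fs, params)
    if params.magnitude_scale == "log":
        mat = np.log1p(mat)
    if params.minmax_scale:
        lo, hi = float(mat.min()), float(mat.max())
        if hi > lo:
            mat = (mat - lo) / (hi - lo)
        else:
            mat = np.zeros_like(mat)
    return SpectrogramPatch(matrix=mat, patch_index=patch_index,
                            start_time_s=start_time_s, subject_id=subject_id,
                            condition=condition, vas=vas)


def make_patches(rec: PPGRecording,
                 params: SpectrogramParams = SpectrogramParams()) -> list[SpectrogramPatch]:
    """All patches of a recording, indexed from 0 in time order."""
    params.validate(rec.fs)
    return [
        stft_patch(w, rec.fs, params, patch_index=k,
                   start_time_s=k * params.patch_window_s,
                   subject_id=rec.subject_id, condition=rec.condition, vas=rec.vas)
        for k, w in enumerate(segment_windows(rec, params))
    ]


def patches_to_arrays(patches: Sequence[SpectrogramPatch]):
    """Stack patches into (X, labels, subject_ids, patch_index, start_time_s)."""
    x = np.stack([p.matrix for p in patches]).astype(np.float32)
    labels = np.array([-1 if p.label is None else p.label for p in patches])
    subjects = np.array([p.subject_id for p in patches])
    idx = np.array([p.patch_index for p in patches])
    t0 = np.array([p.start_time_s for p in patches])
    return x, labels, subjects, idx, t0


def save_patches_h5(path, patches: Iterable[SpectrogramPatch], *,
                    config_hash: str = "") -> None:
    patches = list(patches)
    x, labels, subjects, idx, t0 = patches_to_arrays(patches)
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=x)
        f.create_dataset("labels", data=labels)
        f.create_dataset("subject_ids", data=subjects.astype("S"))
        f.create_dataset("patch_index", data=idx)
        f.create_dataset("start_time_s", data=t0)
        f.attrs["config_hash"] = config_hash


def load_patches_h5(path):
    with h5py.File(path, "r") as f:
        x = f["patches"][:]
        labels = f["labels"][:]
        subjects = f["subject_ids"][:].astype(str)
        idx = f["patch_index"][:]
        t0 = f["start_time_s"][:]
        config_hash = str(f.attrs.get("config_hash", ""))
    return x, labels, subjects, idx, t0, config_hash
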