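"""Band-limited power spectrograms for low-frequency seal vocalizations.

The analysis convention throughout the package: frames start at hop-spaced
sample offsets (no edge padding, no centering), each frame is Hann-windowed
and transformed with a one-sided DFT, and the spectrogram cell holds the
squared magnitude (doubled for non-DC/non-Nyquist bins so that summing a
frame's cells conserves the windowed frame's energy up to the Parseval
factor ``n_dft``).  Energies stay linear; dB conversion happens only at
presentation.  Frequency bin ``k`` is labelled by its center ``k * Δf``
(0-based), frame ``i`` by its start time ``i * hop / fs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

__all__ = [
    "SpectrogramConfig",
    "Spectrogram",
    "compute_spectrogram",
    "frequency_resolution",
    "time_resolution",
    "filter_bandwidth_3db",
    "bandpass",
    "read_wav",
    "write_wav",
    "plot_spectrogram",
]

#: 3-dB main-lobe width of the Hann window, in DFT bins.
HANN_3DB_BINS = 1.44


@dataclass(frozen=True)
class SpectrogramConfig:
    """Analysis settings for a short-time power spectrogram.

    Defaults are the measurement settings used for the monk seal call
    analysis: 8192-point DFT, Hann window, 90% overlap, 20–1000 Hz band.
    """

    sample_rate: int
    n_dft: int = 8192
    overlap_fraction: float = 0.90
    window_name: str = "hann"
    band_low: float = 20.0
    band_high: float = 1000.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or int(self.sample_rate) != self.sample_rate:
            raise ValueError("sample_rate must be a positive integer")
        if self.n_dft <= 0 or int(self.n_dft) != self.n_dft:
            raise ValueError("n_dft must be a positive integer")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.0 <= self.band_low < self.band_high <= self.sample_rate / 2:
            raise ValueError(
                "band must satisfy 0 <= band_low < band_high <= Nyquist"
            )
        if self.hop_samples < 1:
            raise ValueError("hop must be at least one sample")

    @property
    def hop_samples(self) -> int:
        """Frame advance in samples: floor(n_dft * (1 - overlap))."""
        return math.floor(self.n_dft * (1.0 - self.overlap_fraction))


def frequency_resolution(config: SpectrogramConfig) -> float:
    """DFT bin spacing in Hz (sample_rate / n_dft).

    96 kHz / 8192 gives 11.72 Hz; 48 kHz / 8192 gives 5.86 Hz.
    """
    return config.sample_rate / config.n_dft


def time_resolution(config: SpectrogramConfig) -> float:
    """Frame spacing in seconds (hop_samples / sample_rate)."""
    return config.hop_samples / config.sample_rate


def filter_bandwidth_3db(config: SpectrogramConfig) -> float:
    """3-dB analysis-filter bandwidth in Hz for the configured window.

    For the Hann window this is 1.44 bins, i.e. 16.9 Hz at 96 kHz / 8192.
    """
    if config.window_name.lower() != "hann":
        raise ValueError(
            f"3-dB bandwidth factor known only for 'hann', got {config.window_name!r}"
        )
    return HANN_3DB_BINS * frequency_resolution(config)


@dataclass
class Spectrogram:
    """One-sided power spectrogram: ``energy[bin, frame]`` >= 0."""

    energy: np.ndarray
    freq_resolution: float
    time_step: float
    start_offset: float = 0.0
    config: SpectrogramConfig | None = None
    start_bin: int = 0

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.ndim != 2:
            raise ValueError("energy must be a 2-D (bin x frame) matrix")
        if np.any(self.energy < 0) or not np.all(np.isfinite(self.energy)):
            raise ValueError("energy cells must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.energy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.energy.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Bin center frequencies, (start_bin + k) * freq_resolution."""
        return (self.start_bin + np.arange(self.n_bins)) * self.freq_resolution

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds relative to the source audio."""
        return self.start_offset + np.arange(self.n_frames) * self.time_step


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: int,
    config: SpectrogramConfig | None = None,
    *,
    drop_out_of_band: bool = False,
    start_offset: float = 0.0,
) -> Spectrogram:
    """Short-time one-sided power spectrogram of a mono waveform.

    Parameters
    ----------
    waveform
        Mono samples; must contain at least one full frame of ``n_dft``
        samples and no non-finite values.
    sample_rate
        Sampling rate in Hz; must match ``config.sample_rate``.
    config
        Analysis settings; defaults to ``SpectrogramConfig(sample_rate)``.
    drop_out_of_band
        If True, bins outside [band_low, band_high] are removed (the bin
        axis then starts at the first in-band bin); otherwise they are
        kept and zeroed so bin indices stay global.
    start_offset
        Time of the first sample within the source recording, so that
        selection boxes in source-time map correctly onto frames.
    """
    if config is None:
        config = SpectrogramConfig(sample_rate=int(sample_rate))
    if config.sample_rate != sample_rate:
        raise ValueError(
            f"sample_rate {sample_rate} does not match config ({config.sample_rate})"
        )
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if x.size < config.n_dft:
        raise ValueError(
            f"waveform too short: {x.size} samples < one {config.n_dft}-sample frame"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")

    hop = config.hop_samples
    frames = sliding_window_view(x, config.n_dft)[::hop]
    win = sps.get_window(config.window_name, config.n_dft, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    # one-sided doubling; DC and (for even n_dft) Nyquist appear once
    if config.n_dft % 2 == 0:
        spec[:, 1:-1] *= 2.0
    else:
        spec[:, 1:] *= 2.0
    energy = spec.T  # (bin, frame)

    dfreq = frequency_resolution(config)
    freqs = np.arange(energy.shape[0]) * dfreq
    in_band = (freqs >= config.band_low) & (freqs <= config.band_high)
    if drop_out_of_band:
        first = int(np.argmax(in_band))
        return Spectrogram(
            energy[in_band], dfreq, time_resolution(config), start_offset, config, first
        )
    energy[~in_band] = 0.0
    return Spectrogram(energy, dfreq, time_resolution(config), start_offset, config)


def bandpass(
    waveform: np.ndarray,
    low: float,
    high: float,
    sample_rate: int,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward–backward, ``sosfiltfilt``).

    The effective attenuation is twice the one-way filter rolloff; the
    default 4th order gives well over 40 dB one octave outside the band.
    Output length equals input length and no group delay is introduced,
    so selection boundaries are not shifted.
    """
    nyq = sample_rate / 2.0
    if not 0.0 <= low < high <= nyq:
        raise ValueError(f"invalid band ({low}, {high}) for Nyquist {nyq}")
    x = np.asarray(waveform, dtype=float)
    lo = max(low, 1e-6)  # Butterworth bandpass needs a strictly positive edge
    sos = sps.butter(order, [lo, high], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def read_wav(path, channel: int | None = None) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file, returning (float samples, sample_rate).

    Integer PCM is scaled to [-1, 1).  Stereo input raises unless an
    explicit ``channel`` index is given.
    """
    from scipy.io import wavfile

    sample_rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path}: {data.shape[1]}-channel audio; pass channel= to select one"
            )
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    return data, int(sample_rate)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM WAV."""
    from scipy.io import wavfile

    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (x * 32767).astype(np.int16))


def plot_spectrogram(spec: Spectrogram, ax=None, db_floor: float = -80.0):
    """Quick-look dB image of a spectrogram (presentation only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ref = spec.energy.max()
    if ref <= 0:
        ref = 1.0
    db = 10.0 * np.log10(np.maximum(spec.energy / ref, 10 ** (db_floor / 10.0)))
    t, f = spec.times, spec.frequencies
    ax.imshow(
        db,
        origin="lower",
        aspect="auto",
        extent=(t[0], t[-1] + spec.time_step, f[0], f[-1] + spec.freq_resolution),
        cmap="magma",
        vmin=db_floor,
        vmax=0.0,
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax
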