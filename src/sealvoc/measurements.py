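"""Selection-box measurements on power spectrograms.

Implements the twelve spectral/temporal call parameters used to
characterize monk seal vocal types: total duration (DUR), 90% energy
duration (DUR90), the energy-percentile frequencies F5/F25/Fcenter/F75/F95,
the 50% and 90% bandwidths, peak frequency, aggregate entropy, and a
frame-based SNR estimate — plus the descriptive harmonic features.

Conventions
-----------
* A selection box includes spectrogram frames whose start time lies in
  ``[start_time, end_time)`` and bins whose center frequency lies in
  ``[low_freq, high_freq]``.
* Percentile frequencies use the discrete "first bin whose ascending
  cumulative energy reaches q x total" rule, no interpolation.
* DUR90 is the central interval between the first frames reaching 5% and
  95% of the in-box energy (time-marginal cumulative sum).
* DUR comes from the annotation boundaries, not from energy percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectro import Spectrogram

__all__ = [
    "Selection",
    "FeatureVector",
    "total_duration",
    "energy_duration",
    "percentile_frequency",
    "bandwidth",
    "peak_frequency",
    "aggregate_entropy",
    "snr_nist_quick",
    "count_harmonics",
    "measure_selection",
    "read_selection_table",
    "write_selection_table",
    "features_to_frame",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "DUR", "DUR90", "F5", "F25", "Fcenter", "F75", "F95",
    "BDW50", "BDW90", "Fpeak", "AE", "SNRNIST",
    "harmonics_present", "n_harmonics",
]


@dataclass(frozen=True)
class Selection:
    """A time-frequency box delimiting one call."""

    start_time: float
    end_time: float
    low_freq: float
    high_freq: float

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ValueError("start_time must precede end_time")
        if not self.low_freq < self.high_freq:
            raise ValueError("low_freq must be below high_freq")


@dataclass
class FeatureVector:
    """Measured parameters for one selection.

    Units: durations in seconds, frequencies in Hz, aggregate entropy in
    bits, SNR in dB.  Invariants: F5 <= F25 <= Fcenter <= F75 <= F95,
    BDW50 = F75 - F25, BDW90 = F95 - F5, 0 < DUR90 <= DUR, AE >= 0.
    """

    DUR: float
    DUR90: float
    F5: float
    F25: float
    Fcenter: float
    F75: float
    F95: float
    BDW50: float
    BDW90: float
    Fpeak: float
    AE: float
    SNRNIST: float | None = None
    harmonics_present: bool = False
    n_harmonics: int = 0
    n_whoops_per_bout: int | None = None
    label: str | None = None


def _box(spec: Spectrogram, sel: Selection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-box energy submatrix and the matching bin/frame index arrays."""
    t_idx = np.flatnonzero(
        (spec.times >= sel.start_time) & (spec.times < sel.end_time)
    )
    f_idx = np.flatnonzero(
        (spec.frequencies >= sel.low_freq) & (spec.frequencies <= sel.high_freq)
    )
    if t_idx.size == 0 or f_idx.size == 0:
        raise ValueError("selection does not overlap the spectrogram extent")
    return spec.energy[np.ix_(f_idx, t_idx)], f_idx, t_idx


def total_duration(sel: Selection) -> float:
    """Call duration from the annotation boundaries (seconds)."""
    return sel.end_time - sel.start_time


def energy_duration(spec: Spectrogram, sel: Selection, fraction: float = 0.9) -> float:
    """Span of the central `fraction` of in-box energy along time (seconds).

    With the default 0.9, this is the interval between the first frame at
    which the time-marginal cumulative energy reaches 5% of the total and
    the first frame reaching 95%.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    box, _, t_idx = _box(spec, sel)
    marginal = box.sum(axis=0)
    total = marginal.sum()
    if total <= 0:
        raise ValueError("empty selection: no energy inside the box")
    cum = np.cumsum(marginal)
    lo_q = (1.0 - fraction) / 2.0
    i_lo = int(np.searchsorted(cum, lo_q * total))
    i_hi = int(np.searchsorted(cum, (1.0 - lo_q) * total))
    return (i_hi - i_lo) * spec.time_step


def percentile_frequency(spec: Spectrogram, sel: Selection, q: float) -> float:
    """Center frequency of the lowest bin whose ascending cumulative
    in-box energy reaches ``q`` of the total."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    box, f_idx, _ = _box(spec, sel)
    marginal = box.sum(axis=1)
    total = marginal.sum()
    if total <= 0:
        raise ValueError("empty selection: no energy inside the box")
    cum = np.cumsum(marginal)
    k = int(np.searchsorted(cum, q * total))
    k = min(k, f_idx.size - 1)  # guard float round-off at q -> 1
    return float(spec.frequencies[f_idx[k]])


def bandwidth(fv: FeatureVector, which: int = 90) -> float:
    """Energy bandwidth: F95 - F5 (which=90) or F75 - F25 (which=50)."""
    if which == 90:
        return fv.F95 - fv.F5
    if which == 50:
        return fv.F75 - fv.F25
    raise ValueError("which must be 50 or 90")


def peak_frequency(spec: Spectrogram, sel: Selection) -> float:
    """Center frequency of the single maximum-energy cell in the box.

    Ties are broken toward the lowest frequency (then earliest frame).
    """
    box, f_idx, _ = _box(spec, sel)
    if box.max() <= 0:
        raise ValueError("empty selection: no energy inside the box")
    k, _ = np.unravel_index(int(np.argmax(box)), box.shape)
    return float(spec.frequencies[f_idx[k]])


def aggregate_entropy(spec: Spectrogram, sel: Selection) -> float:
    """Shannon entropy (bits) of the normalized in-box energy distribution.

    Low for tonal calls, high for broadband ones; zero-energy cells
    contribute nothing.  Bounded by log2(number of in-box cells).
    """
    box, _, _ = _box(spec, sel)
    total = box.sum()
    if total <= 0:
        raise ValueError("empty selection: no energy inside the box")
    p = box[box > 0] / total
    return float(-(p * np.log2(p)).sum())


def snr_nist_quick(
    waveform: np.ndarray,
    sample_rate: int,
    sel: Selection,
    *,
    frame_ms: float = 20.0,
    signal_percentile: float = 95.0,
    noise_percentile: float = 15.0,
    context_s: float = 1.0,
) -> float:
    """Frame-based signal-to-noise estimate in dB.

    The audio is partitioned into short frames (default 20 ms) and each
    frame's mean power is expressed in dB.  The signal level is a high
    percentile (default 95th) of the in-selection frames; the noise level
    is a low percentile (default 15th) of the frames spanning the
    selection plus up to ``context_s`` seconds of leading context.  When
    no leading context exists, the noise percentile falls back to the
    in-selection frames with a warning.
    """
    x = np.asarray(waveform, dtype=float)
    flen = max(1, int(round(frame_ms * 1e-3 * sample_rate)))
    i0 = max(0, int(sel.start_time * sample_rate))
    i1 = min(x.size, int(sel.end_time * sample_rate))
    if i1 - i0 < flen:
        raise ValueError("selection shorter than one analysis frame")
    c0 = max(0, i0 - int(context_s * sample_rate))

    def frame_db(lo: int, hi: int) -> np.ndarray:
        seg = x[lo:hi]
        n = seg.size // flen
        pw = (seg[: n * flen].reshape(n, flen) ** 2).mean(axis=1)
        return 10.0 * np.log10(np.maximum(pw, 1e-300))

    sel_db = frame_db(i0, i1)
    if c0 < i0:
        noise_pool = frame_db(c0, i1)
    else:
        warnings.warn(
            "no leading context before the selection; noise level "
            "estimated from in-selection frames only",
            stacklevel=2,
        )
        noise_pool = sel_db
    signal = float(np.percentile(sel_db, signal_percentile))
    noise = float(np.percentile(noise_pool, noise_percentile))
    return signal - noise


def count_harmonics(
    spec: Spectrogram,
    sel: Selection,
    f0_hint: float | None = None,
    *,
    rel_threshold_db: float = -20.0,
    tol_bins: int = 1,
    max_harmonics: int = 20,
) -> tuple[bool, int]:
    """Estimate harmonic structure inside a selection.

    The time-aggregated in-box spectrum is scanned for a fundamental
    (strongest local peak, or ``f0_hint``), then partials are counted at
    integer multiples of f0 (within ``tol_bins`` bins) whose energy
    exceeds ``rel_threshold_db`` relative to the strongest partial.
    ``present`` requires at least two partials — a lone tone is not
    harmonic structure.  Never raises for aperiodic sounds; returns
    (False, 0) when no fundamental can be found.
    """
    box, f_idx, _ = _box(spec, sel)
    agg = box.sum(axis=1)
    if agg.max() <= 0:
        return False, 0
    freqs = spec.frequencies[f_idx]
    dfreq = spec.freq_resolution

    if f0_hint is None:
        # local maxima of the aggregate spectrum; fundamental = strongest
        interior = np.flatnonzero(
            (agg[1:-1] >= agg[:-2]) & (agg[1:-1] >= agg[2:])
        ) + 1
        if interior.size == 0:
            return False, 0
        f0 = float(freqs[interior[np.argmax(agg[interior])]])
    else:
        f0 = float(f0_hint)
    if f0 <= 0:
        return False, 0

    peak_energy = []
    for k in range(1, max_harmonics + 1):
        target = k * f0
        if target > freqs[-1] + tol_bins * dfreq:
            break
        near = np.flatnonzero(np.abs(freqs - target) <= tol_bins * dfreq + 1e-9)
        peak_energy.append(agg[near].max() if near.size else 0.0)
    if not peak_energy:
        return False, 0
    peak_energy = np.asarray(peak_energy)
    strongest = peak_energy.max()
    thr = strongest * 10.0 ** (rel_threshold_db / 10.0)
    # count consecutive partials from the fundamental that clear threshold
    # and are genuine local peaks (guards against broadband noise floors)
    n = 0
    for k, e in enumerate(peak_energy, start=1):
        if e >= thr and _is_local_peak(agg, freqs, k * f0, dfreq, tol_bins):
            n += 1
        else:
            break
    return n >= 2, n


def _is_local_peak(agg, freqs, target, dfreq, tol_bins) -> bool:
    near = np.flatnonzero(np.abs(freqs - target) <= tol_bins * dfreq + 1e-9)
    if near.size == 0:
        return False
    j = near[np.argmax(agg[near])]
    lo, hi = max(0, j - 2), min(agg.size, j + 3)
    return agg[j] >= agg[lo:hi].max() * (1.0 - 1e-12)


def measure_selection(
    spec: Spectrogram,
    sel: Selection,
    waveform: np.ndarray | None = None,
    sample_rate: int | None = None,
    *,
    f0_hint: float | None = None,
) -> FeatureVector:
    """Measure all selection parameters, returning a FeatureVector.

    ``waveform``/``sample_rate`` are needed only for the SNR estimate;
    when omitted, SNRNIST is left as None.
    """
    f5 = percentile_frequency(spec, sel, 0.05)
    f25 = percentile_frequency(spec, sel, 0.25)
    f50 = percentile_frequency(spec, sel, 0.50)
    f75 = percentile_frequency(spec, sel, 0.75)
    f95 = percentile_frequency(spec, sel, 0.95)
    present, n_harm = count_harmonics(spec, sel, f0_hint)
    snr = None
    if waveform is not None and sample_rate is not None:
        snr = snr_nist_quick(waveform, sample_rate, sel)
    return FeatureVector(
        DUR=total_duration(sel),
        DUR90=energy_duration(spec, sel, 0.9),
        F5=f5,
        F25=f25,
        Fcenter=f50,
        F75=f75,
        F95=f95,
        BDW50=f75 - f25,
        BDW90=f95 - f5,
        Fpeak=peak_frequency(spec, sel),
        AE=aggregate_entropy(spec, sel),
        SNRNIST=snr,
        harmonics_present=present,
        n_harmonics=n_harm,
    )


# ---------------------------------------------------------------------------
# Selection-table (Raven dialect) and feature-table I/O

_RAVEN_COLUMNS = {
    "begin": "Begin Time (s)",
    "end": "End Time (s)",
    "low": "Low Freq (Hz)",
    "high": "High Freq (Hz)",
}


def read_selection_table(path) -> list[Selection]:
    """Read a tab-separated selection table (Raven dialect).

    Requires the columns "Begin Time (s)", "End Time (s)", "Low Freq (Hz)"
    and "High Freq (Hz)"; extra columns are tolerated and ignored.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RAVEN_COLUMNS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing selection-table columns {missing}")
    return [
        Selection(
            start_time=float(row[_RAVEN_COLUMNS["begin"]]),
            end_time=float(row[_RAVEN_COLUMNS["end"]]),
            low_freq=float(row[_RAVEN_COLUMNS["low"]]),
            high_freq=float(row[_RAVEN_COLUMNS["high"]]),
        )
        for _, row in df.iterrows()
    ]


def write_selection_table(path, selections: list[Selection]) -> None:
    """Write selections in the same tab-separated dialect."""
    df = pd.DataFrame(
        {
            "Selection": np.arange(1, len(selections) + 1),
            "View": "Spectrogram 1",
            "Channel": 1,
            _RAVEN_COLUMNS["begin"]: [s.start_time for s in selections],
            _RAVEN_COLUMNS["end"]: [s.end_time for s in selections],
            _RAVEN_COLUMNS["low"]: [s.low_freq for s in selections],
            _RAVEN_COLUMNS["high"]: [s.high_freq for s in selections],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame headered with the standard symbols."""
    if not features:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    rows = []
    for fv in features:
        row = {c: getattr(fv, c) for c in FEATURE_COLUMNS}
        if fv.label is not None:
            row["label"] = fv.label
        rows.append(row)
    return pd.DataFrame(rows)
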