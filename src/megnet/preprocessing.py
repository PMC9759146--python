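"""Signal cleaning: notch, band decomposition, artifact/spike flagging, segment selection.

The cleaning chain mirrors standard resting-state MEG practice: a zero-phase
notch near the 50 Hz mains frequency, decomposition into seven predefined
frequency bands, exclusion of high-amplitude segments (|x| > 6 pT), automatic
flagging of epileptiform spike transients on the 1-70 Hz band, and selection
of a continuous 60 s analysis window free of flagged events.

All filters are applied forward-backward (zero phase). Band-pass filters are
4th-order Butterworth; the notch is a 2nd-order IIR notch with Q=30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .synthetic_meg import VirtualSensorRecording

__all__ = [
    "CleanSegment",
    "NoCleanSegmentError",
    "notch_filter",
    "bandpass",
    "bandpass_array",
    "detect_artifacts",
    "flag_spikes",
    "select_clean_segment",
    "merge_intervals",
]

FLAG_PAD_S = 0.5  # guard band around flagged samples (filter-edge contamination)


class NoCleanSegmentError(RuntimeError):
    """No contiguous window of the requested length avoids all flagged intervals."""


@dataclass
class CleanSegment:
    """A contiguous artifact- and spike-free analysis window.

    ``band`` is "broadband" until :func:`bandpass` is applied; ``K`` is the
    number of samples, the quantity entering the connectivity t-threshold.
    """

    data: np.ndarray  # samples x nodes
    fs: float
    band: BandDefinition | str
    start_s: float
    node_labels: list[str]

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.K / self.fs


def _design_bandpass(band: BandDefinition, fs: float, order: int = 4):
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.name!r} upper edge {band.hi} Hz >= Nyquist ({fs / 2} Hz)")
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    sos = _design_bandpass(band, fs, order)
    return signal.sosfiltfilt(sos, x, axis=0)


def notch_filter(rec: VirtualSensorRecording, freq: float = 50.0, q: float = 30.0) -> VirtualSensorRecording:
    """Zero-phase IIR notch removing a narrow band around *freq* (mains hum)."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist ({rec.fs / 2} Hz)")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    return replace(rec, data=signal.filtfilt(b, a, rec.data, axis=0))


def bandpass(
    rec: VirtualSensorRecording | CleanSegment, band: BandDefinition, order: int = 4
) -> VirtualSensorRecording | CleanSegment:
    """Zero-phase band-pass of a recording or clean segment into *band*."""
    filtered = bandpass_array(np.asarray(rec.data, dtype=float), band, rec.fs, order)
    if isinstance(rec, CleanSegment):
        return replace(rec, data=filtered, band=band)
    return replace(rec, data=filtered)


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching [start, end] intervals; idempotent."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _samples_to_intervals(mask: np.ndarray, fs: float, total_s: float, pad_s: float) -> list[tuple[float, float]]:
    """Convert a boolean per-sample flag mask to padded, merged time intervals."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    # split into runs of consecutive samples
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    intervals = [
        (max(0.0, s / fs - pad_s), min(total_s, (e + 1) / fs + pad_s)) for s, e in zip(starts, ends)
    ]
    return merge_intervals(intervals)


def detect_artifacts(
    rec: VirtualSensorRecording, threshold: float = 6.0, pad_s: float = FLAG_PAD_S
) -> list[tuple[float, float, str]]:
    """Flag intervals where any channel exceeds *threshold* (pT) in magnitude.

    Applied per channel, any-channel triggers; flagged samples are padded by
    ``pad_s`` on each side and overlapping intervals merged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = (np.abs(rec.data) > threshold).any(axis=1)
    return [(lo, hi, "artifact") for lo, hi in _samples_to_intervals(mask, rec.fs, rec.duration, pad_s)]


def flag_spikes(
    rec: VirtualSensorRecording,
    z_thresh: float = 6.0,
    pad_s: float = FLAG_PAD_S,
    spike_band: tuple[float, float] = (1.0, 70.0),
) -> list[tuple[float, float, str]]:
    """Flag epileptiform spike transients on the 1-70 Hz band.

    The signal is band-passed to *spike_band* and robust z-scores
    (median/MAD per channel) computed; samples exceeding ``z_thresh`` on any
    channel are flagged, padded and merged. Zero-variance channels are
    skipped with a warning. An automated surrogate for visual spike marking.
    """
    if rec.duration < 2.0:
        raise ValueError("recording must be at least 2 s long for spike flagging")
    band = BandDefinition("spike_band", *spike_band)
    x = bandpass_array(rec.data, band, rec.fs)
    # the first/last ~0.5 s of a zero-phase IIR output carry edge transients;
    # exclude them from the robust-z scan (they are re-covered by padding)
    guard = int(round(0.5 * rec.fs))
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    scale = 1.4826 * mad
    ok = scale > 0
    if not ok.all():
        bad = [rec.node_labels[i] for i in np.flatnonzero(~ok)]
        warnings.warn(f"zero-variance channels skipped in spike flagging: {bad}", stacklevel=2)
    if not ok.any():
        return []
    z = np.abs(x[:, ok] - med[ok]) / scale[ok]
    mask = (z > z_thresh).any(axis=1)
    if guard and len(mask) > 2 * guard:
        mask[:guard] = False
        mask[-guard:] = False
    return [(lo, hi, "spike") for lo, hi in _samples_to_intervals(mask, rec.fs, rec.duration, pad_s)]


def select_clean_segment(
    rec: VirtualSensorRecording,
    flags: list[tuple[float, float, str]] | list[tuple[float, float]] | None = None,
    length_s: float = 60.0,
) -> CleanSegment:
    """Earliest contiguous window of exactly *length_s* avoiding all flags.

    Candidate start times are 0 and the end of each flagged interval; the
    earliest start whose window fits inside the recording and overlaps no
    flagged interval wins. Raises :class:`NoCleanSegmentError` if none exists.
    """
    if rec.duration < length_s:
        raise NoCleanSegmentError(f"recording ({rec.duration:.1f} s) shorter than requested {length_s} s window")
    plain = merge_intervals([(f[0], f[1]) for f in (flags or [])])
    candidates = sorted({0.0} | {hi for _, hi in plain})
    for start in candidates:
        end = start + length_s
        if end > rec.duration + 1e-9:
            break
        if all(hi <= start or lo >= end for lo, hi in plain):
            i0 = int(round(start * rec.fs))
            k = int(round(length_s * rec.fs))
            return CleanSegment(
                data=rec.data[i0 : i0 + k].copy(),
                fs=rec.fs,
                band="broadband",
                start_s=start,
                node_labels=list(rec.node_labels),
            )
    raise NoCleanSegmentError(f"no {length_s} s window free of flagged intervals")
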