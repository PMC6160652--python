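"""Preprocessing of resting-state hemodynamic recordings.

Pipeline order is fixed: segment selection -> despiking -> detrending ->
zero-phase band-pass.  The analysis segment discards the initial portion of
the recording (default 3 min, where optode coupling and the subject are
still settling) and keeps a window (default 3 min) centered on the midpoint
of what remains.  The band-pass (default 0.01-0.1 Hz) isolates slow
hemodynamic fluctuations and suppresses cardiac (~1 Hz), respiratory
(~0.3 Hz) and most Mayer-wave (~0.1 Hz) physiology along with drift.

The filter is an order-3 Butterworth band-pass realized in second-order
sections and applied forward-backward (zero phase).  At 50 Hz sampling a
0.01 Hz corner is numerically delicate in transfer-function form; cascaded
sections keep it stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import InvalidSpecError, Recording, SegmentError


@dataclass(frozen=True)
class PreprocessConfig:
    """Segment, despike and filter settings.

    despiking is off by default: the synthetic generator injects no motion
    artifacts unless asked to, and interpolation on clean data is a no-op
    risk rather than a benefit.
    """

    discard_initial_s: float = 180.0
    keep_window_s: float = 180.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    filter_order: int = 3
    despike_enabled: bool = False
    despike_z_threshold: float = 5.0

    def validate(self, sampling_rate_hz: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise InvalidSpecError("need 0 < band_low < band_high")
        if self.band_high_hz >= sampling_rate_hz / 2:
            raise InvalidSpecError(
                f"band_high {self.band_high_hz} Hz infeasible at "
                f"{sampling_rate_hz} Hz sampling (Nyquist limit)"
            )


def select_segment(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Keep the analysis window centered on the post-discard remainder.

    For a 600 s recording with 180 s discard and a 180 s window, the kept
    segment spans 300-480 s.  Raises :class:`SegmentError` when the
    recording cannot accommodate discard + window.
    """
    cfg = cfg or PreprocessConfig()
    required = cfg.discard_initial_s + cfg.keep_window_s
    if rec.duration_s < required - 1e-9:
        raise SegmentError(
            f"recording of {rec.duration_s:.1f} s cannot supply "
            f"{cfg.discard_initial_s:.0f} s discard + {cfg.keep_window_s:.0f} s window "
            f"({required:.0f} s required)"
        )
    fs = rec.sampling_rate_hz
    n_keep = int(round(cfg.keep_window_s * fs))
    remainder_s = rec.duration_s - cfg.discard_initial_s
    start_s = cfg.discard_initial_s + (remainder_s - cfg.keep_window_s) / 2.0
    start = int(round(start_s * fs))
    return Recording(
        data=rec.data[:, start : start + n_keep].copy(),
        sampling_rate_hz=fs,
        signal_type=rec.signal_type,
        channel_ids=rec.channel_ids,
    )


def despike(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Replace motion spikes by cubic-spline interpolation.

    A sample is a spike when its robust z — |x - median| over the scaled
    median absolute deviation — exceeds the configured threshold.  Disabled
    (the default) this is the identity.
    """
    cfg = cfg or PreprocessConfig()
    if not cfg.despike_enabled:
        return rec
    if rec.n_samples < 3:
        raise ValueError("need at least 3 samples to despike")
    data = rec.data.copy()
    t = np.arange(rec.n_samples)
    for ch in range(rec.n_channels):
        x = data[ch]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826  # consistent with SD for Gaussians
        if mad == 0:
            continue
        spikes = np.abs(x - med) / mad > cfg.despike_z_threshold
        if not spikes.any() or spikes.all():
            continue
        good = ~spikes
        data[ch, spikes] = CubicSpline(t[good], x[good])(t[spikes])
    return replace_data(rec, data)


def detrend_and_filter(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Remove each channel's best-fit line, then band-pass with zero phase.

    The forward-backward pass doubles the effective order and cancels phase
    lag; reflective padding (scipy's default odd extension, one padlen)
    limits edge transients on short segments.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.sampling_rate_hz)
    if rec.n_samples <= 3 * cfg.filter_order:
        raise ValueError("segment too short for the configured filter order")
    detrended = signal.detrend(rec.data, axis=1, type="linear")
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rec.sampling_rate_hz,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, detrended, axis=1)
    return replace_data(rec, filtered)


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Full pipeline: select -> despike -> detrend + band-pass."""
    cfg = cfg or PreprocessConfig()
    return detrend_and_filter(despike(select_segment(rec, cfg), cfg), cfg)


def replace_data(rec: Recording, data: np.ndarray) -> Recording:
    """A copy of ``rec`` carrying new sample data (same channels, rate, type)."""
    return Recording(
        data=data,
        sampling_rate_hz=rec.sampling_rate_hz,
        signal_type=rec.signal_type,
        channel_ids=rec.channel_ids,
    )
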