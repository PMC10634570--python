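"""EEG epoching, baseline correction, artifact flagging, and resampling.

The deterministic, scriptable part of an EEG preprocessing chain for a
stimulus-locked design:

* ``epoch_and_baseline`` — cut fixed-length epochs around (photodiode-
  corrected) stimulus onsets and subtract the prestimulus baseline;
* ``detect_muscle_artifacts`` — flag trials whose 110–140 Hz Hilbert
  envelope z-score exceeds a threshold (default 15);
* ``rereference_and_resample`` — re-reference every sample to the median
  across channels, low-pass filter, and decimate (e.g. 1000 -> 500 Hz).

Interactive steps (manual channel/trial rejection, ICA-based eye-artifact
removal) are consumed as externally supplied masks on :class:`EpochSet`,
never computed here.  Filters are zero-phase forward-backward 4th-order
Butterworth; the cutoffs are contracts, the coefficients are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "butter_filter",
    "epoch_and_baseline",
    "detect_muscle_artifacts",
    "rereference_and_resample",
]


@dataclass
class EpochSet:
    """Trials x channels x samples voltage epochs with metadata.

    Parameters
    ----------
    data : (n_trials, n_channels, n_samples) array
        Voltages in microvolts.
    times : (n_samples,) array
        Milliseconds relative to stimulus onset; strictly increasing with
        uniform spacing ``1000 / sample_rate``.
    sample_rate : float
        Hz.
    labels : (n_trials,) array
        Condition label per trial.
    channel_names : sequence of str, optional
    bad_trials, bad_channels : boolean masks, optional
        Externally supplied rejection masks (manual rejection, ICA);
        default all-False.
    is_catch : (n_trials,) boolean array, optional
        Marks catch (immediate-repeat) trials, excluded from analysis.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: np.ndarray
    channel_names: Sequence[str] | None = None
    bad_trials: np.ndarray | None = None
    bad_channels: np.ndarray | None = None
    is_catch: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n_trials, n_channels, n_samples = self.data.shape
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n_samples,):
            raise ValueError("times length must match data samples")
        dt = np.diff(self.times)
        expected = 1000.0 / self.sample_rate
        if n_samples > 1 and not np.allclose(dt, expected, atol=1e-6 * expected):
            raise ValueError(
                "times must be uniformly spaced at 1000/sample_rate ms"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must match trial count")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(n_channels)]
        else:
            self.channel_names = list(self.channel_names)
            if len(self.channel_names) != n_channels:
                raise ValueError("channel_names length must match channels")
        if self.bad_trials is None:
            self.bad_trials = np.zeros(n_trials, dtype=bool)
        else:
            self.bad_trials = np.asarray(self.bad_trials, dtype=bool)
        if self.bad_channels is None:
            self.bad_channels = np.zeros(n_channels, dtype=bool)
        else:
            self.bad_channels = np.asarray(self.bad_channels, dtype=bool)
        if self.is_catch is not None:
            self.is_catch = np.asarray(self.is_catch, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def good_trials(self) -> np.ndarray:
        """Boolean mask of analysable trials (not bad, not catch)."""
        good = ~self.bad_trials
        if self.is_catch is not None:
            good &= ~self.is_catch
        return good

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to trials where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.asarray(mask, dtype=int)
        else:
            idx = np.flatnonzero(mask)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            bad_trials=self.bad_trials[idx],
            is_catch=None if self.is_catch is None else self.is_catch[idx],
        )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def butter_filter(
    data: np.ndarray,
    sample_rate: float,
    kind: str,
    freqs: float | tuple[float, float],
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filter along the last axis.

    ``kind`` is ``"lowpass"``, ``"highpass"`` or ``"bandpass"``; ``freqs``
    the cutoff (Hz) or (low, high) band edges.  All band edges must be
    below Nyquist.
    """
    nyq = sample_rate / 2.0
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(f <= 0) or np.any(f >= nyq):
        raise ValueError(f"cutoffs {freqs} must lie in (0, Nyquist={nyq}) Hz")
    wn = float(f[0]) if f.size == 1 else f
    sos = signal.butter(order, wn, btype=kind, fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(
    continuous: np.ndarray,
    events: Sequence[int],
    sample_rate: float,
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    photodiode_offsets_ms: Sequence[float] | float | None = None,
    labels: Sequence[Any] | None = None,
    baseline_ms: tuple[float, float] | None = None,
    highpass_hz: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> EpochSet:
    """Cut epochs around corrected stimulus onsets and baseline-correct.

    Parameters
    ----------
    continuous : (n_channels, n_samples) array
    events : trigger onset sample indices.
    photodiode_offsets_ms : per-event (or scalar) display-lag correction in
        ms; the effective onset is ``trigger + round(offset * rate / 1000)``
        samples, aligning epochs to the photodiode-defined stimulus onset.
    window_ms : epoch extent (start, end) in ms relative to onset; the
        epoch covers ``[start, end)`` so the default (-200, 1000) at
        1000 Hz yields 1200 samples.
    labels : condition label per event (defaults to the event index).
    baseline_ms : baseline interval; default is the prestimulus part of
        the window, ``[window start, 0)``.  The per-channel mean over this
        interval is subtracted from each epoch.
    highpass_hz : optional slow-drift high-pass (e.g. 0.1 Hz) applied to
        each epoch after baseline correction.

    Events whose (corrected) epoch would extend past either recording
    edge are dropped with a log entry.
    """
    x = np.asarray(continuous, dtype=float)
    if x.ndim != 2:
        raise ValueError("continuous must be (channels, samples)")
    events = np.asarray(events, dtype=int)
    n_events = events.size
    if photodiode_offsets_ms is None:
        offsets = np.zeros(n_events, dtype=int)
    else:
        off = np.broadcast_to(
            np.asarray(photodiode_offsets_ms, dtype=float), (n_events,)
        )
        offsets = np.round(off * sample_rate / 1000.0).astype(int)
    if labels is None:
        labels = np.arange(n_events)
    labels = np.asarray(labels)
    if labels.shape != (n_events,):
        raise ValueError("labels length must match events")

    start = int(round(window_ms[0] * sample_rate / 1000.0))
    stop = int(round(window_ms[1] * sample_rate / 1000.0))
    n_samp = stop - start
    if n_samp < 1:
        raise ValueError("empty epoch window")
    times = (np.arange(start, stop) / sample_rate) * 1000.0

    onsets = events + offsets
    keep = (onsets + start >= 0) & (onsets + stop <= x.shape[1])
    if not np.all(keep):
        dropped = np.flatnonzero(~keep)
        logger.warning(
            "dropping %d event(s) too close to recording edge: %s",
            dropped.size, dropped.tolist(),
        )
    onsets, labels = onsets[keep], labels[keep]

    epochs = np.stack([x[:, o + start : o + stop] for o in onsets])

    if baseline_ms is None:
        baseline_ms = (window_ms[0], 0.0)
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if bmask.any():
        epochs = epochs - epochs[:, :, bmask].mean(axis=2, keepdims=True)
    if highpass_hz is not None:
        epochs = butter_filter(epochs, sample_rate, "highpass", highpass_hz)
    return EpochSet(epochs, times, sample_rate, labels, channel_names=channel_names)


# ---------------------------------------------------------------------------
# Muscle-artifact flagging
# ---------------------------------------------------------------------------

def detect_muscle_artifacts(
    epochs: EpochSet,
    band: tuple[float, float] = (110.0, 140.0),
    z_threshold: float = 15.0,
) -> np.ndarray:
    """Flag trials containing high-frequency muscle activity.

    Each trial/channel is band-pass filtered to ``band``, the magnitude of
    the analytic (Hilbert) envelope is taken, and envelopes are z-scored
    per channel across all trials and timepoints.  A trial is flagged if
    any timepoint on any channel exceeds ``z_threshold``.

    Returns a boolean (n_trials,) mask (True = artifact).
    """
    if band[1] >= epochs.sample_rate / 2.0:
        raise ValueError(
            f"band {band} exceeds Nyquist ({epochs.sample_rate / 2} Hz)"
        )
    filtered = butter_filter(epochs.data, epochs.sample_rate, "bandpass", band)
    envelope = np.abs(signal.hilbert(filtered, axis=-1))
    # z-score per channel over the pooled (trial, time) population
    mu = envelope.mean(axis=(0, 2), keepdims=True)
    sd = envelope.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = (envelope - mu) / sd
    return (z > z_threshold).any(axis=(1, 2))


# ---------------------------------------------------------------------------
# Re-reference + resample
# ---------------------------------------------------------------------------

def rereference_and_resample(
    epochs: EpochSet,
    new_rate: float = 500.0,
    lowpass_hz: float | None = 100.0,
) -> EpochSet:
    """Median re-reference, anti-alias low-pass, and decimate.

    At every timepoint the across-channel median is subtracted, making
    the channel median exactly zero (and the result invariant to adding
    any common offset).  A zero-phase low-pass at ``lowpass_hz`` is then
    applied before decimating by the integer factor
    ``sample_rate / new_rate`` (non-integer factors are an error).
    """
    factor = epochs.sample_rate / new_rate
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ValueError(
            f"new_rate {new_rate} must integer-divide sample_rate "
            f"{epochs.sample_rate}"
        )
    data = epochs.data - np.median(epochs.data, axis=1, keepdims=True)
    if lowpass_hz is not None:
        if lowpass_hz >= new_rate / 2.0:
            raise ValueError(
                f"lowpass {lowpass_hz} Hz must be below the new Nyquist "
                f"({new_rate / 2} Hz) to prevent aliasing"
            )
        data = butter_filter(data, epochs.sample_rate, "lowpass", lowpass_hz)
    if q > 1:
        data = data[:, :, ::q]
    return replace(
        epochs,
        data=data,
        times=epochs.times[::q],
        sample_rate=new_rate,
    )
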