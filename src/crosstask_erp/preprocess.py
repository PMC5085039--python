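"""From continuous recordings to epochs and spatio-temporal features.

The chain mirrors standard ERP practice for this paradigm: linked-mastoid
re-referencing, 0.5-40 Hz zero-phase IIR band-pass (Butterworth applied
forward-backward), segmentation into 1 s epochs from -100 to +900 ms around
stimulus onset with the first eight markers of every repetition discarded,
baseline correction on the 100 ms pre-stimulus interval, optional
max-min artifact rejection (100 uV EEG / 200 uV EOG), and downsampling of
the 100-800 ms window to 15 time points per scalp channel (62 channels x
15 points = 930 features on the default montage).

Classification deliberately consumes *all* epochs including artifactual
ones (the multivariate classifier can project artifacts out); the rejection
mask is applied only by the discriminability analyses.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochSet, FeatureMatrix
from .events import ConfigurationError
from .montage import EOG_CHANNEL, MASTOIDS

logger = logging.getLogger(__name__)

#: order of the Butterworth band-pass per band edge; applied forward-backward
#: the effective attenuation at 50 Hz exceeds 20 dB.
FILTER_ORDER = 5


class MontageError(KeyError):
    """A channel required by the montage convention is missing."""


def rereference_linked_mastoids(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the mean of the two mastoid signals from every channel.

    The EOG channel is left untouched (it is thresholded on its raw
    referenced signal).  Mastoid channels remain in the container but are
    excluded from the scalp-channel set used downstream.
    """
    for m in MASTOIDS:
        if m not in rec.channel_names:
            raise MontageError(f"mastoid channel {m!r} missing; cannot re-reference")
    out = rec.copy()
    ref = (rec.get_channel(MASTOIDS[0]) + rec.get_channel(MASTOIDS[1])) / 2.0
    eog = [i for i, c in enumerate(out.channel_names) if c == EOG_CHANNEL]
    eeg = [i for i in range(len(out.channel_names)) if i not in eog]
    out.data[eeg] -= ref[None, :]
    out.reference = "linked-mastoids"
    return out


def design_bandpass(low_hz: float, high_hz: float, sfreq: float,
                    order: int = FILTER_ORDER) -> np.ndarray:
    """Second-order sections of the band-pass used throughout."""
    nyq = sfreq / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigurationError(
            f"invalid band edges ({low_hz}, {high_hz}) Hz at {sfreq} Hz sampling"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=sfreq, output="sos")


def bandpass(rec: ContinuousRecording, low_hz: float = 0.5,
             high_hz: float = 40.0) -> ContinuousRecording:
    """Zero-phase band-pass: Butterworth applied forward and backward."""
    import dataclasses

    sos = design_bandpass(low_hz, high_hz, rec.sampling_rate)
    return dataclasses.replace(
        rec, data=signal.sosfiltfilt(sos, rec.data, axis=1),
        events=list(rec.events), channel_names=list(rec.channel_names))


def segment(rec: ContinuousRecording, tmin_ms: float = -100.0,
            tmax_ms: float = 900.0, discard_first_n: int = 8) -> EpochSet:
    """Cut stimulus-locked epochs over the half-open window [tmin, tmax) ms.

    The first ``discard_first_n`` events of every repetition are dropped
    (imprecise stimulus timing at sequence start in the emulated setup).
    Epochs that would extend beyond the recording are dropped with a
    warning; event order within repetitions is preserved.
    """
    sfreq = rec.sampling_rate
    s_lo = int(round(tmin_ms * sfreq / 1000.0))
    s_hi = int(round(tmax_ms * sfreq / 1000.0))
    n_t = s_hi - s_lo
    if n_t <= 0:
        raise ConfigurationError("empty epoch window")

    counts: dict[int, int] = {}
    epochs, labels, kept_events = [], [], []
    for ev in rec.events:
        counts[ev.repetition_index] = counts.get(ev.repetition_index, 0) + 1
        if counts[ev.repetition_index] <= discard_first_n:
            continue
        s0 = rec.onset_sample(ev)
        lo, hi = s0 + s_lo, s0 + s_hi
        if lo < 0 or hi > rec.n_samples:
            logger.warning(
                "dropping epoch at %d ms (window outside recording bounds)", ev.onset_ms
            )
            continue
        epochs.append(rec.data[:, lo:hi])
        labels.append(1 if ev.is_target else 0)
        kept_events.append(ev)

    data = (np.stack(epochs) if epochs
            else np.empty((0, len(rec.channel_names), n_t)))
    times_ms = (np.arange(s_lo, s_hi)) * (1000.0 / sfreq)
    return EpochSet(
        data=data,
        times_ms=times_ms,
        labels=np.array(labels, dtype=int),
        channel_names=list(rec.channel_names),
        events=kept_events,
        participant=rec.participant,
        condition=rec.condition,
        sampling_rate=sfreq,
    )


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float] = (-100.0, 0.0),
                     inplace: bool = False) -> EpochSet:
    """Subtract, per epoch and channel, the mean over the pre-stimulus
    window [window_ms[0], window_ms[1]) ms.  Idempotent."""
    mask = epochs.time_mask(*window_ms)
    if not mask.any():
        raise ConfigurationError(f"baseline window {window_ms} outside epoch")
    out = epochs if inplace else epochs.select(np.arange(epochs.n_epochs))
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, eeg_thresh_uV: float = 100.0,
                     eog_thresh_uV: float = 200.0,
                     window_ms: tuple[float, float] = (0.0, 900.0)) -> EpochSet:
    """Max-min (peak-to-peak) artifact criterion on the post-stimulus window.

    An epoch is kept iff peak-to-peak amplitude is <= ``eeg_thresh_uV`` on
    every scalp channel and <= ``eog_thresh_uV`` on the EOG channel.  Only
    the ``kept`` mask is updated; the data are untouched.
    """
    import dataclasses

    tmask = epochs.time_mask(*window_ms)
    scalp_idx = [epochs.channel_index(c) for c in epochs.scalp_channels]
    seg = epochs.data[:, :, tmask]
    ptp = seg.max(axis=2) - seg.min(axis=2)  # epochs x channels
    ok = (ptp[:, scalp_idx] <= eeg_thresh_uV).all(axis=1)
    if EOG_CHANNEL in epochs.channel_names:
        ok &= ptp[:, epochs.channel_index(EOG_CHANNEL)] <= eog_thresh_uV
    # data are shared, only the mask is new
    return dataclasses.replace(epochs, kept=ok, events=list(epochs.events),
                               channel_names=list(epochs.channel_names))


def _downsample_times(window_ms: tuple[float, float], target_rate_hz: float
                      ) -> np.ndarray:
    """Nominal feature time points: window endpoints inclusive at the target
    sampling interval (100, 150, ..., 800 ms for the defaults)."""
    step = 1000.0 / target_rate_hz
    n = int(round((window_ms[1] - window_ms[0]) / step)) + 1
    return window_ms[0] + step * np.arange(n)


def extract_features(epochs: EpochSet, window_ms: tuple[float, float] = (100.0, 800.0),
                     target_rate_hz: float = 20.0, method: str = "mean",
                     use_mask: bool = False) -> FeatureMatrix:
    """Spatio-temporal features: per scalp channel, the analysis window
    downsampled to ``target_rate_hz``, concatenated channel-major.

    ``method='mean'`` (default) averages over 15 consecutive equal-width
    bins spanning the closed window [100, 800] ms and reports bin centers
    as the time points; ``method='pick'`` picks the samples at exactly
    100, 150, ..., 800 ms.  On the default montage both yield
    62 x 15 = 930 features.

    ``use_mask=True`` restricts rows to artifact-free epochs; the default
    keeps all epochs (classification operates on unrejected data).
    """
    lo, hi = window_ms
    if lo < epochs.times_ms[0] or hi > epochs.times_ms[-1]:
        raise ConfigurationError(f"analysis window {window_ms} not covered by epoch")
    nominal = _downsample_times(window_ms, target_rate_hz)
    n_points = nominal.size

    src = epochs.kept_only() if use_mask else epochs
    scalp = src.scalp_channels
    ch_idx = [src.channel_index(c) for c in scalp]
    t = src.times_ms

    arr = src.data[:, ch_idx, :]  # epochs x scalp channels x time
    if method == "pick":
        cols_t = []
        for tm in nominal:
            j = int(np.argmin(np.abs(t - tm)))
            if abs(t[j] - tm) > 1e-6:
                logger.warning("picked sample %.3f ms for nominal %.1f ms", t[j], tm)
            cols_t.append(j)
        vals = arr[:, :, cols_t]  # epochs x ch x points
        times_out = nominal
    elif method == "mean":
        edges = np.linspace(lo, hi, n_points + 1)
        vals = np.empty((src.n_epochs, len(ch_idx), n_points))
        for k in range(n_points):
            m = (t >= edges[k]) & ((t < edges[k + 1]) if k < n_points - 1
                                   else (t <= edges[k + 1]))
            vals[:, :, k] = arr[:, :, m].mean(axis=2)
        times_out = (edges[:-1] + edges[1:]) / 2.0
    else:
        raise ConfigurationError(f"unknown downsampling method {method!r}")

    X = vals.reshape(src.n_epochs, -1)
    feature_index = [(c, float(tm)) for c in scalp for tm in times_out]
    epoch_index = (np.flatnonzero(epochs.kept) if use_mask
                   else np.arange(epochs.n_epochs))
    return FeatureMatrix(X=X, y=src.labels, feature_index=feature_index,
                         epoch_index=epoch_index,
                         participant=src.participant, condition=src.condition)


def preprocess_recording(rec: ContinuousRecording, *, low_hz: float = 0.5,
                         high_hz: float = 40.0, tmin_ms: float = -100.0,
                         tmax_ms: float = 900.0, discard_first_n: int = 8,
                         reject: bool = True, eeg_thresh_uV: float = 100.0,
                         eog_thresh_uV: float = 200.0) -> EpochSet:
    """Full continuous-to-epochs chain: re-reference, band-pass, segment,
    baseline-correct and (by default) record the artifact mask."""
    rec = rereference_linked_mastoids(rec)
    rec = bandpass(rec, low_hz, high_hz)
    epochs = segment(rec, tmin_ms, tmax_ms, discard_first_n)
    epochs = baseline_correct(epochs, inplace=True)  # segment output is fresh
    if reject:
        epochs = reject_artifacts(epochs, eeg_thresh_uV, eog_thresh_uV)
    return epochs
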