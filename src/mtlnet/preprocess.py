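"""Conditioning of continuous recordings into clean fixed-length epochs.

The chain mirrors standard intracranial-EEG practice for parametric spectral
connectivity: a zero-phase 0.5 Hz high-pass removes DC, the signal is
decimated to 250 Hz (anti-alias filtered first), cut into contiguous 10 s
blocks, and blocks contaminated by large-amplitude artefacts or flat
channels are rejected by a quantitative surrogate for visual selection.
Channels flagged as seizure onset zone (SOZ) can be excluded, and an epoch
set can be split into early/late halves for stability checks.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal

from .recording import EpochSet, MultichannelRecording

__all__ = [
    "highpass",
    "decimate",
    "make_epochs",
    "select_epochs",
    "split_half",
    "exclude_channels",
]

logger = logging.getLogger(__name__)


def highpass(recording: MultichannelRecording, cutoff=0.5) -> MultichannelRecording:
    """Zero-phase Butterworth high-pass (order 4, forward-backward).

    Removes DC while preserving pass-band amplitude; forward-backward
    filtering avoids the phase distortion that would bias directed metrics.
    `cutoff` must lie strictly between 0 and the Nyquist frequency.
    """
    nyq = recording.sampling_rate / 2
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz")
    sos = signal.butter(4, cutoff, btype="highpass", fs=recording.sampling_rate,
                        output="sos")
    # long reflect-padding: the 0.5 Hz filter's impulse response spans
    # seconds, and the default padding leaves visible edge transients
    padlen = int(min(recording.n_samples - 1,
                     3 * recording.sampling_rate / cutoff))
    out = signal.sosfiltfilt(sos, recording.data, axis=0, padlen=padlen)
    return recording.with_data(out)


def decimate(recording: MultichannelRecording, target_rate=250.0) -> MultichannelRecording:
    """Downsample by an integer factor after zero-phase anti-alias filtering.

    An 8th-order Butterworth low-pass at 0.8x the new Nyquist is applied
    forward-backward, then every `factor`-th sample is kept. The original
    rate must be an integer multiple of `target_rate`.
    """
    fs = recording.sampling_rate
    factor = fs / target_rate
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError(
            f"sampling rate {fs} Hz is not an integer multiple of {target_rate} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording.with_data(recording.data.copy())
    sos = signal.butter(8, 0.8 * (target_rate / 2), btype="lowpass", fs=fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=0)
    out = filtered[::factor]
    rec = recording.with_data(out)
    rec.sampling_rate = float(target_rate)
    return rec


def make_epochs(recording: MultichannelRecording, epoch_length=10.0) -> EpochSet:
    """Cut the recording into contiguous non-overlapping blocks.

    A trailing partial block is dropped. Raises if the recording is shorter
    than one epoch.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    samples = int(round(epoch_length * recording.sampling_rate))
    n_epochs = recording.n_samples // samples
    if n_epochs < 1:
        raise ValueError(
            f"recording ({recording.duration:.1f} s) shorter than one "
            f"{epoch_length:g} s epoch"
        )
    epochs = [
        recording.data[i * samples : (i + 1) * samples].copy()
        for i in range(n_epochs)
    ]
    starts = [i * samples / recording.sampling_rate for i in range(n_epochs)]
    return EpochSet(
        epochs=epochs,
        epoch_length=epoch_length,
        sampling_rate=recording.sampling_rate,
        channel_labels=list(recording.channel_labels),
        start_times=starts,
        region_of=dict(recording.region_of),
        soz_flag=dict(recording.soz_flag),
        source_id=recording.recording_id,
    )


def select_epochs(epochs: EpochSet, amplitude_z_threshold=6.0,
                  flat_threshold=1e-12) -> EpochSet:
    """Reject artefact-laden or flat epochs.

    For every channel, the peak absolute amplitude of each epoch is scored
    by a robust z (median / scaled MAD across epochs); an epoch is removed
    when any channel exceeds `amplitude_z_threshold` or any channel variance
    falls below `flat_threshold`. This is a reproducible surrogate for the
    visual selection of blocks free of movement artefacts and overt
    epileptic activity.
    """
    if amplitude_z_threshold <= 0 or flat_threshold <= 0:
        raise ValueError("thresholds must be positive")
    peaks = np.array([np.max(np.abs(e), axis=0) for e in epochs.epochs])
    variances = np.array([np.var(e, axis=0) for e in epochs.epochs])
    med = np.median(peaks, axis=0)
    mad = np.median(np.abs(peaks - med), axis=0) * 1.4826
    mad = np.where(mad <= 0, np.finfo(float).eps, mad)
    z = (peaks - med) / mad
    bad_amp = np.any(z > amplitude_z_threshold, axis=1)
    bad_flat = np.any(variances < flat_threshold, axis=1)
    keep = ~(bad_amp | bad_flat)
    if not keep.any():
        crit = "amplitude" if bad_amp.all() else "flatness"
        raise ValueError(f"no epoch survives selection ({crit} criterion)")
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info(
            "select_epochs: rejected %d/%d epochs (%d amplitude, %d flat)",
            n_rej, epochs.n_epochs, int(bad_amp.sum()), int(bad_flat.sum()),
        )
    return epochs.subset(np.flatnonzero(keep))


def split_half(epochs: EpochSet):
    """Split into early and late halves, preserving temporal order.

    With an odd count, the extra epoch goes to the early half. Requires at
    least two epochs.
    """
    m = epochs.n_epochs
    if m < 2:
        raise ValueError("need at least 2 epochs to split")
    cut = (m + 1) // 2
    return epochs.subset(range(cut)), epochs.subset(range(cut, m))


def exclude_channels(obj, soz_only=True, labels=()):
    """Remove channels from a recording or epoch set.

    With ``soz_only=True`` (default) every channel whose SOZ flag is set is
    dropped; additional labels can be given explicitly. Region and SOZ maps
    shrink accordingly. If the exclusion empties a region, a warning names
    it (its region pairs will be absent downstream).
    """
    drop = set(labels)
    if soz_only:
        drop |= {l for l in obj.channel_labels if obj.soz_flag.get(l, False)}
    missing = drop - set(obj.channel_labels)
    if missing:
        raise ValueError(f"unknown channel labels: {sorted(missing)}")
    if not drop:
        return obj
    keep_idx = [i for i, l in enumerate(obj.channel_labels) if l not in drop]
    if not keep_idx:
        raise ValueError("exclusion would remove every channel")
    keep_labels = [obj.channel_labels[i] for i in keep_idx]
    region_of = {l: r for l, r in obj.region_of.items() if l in keep_labels}
    soz_flag = {l: f for l, f in obj.soz_flag.items() if l in keep_labels}
    emptied = set(obj.region_of.values()) - set(region_of.values())
    for region in sorted(emptied):
        warnings.warn(
            f"region {region} has no contacts left after exclusion; "
            "its pairs will be dropped from statistics",
            RuntimeWarning,
        )
    if isinstance(obj, MultichannelRecording):
        return MultichannelRecording(
            data=obj.data[:, keep_idx],
            sampling_rate=obj.sampling_rate,
            channel_labels=keep_labels,
            region_of=region_of,
            soz_flag=soz_flag,
            recording_id=obj.recording_id,
        )
    if isinstance(obj, EpochSet):
        return EpochSet(
            epochs=[e[:, keep_idx] for e in obj.epochs],
            epoch_length=obj.epoch_length,
            sampling_rate=obj.sampling_rate,
            channel_labels=keep_labels,
            start_times=list(obj.start_times),
            region_of=region_of,
            soz_flag=soz_flag,
            source_id=obj.source_id,
        )
    raise TypeError(f"cannot exclude channels from {type(obj).__name__}")
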