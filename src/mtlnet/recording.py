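"""Core in-memory containers for continuous recordings and epoched data.

A :class:`MultichannelRecording` holds a referential-montage multichannel
signal (samples x channels) together with its sampling rate, channel labels,
an optional channel->region map and optional seizure-onset-zone (SOZ) flags.
An :class:`EpochSet` holds equal-length, non-overlapping blocks cut from such
a recording, which are the unit on which MVAR models are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MultichannelRecording", "EpochSet"]


@dataclass
class MultichannelRecording:
    """Continuous multichannel signal with channel metadata.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in arbitrary (consistent) units, one column per channel.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        One unique label per channel.
    region_of : dict
        Maps a channel label to its anatomical region (e.g. ``"AMG"``).
        Channels outside the regions of interest may be absent from the map.
    soz_flag : dict
        Maps a channel label to True when the contact lies in the clinically
        defined seizure onset zone. Missing labels count as False.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    region_of: dict = field(default_factory=dict)
    soz_flag: dict = field(default_factory=dict)
    recording_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def duration(self):
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate

    def is_soz(self, label):
        return bool(self.soz_flag.get(label, False))

    def with_data(self, data):
        """Copy of the recording with `data` replaced (same metadata)."""
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Equal-length contiguous blocks cut from one recording.

    Epochs keep the channel metadata of their source recording; `start_times`
    (seconds, strictly increasing) record provenance. Each epoch spans the
    half-open interval [start, start + epoch_length).
    """

    epochs: list
    epoch_length: float
    sampling_rate: float
    channel_labels: list
    start_times: list
    region_of: dict = field(default_factory=dict)
    soz_flag: dict = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self):
        self.epochs = [np.asarray(e, dtype=float) for e in self.epochs]
        if not self.epochs:
            raise ValueError("EpochSet requires at least one epoch")
        shape = self.epochs[0].shape
        for e in self.epochs:
            if e.shape != shape:
                raise ValueError("all epochs must share the same shape")
        if shape[1] != len(self.channel_labels):
            raise ValueError("label count does not match channel count")
        starts = list(self.start_times)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")

    @property
    def n_epochs(self):
        return len(self.epochs)

    @property
    def n_channels(self):
        return self.epochs[0].shape[1]

    @property
    def epoch_samples(self):
        return self.epochs[0].shape[0]

    @property
    def n_samples_total(self):
        return self.n_epochs * self.epoch_samples

    def subset(self, indices):
        """New EpochSet containing the epochs at `indices` (order kept)."""
        indices = list(indices)
        return replace(
            self,
            epochs=[self.epochs[i] for i in indices],
            start_times=[self.start_times[i] for i in indices],
        )
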