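"""Cortico-cortical evoked potential (CCEP) quantification for SPES data.

Single-pulse electrical stimulation (SPES) probes effective connectivity:
stimulating one contact pair evokes deflections at remote contacts. The
early N1 component is scored per recording channel as the z-score of the
maximum absolute amplitude of the trial-averaged waveform inside the 100 ms
window starting 10 ms after the pulse (the first 10 ms are skipped to
exclude the stimulation artefact), relative to the SD of the averaged
waveform's pre-stimulus baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import MultichannelRecording

__all__ = [
    "CCEPTrialSet",
    "AveragedCCEP",
    "CCEPResponse",
    "extract_trials",
    "baseline_average",
    "n1_zscore",
    "session_response_table",
]

#: Half-open N1 scoring window [10, 110) ms after stimulus onset.
N1_WINDOW = (0.010, 0.110)


@dataclass
class CCEPTrialSet:
    """Per-trial stimulus-locked segments for one stimulated pair."""

    stimulated_pair: tuple
    trials: np.ndarray  # (n_trials, n_times, n_channels)
    times: np.ndarray  # seconds relative to stimulus onset
    sampling_rate: float
    channel_labels: list
    region_of: dict

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_times, n_channels)")
        if self.trials.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")
        if not (self.times[0] <= 0 <= self.times[-1]):
            raise ValueError("stimulus onset (t=0) must lie inside the window")

    @property
    def n_trials(self):
        return self.trials.shape[0]


@dataclass
class AveragedCCEP:
    """Trial-averaged waveform with baseline statistics per channel."""

    stimulated_pair: tuple
    average: np.ndarray  # (n_times, n_channels)
    times: np.ndarray
    baseline_mean: np.ndarray  # per channel, of the averaged waveform
    baseline_sd: np.ndarray
    sampling_rate: float
    channel_labels: list
    region_of: dict
    n_trials: int


@dataclass
class CCEPResponse:
    """N1 score of one (stimulated pair, recording channel) combination."""

    stimulated_pair: tuple
    channel: str
    source_region: str
    target_region: str
    z: float
    latency_s: float
    flat: bool = False


def _neighbor_labels(label, labels):
    """Labels on the same electrode with contact number +-1 (e.g. HPC2/HPC4
    for HPC3). Used to drop contacts adjacent to the stimulation site."""
    import re

    m = re.match(r"^(.*?)(\d+)$", label)
    if not m:
        return set()
    stem, num = m.group(1), int(m.group(2))
    cands = {f"{stem}{num - 1}", f"{stem}{num + 1}"}
    return cands & set(labels)


def extract_trials(
    recording: MultichannelRecording,
    events: pd.DataFrame,
    pre=1.0,
    post=2.0,
    exclude_stim_neighbors=True,
) -> CCEPTrialSet:
    """Cut stimulus-locked trials (default -1 s to +2 s) out of a recording.

    The stimulating contact pair (and, by default, its immediate neighbour
    contacts) is removed from the recorded channels. Events whose window
    would reach outside the recording are dropped with a warning.
    """
    if len(events) == 0:
        raise ValueError("no stimulation events")
    pair = (
        str(events["cathode_label"].iloc[0]),
        str(events["anode_label"].iloc[0]),
    )
    drop = set(pair)
    if exclude_stim_neighbors:
        for label in pair:
            drop |= _neighbor_labels(label, recording.channel_labels)
    keep_idx = [
        i for i, l in enumerate(recording.channel_labels) if l not in drop
    ]
    if not keep_idx:
        raise ValueError("no recording channels left after excluding the "
                         "stimulated pair")
    labels = [recording.channel_labels[i] for i in keep_idx]
    fs = recording.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    trials = []
    dropped = 0
    for onset in events["onset_seconds"]:
        i0 = int(round(onset * fs))
        if i0 - n_pre < 0 or i0 + n_post > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[i0 - n_pre : i0 + n_post, keep_idx])
    if dropped:
        warnings.warn(
            f"{dropped} event(s) too close to the recording edge were "
            "dropped",
            RuntimeWarning,
        )
    if not trials:
        raise ValueError("every event fell outside the recording")
    return CCEPTrialSet(
        stimulated_pair=pair,
        trials=np.stack(trials),
        times=times,
        sampling_rate=fs,
        channel_labels=labels,
        # keep the full map: the stimulated pair's region is still needed
        # to label the source of each response
        region_of=dict(recording.region_of),
    )


def baseline_average(trials: CCEPTrialSet, baseline_window=(-1.0, -0.01)) -> AveragedCCEP:
    """Baseline-correct each trial, average, and measure the baseline noise.

    Each trial has its per-channel baseline mean subtracted before
    averaging; the baseline SD is then computed on the averaged waveform's
    baseline segment (the noise floor against which N1 is scored).
    """
    lo, hi = baseline_window
    if lo >= hi or hi > 0:
        raise ValueError("baseline window must be pre-stimulus and ordered")
    mask = (trials.times >= lo) & (trials.times < hi)
    if mask.sum() < 2:
        raise ValueError("baseline window contains too few samples")
    corrected = trials.trials - trials.trials[:, mask, :].mean(
        axis=1, keepdims=True
    )
    avg = corrected.mean(axis=0)
    base = avg[mask]
    sd = base.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("degenerate (zero-variance) baseline")
    return AveragedCCEP(
        stimulated_pair=trials.stimulated_pair,
        average=avg,
        times=trials.times,
        baseline_mean=base.mean(axis=0),
        baseline_sd=sd,
        sampling_rate=trials.sampling_rate,
        channel_labels=trials.channel_labels,
        region_of=trials.region_of,
        n_trials=trials.n_trials,
    )


def n1_zscore(avg: AveragedCCEP, response_window=N1_WINDOW):
    """Score the N1 component per channel.

    z = max |averaged amplitude| over the half-open `response_window`
    divided by the baseline SD; the latency is the time of that maximum.
    The absolute value is used because N1 polarity varies with a referential
    montage. Channels with zero baseline SD are flagged flat with z = 0.

    Returns a list of :class:`CCEPResponse`.
    """
    lo, hi = response_window
    if lo < avg.times[0] or hi > avg.times[-1]:
        raise ValueError("response window outside the trial window")
    mask = (avg.times >= lo) & (avg.times < hi)
    seg = np.abs(avg.average[mask])
    seg_times = avg.times[mask]
    src_regions = {avg.region_of.get(l) for l in avg.stimulated_pair}
    src_regions.discard(None)
    source_region = next(iter(src_regions)) if len(src_regions) == 1 else (
        "+".join(sorted(src_regions)) if src_regions else ""
    )
    out = []
    for ci, label in enumerate(avg.channel_labels):
        sd = avg.baseline_sd[ci]
        if sd == 0:
            out.append(
                CCEPResponse(avg.stimulated_pair, label,
                             source_region, avg.region_of.get(label, ""),
                             z=0.0, latency_s=float("nan"), flat=True)
            )
            continue
        k = int(np.argmax(seg[:, ci]))
        out.append(
            CCEPResponse(
                avg.stimulated_pair,
                label,
                source_region,
                avg.region_of.get(label, ""),
                z=float(seg[k, ci] / sd),
                latency_s=float(seg_times[k]),
            )
        )
    return out


def session_response_table(
    recording, events, pre=1.0, post=2.0, baseline_window=(-1.0, -0.01),
    response_window=N1_WINDOW,
) -> pd.DataFrame:
    """Full per-session CCEP pipeline returning the long-format table
    (stim_pair, channel, source_region, target_region, z, latency_s)."""
    trials = extract_trials(recording, events, pre=pre, post=post)
    avg = baseline_average(trials, baseline_window=baseline_window)
    rows = n1_zscore(avg, response_window=response_window)
    return pd.DataFrame(
        {
            "stim_pair": ["-".join(r.stimulated_pair) for r in rows],
            "channel": [r.channel for r in rows],
            "source_region": [r.source_region for r in rows],
            "target_region": [r.target_region for r in rows],
            "z": [r.z for r in rows],
            "latency_s": [r.latency_s for r in rows],
        }
    )
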