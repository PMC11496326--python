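"""Reading and writing recordings, event tables and configuration files.

Two on-disk signal formats are supported:

* a columnar numeric text dialect — first line ``# sampling_rate_hz=<fs>``,
  second line the tab-separated channel labels, then one whitespace-
  separated row per sample;
* EDF (16-bit European Data Format). Reading goes through :mod:`mne`;
  writing uses a small self-contained EDF writer (1 s data records,
  per-channel physical scaling), sufficient for round-tripping simulated
  recordings.

Channel->region maps with SOZ flags, and synthetic-generator parameters,
are read from YAML config files. Stimulation event tables are plain CSV
with columns ``onset_seconds, cathode_label, anode_label``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .recording import MultichannelRecording
from .synth import CouplingEdge, RegionSpec

__all__ = [
    "write_columnar",
    "read_columnar",
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "load_channel_config",
    "load_generator_config",
]


# ---------------------------------------------------------------- columnar

def write_columnar(recording: MultichannelRecording, path):
    header = (
        f"# sampling_rate_hz={recording.sampling_rate:g}\n"
        + "\t".join(recording.channel_labels)
    )
    np.savetxt(path, recording.data, fmt="%.9g", header=header, comments="")


def read_columnar(path, region_of=None, soz_flag=None) -> MultichannelRecording:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# sampling_rate_hz="):
            raise ValueError(f"{path}: missing sampling-rate header line")
        fs = float(first.split("=", 1)[1])
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, ndmin=2)
    return MultichannelRecording(
        data=data,
        sampling_rate=fs,
        channel_labels=labels,
        region_of=region_of or {},
        soz_flag=soz_flag or {},
    )


# --------------------------------------------------------------------- EDF

def _ascii(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: MultichannelRecording, path):
    """Write a 16-bit EDF file with 1 s data records.

    The sampling rate must be a positive integer; a trailing partial second
    is padded with the channel's final value (EDF stores whole records).
    Physical min/max are taken per channel from the data.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    data = recording.data
    n_ch = recording.n_channels
    n_rec = int(np.ceil(data.shape[0] / fs))
    padded = np.empty((n_rec * fs, n_ch))
    padded[: data.shape[0]] = data
    padded[data.shape[0]:] = data[-1]
    pmin = padded.min(axis=0)
    pmax = padded.max(axis=0)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    header = b""
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)  # local patient id (anonymous)
    header += _ascii("Startdate X X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (n_ch + 1), 8)
    header += _ascii("", 44)
    header += _ascii(n_rec, 8)
    header += _ascii("1", 8)  # record duration, seconds
    header += _ascii(n_ch, 4)

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += field(recording.channel_labels, 16)
    header += field([""] * n_ch, 80)  # transducer
    header += field(["uV"] * n_ch, 8)
    header += field([f"{v:.6g}"[:8] for v in pmin], 8)
    header += field([f"{v:.6g}"[:8] for v in pmax], 8)
    header += field([dmin] * n_ch, 8)
    header += field([dmax] * n_ch, 8)
    header += field([""] * n_ch, 80)  # prefiltering
    header += field([fs] * n_ch, 8)
    header += field([""] * n_ch, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            block = digital[rec * fs : (rec + 1) * fs]  # (fs, n_ch)
            fh.write(block.T.tobytes())


def read_edf(path, region_of=None, soz_flag=None) -> MultichannelRecording:
    """Read an EDF file via mne (physical units rescaled back to uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # mne stores Volts; we wrote uV
    return MultichannelRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        region_of=region_of or {},
        soz_flag=soz_flag or {},
    )


# ------------------------------------------------------------------ events

def write_events(events: pd.DataFrame, path):
    events.to_csv(path, index=False,
                  columns=["onset_seconds", "cathode_label", "anode_label"])


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path)
    required = {"onset_seconds", "cathode_label", "anode_label"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    return events


# ------------------------------------------------------------------ config

def load_channel_config(path):
    """Read a channel->region/SOZ map.

    Expected YAML shape::

        channels:
          - {label: AMG1, region: AMG, soz: false}
          - {label: HPC1, region: HPC, soz: true}

    Returns ``(region_of, soz_flag)`` dicts.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    region_of, soz_flag = {}, {}
    for entry in doc["channels"]:
        label = str(entry["label"])
        if "region" in entry and entry["region"] is not None:
            region_of[label] = str(entry["region"])
        soz_flag[label] = bool(entry.get("soz", False))
    return region_of, soz_flag


def load_generator_config(path):
    """Read synthetic-generator parameters.

    Expected YAML shape::

        regions: {AMG: 2, HPC: 2, TP: 2, PHP: 2}
        edges:
          - {source: AMG, target: HPC, strength: 0.4, lag: 16}
        order: 24
        seed: 1
        sampling_rate: 2000

    Returns a dict of keyword arguments for
    :func:`mtlnet.synth.make_ground_truth_mvar` under the keys
    ``region_spec``, ``edges``, ``order``, ``seed``, ``sampling_rate``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    spec = RegionSpec({str(k): int(v) for k, v in doc["regions"].items()})
    edges = [
        CouplingEdge(
            source=str(e["source"]),
            target=str(e["target"]),
            strength=float(e["strength"]),
            lag=int(e.get("lag", 1)),
        )
        for e in doc.get("edges", [])
    ]
    return {
        "region_spec": spec,
        "edges": edges,
        "order": int(doc.get("order", 3)),
        "seed": int(doc.get("seed", 0)),
        "sampling_rate": float(doc.get("sampling_rate", 2000.0)),
    }
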