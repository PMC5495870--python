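"""Readers and writers: internal HDF5 container, EDF export/import,
BrainVision import, network and loading exports.

The internal container is a plain HDF5 file holding the 4-D data array
plus metadata attributes; round-trips are bit-exact.  EDF export writes
one data record per trial (16-bit, physical scaling from the data
range) with an optional rectangular onset-marker channel, so that
standard EEG software — and :func:`read_edf` below, via ``mne`` — can
recover both the signals and the onset markers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import h5py
import numpy as np

from .datatypes import MultiTrialRecording

__all__ = [
    "write_container",
    "read_container",
    "write_edf",
    "read_edf",
    "read_brainvision",
    "write_network_json",
    "write_network_graphml",
    "read_network_json",
]

ONSET_CHANNEL = "ONSET"


# --------------------------------------------------------------------------
# Internal HDF5 container
# --------------------------------------------------------------------------

def _config_to_json(cfg) -> str:
    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    return json.dumps(cfg, default=default)


def write_container(rec: MultiTrialRecording, path) -> None:
    """Write a recording to the internal HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["channel_names"] = json.dumps(rec.channel_names)
        if rec.onset_sample is not None:
            f.create_dataset("onset_sample", data=np.asarray(rec.onset_sample))
        if rec.ground_truth is not None:
            f.attrs["ground_truth"] = _config_to_json(rec.ground_truth)
        if rec.meta:
            f.attrs["meta"] = _config_to_json(rec.meta)


def read_container(path) -> MultiTrialRecording:
    """Read a recording from the internal HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        names = json.loads(f.attrs["channel_names"])
        onset = None
        if "onset_sample" in f:
            onset = f["onset_sample"][()]
            if onset.ndim == 0:
                onset = int(onset)
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
        gt = json.loads(f.attrs["ground_truth"]) if "ground_truth" in f.attrs else None
    return MultiTrialRecording(
        data=data, fs=fs, channel_names=names, onset_sample=onset, ground_truth=gt, meta=meta
    )


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: MultiTrialRecording, path, add_onset_channel: bool = True) -> None:
    """Export a recording as a plain EDF file, one data record per trial.

    Trials of all subjects are written as consecutive fixed-length data
    records.  When ``add_onset_channel`` is set and the recording has an
    onset marker, an extra rectangular marker channel (1 from the onset
    sample onward) is appended so downstream software can recover the
    event without EDF+ annotations.
    """
    data = rec.data.reshape(-1, rec.n_channels, rec.n_samples)  # (records, C, T)
    names = list(rec.channel_names)
    if add_onset_channel and rec.onset_sample is not None:
        onset = int(np.asarray(rec.onset_sample).flat[0])
        marker = np.zeros((data.shape[0], 1, rec.n_samples))
        marker[:, :, onset:] = 1.0
        data = np.concatenate([data, marker], axis=1)
        names.append(ONSET_CHANNEL)
    n_records, n_sig, spr = data.shape

    phys_min = data.min(axis=(0, 2))
    phys_max = data.max(axis=(0, 2))
    same = phys_max - phys_min < 1e-12
    phys_max = np.where(same, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_sig), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(f"{rec.n_samples / rec.fs:g}", 8),
            _edf_field(n_sig, 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_edf_field(n, 16) for n in names),
            b"".join(_edf_field("", 80) for _ in names),
            b"".join(_edf_field("uV", 8) for _ in names),
            b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_min),
            b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in phys_max),
            b"".join(_edf_field(dig_min, 8) for _ in names),
            b"".join(_edf_field(dig_max, 8) for _ in names),
            b"".join(_edf_field("", 80) for _ in names),
            b"".join(_edf_field(spr, 8) for _ in names),
            b"".join(_edf_field("", 32) for _ in names),
        ]
    )
    # re-read the truncated physical bounds so scaling matches the header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    pmax = np.where(pmax - pmin < 1e-12, pmin + 1.0, pmax)
    gain = (dig_max - dig_min) / (pmax - pmin)

    with open(path, "wb") as f:
        f.write(header + per_sig)
        for rec_i in range(n_records):
            for c in range(n_sig):
                x = np.clip(data[rec_i, c], pmin[c], pmax[c])
                d = np.round((x - pmin[c]) * gain[c] + dig_min).astype("<i2")
                f.write(d.tobytes())


def read_edf(path, trial_length: float | None = None) -> MultiTrialRecording:
    """Read an EDF file (via mne) into a recording.

    Continuous data are reshaped into trials of ``trial_length`` seconds
    (default: the EDF record duration).  A rectangular onset-marker
    channel written by :func:`write_edf` is converted back into the
    onset sample index and removed from the data.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts for uV-typed channels
    names = list(raw.ch_names)
    if trial_length is None:
        trial_length = raw.n_times / fs
        n_trials = 1
    n_samp = int(round(trial_length * fs))
    n_trials = data.shape[1] // n_samp
    data = data[:, : n_trials * n_samp].reshape(len(names), n_trials, n_samp)
    data = data.transpose(1, 0, 2)[None]  # (1, trials, channels, samples)

    onset = None
    if ONSET_CHANNEL in names:
        mi = names.index(ONSET_CHANNEL)
        marker = data[0, 0, mi]
        above = np.flatnonzero(marker > 0.5 * marker.max()) if marker.max() > 0 else []
        if len(above):
            onset = int(above[0])
        keep = [i for i in range(len(names)) if i != mi]
        data = data[:, :, keep]
        names = [names[i] for i in keep]
    return MultiTrialRecording(data=data, fs=fs, channel_names=names, onset_sample=onset)


def read_brainvision(vhdr_path) -> MultiTrialRecording:
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg) via mne as one trial."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    return MultiTrialRecording(
        data=data[None, None],
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------

def _to_nx(net):
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for src, tgt, w, level in net.edges:
        g.add_edge(src, tgt, weight=float(w), level=int(level))
    return g


def write_network_json(net, path) -> None:
    payload = {
        "nodes": net.nodes,
        "thresholds": list(net.thresholds),
        "roi": None
        if net.roi is None
        else {"band": list(net.roi.band), "interval": list(net.roi.interval), "label": net.roi.label},
        "edges": [
            {"source": s, "target": t, "weight": float(w), "level": int(l)}
            for s, t, w, l in net.edges
        ],
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def read_network_json(path):
    from .connectivity import DirectedNetwork, ROISpec

    with open(path) as f:
        payload = json.load(f)
    roi = None
    if payload.get("roi"):
        r = payload["roi"]
        roi = ROISpec(tuple(r["band"]), tuple(r["interval"]), r.get("label", ""))
    return DirectedNetwork(
        nodes=payload["nodes"],
        edges=[(e["source"], e["target"], e["weight"], e["level"]) for e in payload["edges"]],
        roi=roi,
        thresholds=tuple(payload.get("thresholds", (0.08, 0.10, 0.12))),
    )


def write_network_graphml(net, path) -> None:
    import networkx as nx

    nx.write_graphml(_to_nx(net), path)
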