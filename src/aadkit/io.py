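"""Readers, writers and containers.

Two on-disk formats:

- the *fixture container*: one hierarchical array file (HDF5) per cohort
  with a JSON sidecar carrying provenance (config, seed, package
  version), addressable by (subject, block, condition);
- the *multistream container*: named streams (EEG / audio / markers) with
  per-stream sample arrays and timestamps, mirroring the information
  model of LSL/XDF recordings.  Reading aligns every stream to the EEG
  clock by least-squares linear timestamp regression (offset + drift) and
  turns marker streams into (time, label) event pairs.

WAV audio goes through ``scipy.io.wavfile``, scaled to [-1, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .envelope import AudioStream, Envelope
from .preprocess import EEGRecording
from .synthetic import (
    CohortDataset,
    GroundTruth,
    SimulationConfig,
    KernelSpec,
    SyntheticRecording,
)

__all__ = [
    "Stream",
    "MultistreamRecording",
    "read_audio",
    "write_audio",
    "write_multistream",
    "read_multistream",
    "save_cohort",
    "load_cohort",
]


@dataclass
class Stream:
    """One named data stream with its own clock."""

    name: str
    kind: str  # eeg | audio | markers
    samples: np.ndarray
    timestamps: np.ndarray
    nominal_rate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"stream {self.name!r}: timestamps not strictly increasing")


@dataclass
class MultistreamRecording:
    """Aligned multistream recording: EEG + optional audio + events."""

    eeg: EEGRecording
    audio: AudioStream | None
    events: list[tuple[float, str]]
    clock: dict[str, tuple[float, float]]  # per-stream (offset, drift) vs EEG clock


def read_audio(path) -> AudioStream:
    """Read a WAV file, scaling integer formats to [-1, 1]."""
    try:
        fs, data = wavfile.read(path)
    except Exception as err:
        raise ValueError(f"not a readable WAV file: {path}") from err
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioStream(data.astype(float), float(fs), source_id=str(path))


def write_audio(path, audio: AudioStream) -> None:
    """Write a waveform as 16-bit WAV (samples clipped to [-1, 1])."""
    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, int(audio.fs), (x * 32767).astype(np.int16))


def write_multistream(path, streams: list[Stream]) -> None:
    """Write streams to the HDF5 multistream container."""
    with h5py.File(path, "w") as f:
        for s in streams:
            g = f.create_group(s.name)
            g.attrs["kind"] = s.kind
            g.attrs["nominal_rate"] = s.nominal_rate
            g.create_dataset("timestamps", data=s.timestamps, track_times=False)
            if s.kind == "markers":
                dt = h5py.string_dtype()
                labels = [str(x) for x in np.asarray(s.samples).tolist()]
                g.create_dataset("samples", data=labels, dtype=dt, track_times=False)
            else:
                g.create_dataset("samples", data=np.asarray(s.samples, dtype=float), track_times=False)
            if s.labels:
                g.attrs["labels"] = json.dumps(list(s.labels))


def _fit_clock(timestamps: np.ndarray) -> tuple[float, float]:
    """Least-squares linear fit t ~ offset + drift * index."""
    idx = np.arange(timestamps.size, dtype=float)
    if timestamps.size == 1:
        return float(timestamps[0]), 0.0
    drift, offset = np.polyfit(idx, timestamps, 1)
    return float(offset), float(drift)


def read_multistream(path) -> MultistreamRecording:
    """Read a multistream container and align all streams to the EEG clock.

    Each stream's timestamps are regressed linearly on sample index; other
    streams' event/sample times are re-expressed relative to the EEG
    stream's fitted start time, recovering inter-stream clock offsets.
    """
    streams: dict[str, Stream] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            ts = np.asarray(g["timestamps"])
            if ts.size > 1 and np.any(np.diff(ts) <= 0):
                raise ValueError(
                    f"corrupt file: stream {name!r} has non-monotone timestamps"
                )
            kind = g.attrs["kind"]
            if kind == "markers":
                samples = np.asarray(g["samples"]).astype(str)
            else:
                samples = np.asarray(g["samples"], dtype=float)
            labels = json.loads(g.attrs.get("labels", "[]"))
            streams[name] = Stream(name, kind, samples, ts, float(g.attrs["nominal_rate"]), labels)

    eeg_streams = [s for s in streams.values() if s.kind == "eeg"]
    if not eeg_streams:
        raise ValueError("format error: no 'eeg' stream present in " + str(path))
    es = eeg_streams[0]
    eeg_offset, _ = _fit_clock(es.timestamps)

    clock: dict[str, tuple[float, float]] = {}
    events: list[tuple[float, str]] = []
    audio = None
    for s in streams.values():
        offset, drift = _fit_clock(s.timestamps)
        clock[s.name] = (offset - eeg_offset, drift)
        if s.kind == "markers":
            for t, lab in zip(s.timestamps, s.samples):
                events.append((float(t - eeg_offset), str(lab)))
        elif s.kind == "audio" and audio is None:
            audio = AudioStream(np.asarray(s.samples, dtype=float), s.nominal_rate, s.name)

    data = np.atleast_2d(np.asarray(es.samples, dtype=float))
    labels = es.labels or [f"Ch{i + 1:02d}" for i in range(data.shape[0])]
    eeg = EEGRecording(data, es.nominal_rate, labels)
    events.sort(key=lambda e: e[0])
    return MultistreamRecording(eeg, audio, events, clock)


# ---------------------------------------------------------------------------
# fixture container


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    k = d["kernel"]
    if k.get("topography") is not None:
        k["topography"] = list(np.asarray(k["topography"], dtype=float))
    return d


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_cohort(path, cohort: CohortDataset) -> None:
    """Write a cohort to the HDF5 fixture container + JSON sidecar."""
    path = Path(path)
    from . import __version__

    with h5py.File(path, "w") as f:
        for (subj, block, cond), rec in cohort.recordings.items():
            g = f.create_group(f"subject_{subj:02d}/{block}/{cond}")
            g.create_dataset(
                "eeg",
                data=rec.eeg.data,
                compression="gzip",
                compression_opts=1,
                track_times=False,
            )
            g.attrs["fs_eeg"] = rec.eeg.fs
            g.attrs["labels"] = json.dumps(rec.eeg.labels)
            g.create_dataset("env_att", data=rec.env_att.samples, track_times=False)
            g.attrs["fs_env"] = rec.env_att.fs
            if rec.env_ign is not None:
                g.create_dataset("env_ign", data=rec.env_ign.samples, track_times=False)
            t = rec.truth
            gt = g.create_group("truth")
            gt.create_dataset("kernels", data=t.kernels, track_times=False)
            gt.create_dataset("side_switches", data=t.side_switches, track_times=False)
            gt.attrs["g_att"] = t.g_att
            gt.attrs["g_ign"] = t.g_ign
            if t.street_entry is not None:
                gt.attrs["street_entry"] = t.street_entry
                gt.attrs["street_exit"] = t.street_exit
            gt.attrs["artifact_log"] = json.dumps(
                [[k, s, e, c] for (k, s, e, c) in t.artifact_log]
            )
    sidecar = {
        "config": _config_dict(cohort.config),
        "config_hash": config_hash(cohort.config),
        "seed": cohort.config.seed,
        "package_version": __version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))


def load_cohort(path) -> CohortDataset:
    """Read a cohort fixture container written by :func:`save_cohort`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["config"])
    kernel_d = dict(cfg_d.pop("kernel"))
    if kernel_d.get("topography") is not None:
        kernel_d["topography"] = np.asarray(kernel_d["topography"])
    cfg_d["side_switch_range"] = tuple(cfg_d["side_switch_range"])
    for int_key in ("n_subjects", "channels", "seed"):
        cfg_d[int_key] = int(cfg_d[int_key])
    config = SimulationConfig(kernel=KernelSpec(**kernel_d), **cfg_d)

    recordings = {}
    with h5py.File(path, "r") as f:
        for subj_key in f:
            subj = int(subj_key.split("_")[1])
            for block in f[subj_key]:
                for cond in f[subj_key][block]:
                    g = f[subj_key][block][cond]
                    eeg = EEGRecording(
                        np.asarray(g["eeg"]),
                        float(g.attrs["fs_eeg"]),
                        json.loads(g.attrs["labels"]),
                    )
                    env_att = Envelope(np.asarray(g["env_att"]), float(g.attrs["fs_env"]))
                    env_ign = (
                        Envelope(np.asarray(g["env_ign"]), float(g.attrs["fs_env"]))
                        if "env_ign" in g
                        else None
                    )
                    gt = g["truth"]
                    truth = GroundTruth(
                        kernels=np.asarray(gt["kernels"]),
                        g_att=float(gt.attrs["g_att"]),
                        g_ign=float(gt.attrs["g_ign"]),
                        condition=cond,
                        side_switches=np.asarray(gt["side_switches"]),
                        street_entry=float(gt.attrs["street_entry"])
                        if "street_entry" in gt.attrs
                        else None,
                        street_exit=float(gt.attrs["street_exit"])
                        if "street_exit" in gt.attrs
                        else None,
                        artifact_log=[
                            (k, s, e, c)
                            for k, s, e, c in json.loads(gt.attrs["artifact_log"])
                        ],
                    )
                    recordings[(subj, block, cond)] = SyntheticRecording(
                        subj, block, cond, eeg, env_att, env_ign, truth
                    )
    return CohortDataset(recordings, config)
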