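"""Readers and writers for recordings, montages, and the result container.

Supported inputs: EDF/BDF (continuous, uniform sampling rate), or a raw
float64 matrix (.npy or text) with a JSON sidecar header ``{fs, labels,
units}``.  Montages are whitespace-delimited ``label x y z`` text (.sfp
style).  Results serialize to an HDF5 container with one group per pipeline
stage; scalars and strings round-trip bit-exactly, arrays to full double
precision.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path

import h5py
import numpy as np

from .model import Montage, Recording
from .noisy import NoisyChannelResult, WindowStats
from .params import PipelineConfig, config_from_flat_dict, config_to_flat_dict
from .reference import ReferenceResult

__all__ = [
    "read_montage",
    "write_montage",
    "read_edf",
    "write_edf",
    "read_recording",
    "write_result",
    "read_result",
]

_UNIT_SCALE = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


# ---------------------------------------------------------------------------
# montage text format
# ---------------------------------------------------------------------------

def read_montage(path) -> Montage:
    labels, positions = [], []
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage line: {raw_line!r}")
        labels.append(parts[0])
        positions.append([float(v) for v in parts[1:]])
    if not labels:
        raise ValueError(f"montage file {path} contains no electrodes")
    return Montage(tuple(labels), np.array(positions))


def write_montage(montage: Montage, path) -> None:
    lines = [
        f"{label}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}"
        for label, p in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# EDF / BDF
# ---------------------------------------------------------------------------

def _ascii(field: bytes) -> str:
    return field.decode("ascii", errors="replace").strip()


def read_edf(path):
    """Minimal continuous EDF/BDF reader.

    Returns ``(data_uV, fs, labels)``.  All signals must share one sampling
    rate; physical scaling and unit conversion to microvolts are applied.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path} is too short to be EDF/BDF")
    is_bdf = raw[0] == 0xFF and raw[1:8] == b"BIOSEMI"
    if not is_bdf and not raw[:1].isascii():
        raise ValueError(f"{path}: unrecognized signal file format")
    n_records = int(_ascii(raw[236:244]))
    record_dur = float(_ascii(raw[244:252]))
    ns = int(_ascii(raw[252:256]))
    if ns <= 0:
        raise ValueError("no signals in file")
    off = 256

    def fields(width):
        nonlocal off
        vals = [_ascii(raw[off + i * width: off + (i + 1) * width]) for i in range(ns)]
        off += ns * width
        return vals

    labels = fields(16)
    fields(80)  # transducer
    dims = fields(8)
    phys_min = [float(v) for v in fields(8)]
    phys_max = [float(v) for v in fields(8)]
    dig_min = [float(v) for v in fields(8)]
    dig_max = [float(v) for v in fields(8)]
    fields(80)  # prefilter
    spr = [int(v) for v in fields(8)]
    fields(32)  # reserved
    if len(set(spr)) != 1:
        raise ValueError("signals with differing sampling rates are not supported")
    if record_dur <= 0 or not np.isfinite(record_dur):
        raise ValueError(f"non-finite or non-positive record duration {record_dur}")
    fs = spr[0] / record_dur

    bytes_per = 3 if is_bdf else 2
    payload = raw[off:]
    expected = n_records * ns * spr[0] * bytes_per
    if len(payload) < expected:
        raise ValueError("truncated EDF/BDF data section")
    if is_bdf:
        b = np.frombuffer(payload[:expected], dtype=np.uint8).reshape(-1, 3)
        digital = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        digital = np.where(digital >= 1 << 23, digital - (1 << 24), digital)
    else:
        digital = np.frombuffer(payload[:expected], dtype="<i2").astype(np.int32)
    digital = digital.reshape(n_records, ns, spr[0])
    data = np.empty((ns, n_records * spr[0]), dtype=np.float64)
    for i in range(ns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        chan = digital[:, i, :].reshape(-1).astype(np.float64)
        phys = (chan - dig_min[i]) * gain + phys_min[i]
        scale = _UNIT_SCALE.get(dims[i].lower(), 1.0)
        data[i] = phys * scale
    return data, fs, labels


def write_edf(path, data, fs, labels, *, bdf: bool = False) -> None:
    """Minimal EDF/BDF writer (1 s records, microvolt signals)."""
    data = np.asarray(data, dtype=np.float64)
    ns, n = data.shape
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    n_records = n // spr
    if n_records * spr != n:
        raise ValueError("sample count must be a whole number of 1 s records")
    dig_max = (1 << 23) - 1 if bdf else (1 << 15) - 1
    dig_min = -dig_max - 1
    span = np.abs(data).max(axis=1)
    span = np.where(span > 0, span * 1.01, 1.0)
    # quantize against the value the 8-char header field actually stores
    span = np.array([float(f"{s:.6g}"[:8]) for s in span])

    head = bytearray()
    head += b"\xffBIOSEMI" if bdf else b"0" + b" " * 7
    head += b" " * 80 + b" " * 80
    head += b"01.01.00" + b"00.00.00"
    head += f"{256 * (1 + ns):<8d}".encode()
    head += (b"24BIT" + b" " * 39) if bdf else b" " * 44
    head += f"{n_records:<8d}".encode()
    head += f"{1:<8d}".encode()
    head += f"{ns:<4d}".encode()

    def block(values, width):
        out = bytearray()
        for v in values:
            s = f"{v:<{width}}"
            if len(s) > width:
                raise ValueError(f"field {v!r} too wide for EDF header")
            out += s.encode("ascii")
        return out

    head += block(labels, 16)
    head += block([""] * ns, 80)
    head += block(["uV"] * ns, 8)
    head += block([f"{-s:.6g}"[:8] for s in span], 8)
    head += block([f"{s:.6g}"[:8] for s in span], 8)
    head += block([dig_min] * ns, 8)
    head += block([dig_max] * ns, 8)
    head += block([""] * ns, 80)
    head += block([spr] * ns, 8)
    head += block([""] * ns, 32)

    gains = (dig_max - dig_min) / (2.0 * span)
    digital = np.rint((data + span[:, None]) * gains[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype(np.int32)
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(bytes(head))
        if bdf:
            flat = records.reshape(-1)
            raw = np.empty((flat.size, 3), dtype=np.uint8)
            u = flat.astype(np.int64) & 0xFFFFFF
            raw[:, 0] = u & 0xFF
            raw[:, 1] = (u >> 8) & 0xFF
            raw[:, 2] = (u >> 16) & 0xFF
            fh.write(raw.tobytes())
        else:
            fh.write(records.astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# recording entry point
# ---------------------------------------------------------------------------

def _read_matrix(path: Path):
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise FileNotFoundError(f"matrix input needs a JSON header at {header_path}")
    header = json.loads(header_path.read_text())
    for key in ("fs", "labels"):
        if key not in header:
            raise ValueError(f"matrix header missing {key!r}")
    fs = float(header["fs"])
    if not np.isfinite(fs):
        raise ValueError(f"non-finite sampling rate {header['fs']!r}")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, ndmin=2)
    scale = _UNIT_SCALE.get(str(header.get("units", "uV")).lower())
    if scale is None:
        raise ValueError(f"unknown units {header['units']!r}")
    return np.asarray(data, dtype=np.float64) * scale, fs, list(header["labels"])


def read_recording(path, montage_path=None, evaluation_channels=()) -> Recording:
    """Load a recording and align channel order with its montage."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        data, fs, labels = read_edf(path)
    elif suffix in (".npy", ".txt", ".csv", ".tsv"):
        data, fs, labels = _read_matrix(path)
    else:
        raise ValueError(f"unknown recording format {suffix!r}")
    if montage_path is None:
        raise ValueError("a montage file is required (label x y z per line)")
    montage = read_montage(montage_path)
    if set(labels) != set(montage.labels):
        raise ValueError(
            f"signal channels ({len(labels)}) do not match montage channels "
            f"({len(montage.labels)})"
        )
    order = [labels.index(l) for l in montage.labels]
    return Recording(
        data[order], fs, montage, evaluation_channels=tuple(evaluation_channels)
    )


# ---------------------------------------------------------------------------
# HDF5 result container
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")
_STAGES = ("original", "before_interp", "final")


def _write_labels(group, name, labels):
    group.create_dataset(name, data=np.array(sorted(labels), dtype=object), dtype=_STR)


def _read_labels(group, name):
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def _write_noisy(group, noisy: NoisyChannelResult):
    s = noisy.stats
    group.attrs["window_seconds"] = s.window_seconds
    group.attrs["ransac_window_seconds"] = s.ransac_window_seconds
    group.create_dataset("channels", data=np.array(noisy.channels, dtype=object), dtype=_STR)
    for name in ("deviation_z", "max_correlation", "noise_z", "window_deviation"):
        group.create_dataset(name, data=getattr(s, name))
    group.create_dataset("dropout_flags", data=s.dropout_flags.astype(np.uint8))
    if s.ransac_correlation is not None:
        group.create_dataset("ransac_correlation", data=s.ransac_correlation)
    bad = group.create_group("bad_by")
    for cat, chans in noisy.bad_by.items():
        _write_labels(bad, cat, chans)


def _read_noisy(group, params) -> NoisyChannelResult:
    channels = tuple(_read_labels(group, "channels"))
    stats = WindowStats(
        deviation_z=group["deviation_z"][()],
        max_correlation=group["max_correlation"][()],
        noise_z=group["noise_z"][()],
        dropout_flags=group["dropout_flags"][()].astype(bool),
        ransac_correlation=group["ransac_correlation"][()]
        if "ransac_correlation" in group
        else None,
        window_deviation=group["window_deviation"][()],
        window_seconds=float(group.attrs["window_seconds"]),
        ransac_window_seconds=float(group.attrs["ransac_window_seconds"]),
    )
    bad_by = {cat: frozenset(_read_labels(group["bad_by"], cat)) for cat in group["bad_by"]}
    return NoisyChannelResult(channels, bad_by, stats, params)


def write_result(
    recording: Recording,
    result: ReferenceResult,
    path,
    config: PipelineConfig | None = None,
) -> None:
    """Serialize the processed recording and full reference provenance."""
    config = config or PipelineConfig()
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "eegclean-result"
        fh.attrs["format_version"] = 1

        sig = fh.create_group("signal")
        sig.create_dataset("data", data=recording.data)
        sig.attrs["fs"] = recording.fs
        sig.create_dataset(
            "labels", data=np.array(recording.montage.labels, dtype=object), dtype=_STR
        )
        sig.create_dataset("positions", data=recording.montage.positions)
        sig.create_dataset(
            "evaluation_channels",
            data=np.array(recording.evaluation_channels, dtype=object),
            dtype=_STR,
        )

        ref = fh.create_group("reference")
        ref.create_dataset("reference_signal", data=np.asarray(result.reference_signal))
        _write_labels(ref, "interpolated", result.interpolated)
        _write_labels(ref, "still_bad", result.still_bad)
        ref.attrs["iterations_used"] = int(result.iterations_used)
        originals = ref.create_group("original_bad_signals")
        for label, row in result.original_bad_signals.items():
            originals.create_dataset(label, data=np.asarray(row))

        noisy = fh.create_group("noisy")
        for stage, snapshot in zip(
            _STAGES,
            (result.noisy_original, result.noisy_before_interp, result.noisy_final),
        ):
            if snapshot is not None:
                _write_noisy(noisy.create_group(stage), snapshot)

        cfg = fh.create_group("config")
        for key, value in config_to_flat_dict(config).items():
            if value is None:
                cfg.attrs[key] = "none"
            elif isinstance(value, (list, tuple)):
                cfg.attrs[key] = np.asarray(value, dtype=np.float64)
            else:
                cfg.attrs[key] = value


def read_result(path):
    """Inverse of :func:`write_result`.

    Returns ``(recording, reference_result, config)``.
    """
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "eegclean-result":
            raise ValueError(f"{path} is not an eegclean result container")
        for required in ("signal", "reference", "noisy", "config"):
            if required not in fh:
                raise ValueError(f"result container is missing the {required!r} group")

        flat = {}
        for key, value in fh["config"].attrs.items():
            if isinstance(value, np.ndarray):
                flat[key] = [float(v) for v in value]
            elif isinstance(value, bytes):
                flat[key] = value.decode()
            elif isinstance(value, str) and value == "none":
                flat[key] = None
            elif isinstance(value, np.bool_):
                flat[key] = bool(value)
            elif isinstance(value, np.integer):
                flat[key] = int(value)
            elif isinstance(value, np.floating):
                flat[key] = float(value)
            else:
                flat[key] = value
        config = config_from_flat_dict(flat)

        sig = fh["signal"]
        montage = Montage(tuple(_read_labels(sig, "labels")), sig["positions"][()])
        recording = Recording(
            sig["data"][()],
            float(sig.attrs["fs"]),
            montage,
            evaluation_channels=tuple(_read_labels(sig, "evaluation_channels")),
        )

        ref = fh["reference"]
        noisy = fh["noisy"]
        if "original" not in noisy:
            raise ValueError("result container is missing the original statistics snapshot")
        snapshots = {
            stage: _read_noisy(noisy[stage], config.noisy) if stage in noisy else None
            for stage in _STAGES
        }
        result = ReferenceResult(
            reference_signal=ref["reference_signal"][()],
            interpolated=frozenset(_read_labels(ref, "interpolated")),
            still_bad=frozenset(_read_labels(ref, "still_bad")),
            noisy_original=snapshots["original"],
            noisy_before_interp=snapshots["before_interp"],
            noisy_final=snapshots["final"],
            iterations_used=int(ref.attrs["iterations_used"]),
            original_bad_signals={
                label: ds[()] for label, ds in ref["original_bad_signals"].items()
            },
        )
    return recording, result, config
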