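"""Readers/writers: portable epoch format, schedule JSON, EDF+ export.

The epoch format is a raw little-endian float64 array (C order, trials x
channels x time) in ``<name>.dat`` plus a JSON sidecar ``<name>.json``
holding sampling rate, window, labels, layout, provenance and a SHA-256
of the array bytes so corruption or sidecar/array mismatch is detected
on read.  The round trip is bit-exact for the array.

EDF export writes EDF+C with one 16-bit signal per channel and the event
schedule as EDF+ annotations; per the format, amplitudes are quantised
to the per-channel physical range, so the EDF round trip is lossy at the
quantisation step while the .dat format is not.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .containers import EpochSet, EventSchedule, Recording, n_epoch_samples
from .layout import SensorLayout

_MAGIC = "auderp-epochs-v1"


def _base(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in {".dat", ".json"} else p


def _epoch_digest(raw: bytes, shape, srate, tmin, tmax, labels) -> str:
    """Checksum binding the array bytes to the critical sidecar fields."""
    meta = json.dumps([list(shape), float(srate), float(tmin), float(tmax),
                       list(labels)]).encode()
    return hashlib.sha256(raw + meta).hexdigest()


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` as ``<base>.dat`` + ``<base>.json``."""
    base = _base(path)
    raw = np.ascontiguousarray(epochs.data, dtype="<f8").tobytes()
    digest = _epoch_digest(raw, epochs.data.shape, epochs.srate, epochs.tmin,
                           epochs.tmax, epochs.labels)
    sidecar = {
        "format": _MAGIC,
        "shape": list(epochs.data.shape),
        "dtype": "<f8",
        "order": "C",
        "srate": epochs.srate,
        "tmin": epochs.tmin,
        "tmax": epochs.tmax,
        "n_times": n_epoch_samples(epochs.tmin, epochs.tmax, epochs.srate),
        "labels": list(epochs.labels),
        "subject_id": epochs.subject_id,
        "rejected_mask": epochs.rejected_mask.astype(int).tolist(),
        "non_scalp": list(epochs.non_scalp),
        "layout": epochs.layout.to_dict(),
        "provenance": _jsonable(epochs.provenance),
        "sha256": digest,
    }
    base.parent.mkdir(parents=True, exist_ok=True)
    base.with_suffix(".dat").write_bytes(raw)
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path: str | Path) -> EpochSet:
    """Read epochs written by :func:`write_epochs`, verifying integrity."""
    base = _base(path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if sidecar.get("format") != _MAGIC:
        raise IOError(f"{base}: not an epoch sidecar")
    raw = base.with_suffix(".dat").read_bytes()
    shape = tuple(sidecar["shape"])
    digest = _epoch_digest(raw, shape, sidecar["srate"], sidecar["tmin"],
                           sidecar["tmax"], sidecar["labels"])
    if digest != sidecar["sha256"]:
        raise IOError(f"{base}: array/sidecar mismatch (checksum failed)")
    data = np.frombuffer(raw, dtype="<f8").reshape(shape).astype(float)
    if len(sidecar["labels"]) != shape[0]:
        raise IOError(f"{base}: label count does not match trial axis")
    return EpochSet(
        data=data,
        tmin=sidecar["tmin"], tmax=sidecar["tmax"], srate=sidecar["srate"],
        labels=list(sidecar["labels"]),
        layout=SensorLayout.from_dict(sidecar["layout"]),
        subject_id=sidecar.get("subject_id", ""),
        rejected_mask=np.array(sidecar["rejected_mask"], dtype=bool),
        non_scalp=list(sidecar.get("non_scalp", [])),
        provenance=sidecar.get("provenance", {}),
    )


def schedule_to_json(schedule: EventSchedule, path: str | Path | None = None) -> str:
    """Serialise a schedule; returns the JSON text (and writes it if asked)."""
    doc = {
        "onsets_s": schedule.onsets.tolist(),
        "labels": list(schedule.labels),
        "block_index": schedule.block_index.tolist(),
        "metadata": _jsonable(schedule.metadata),
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def schedule_from_json(source: str | Path) -> EventSchedule:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    doc = json.loads(text)
    meta = {k: (np.array(v) if isinstance(v, list) else v)
            for k, v in doc.get("metadata", {}).items()}
    return EventSchedule(np.array(doc["onsets_s"]), list(doc["labels"]),
                         np.array(doc["block_index"]), meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# EDF+ export

_EDF_MAX_SIGNALS = 256


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _annotation_records(events: EventSchedule, n_records: int,
                        record_dur: float) -> list[bytes]:
    """Pack events into per-record TAL byte strings (EDF+ annotations)."""
    by_record: list[list[bytes]] = [[] for _ in range(n_records)]
    for onset, label in zip(events.onsets, events.labels):
        rec = min(int(onset // record_dur), n_records - 1)
        tal = f"+{onset:.4f}".rstrip("0").rstrip(".").encode() or b"+0"
        by_record[rec].append(tal + b"\x14" + label.encode("ascii", "replace") + b"\x14\x00")
    out = []
    for rec in range(n_records):
        stamp = f"+{rec * record_dur:.4f}".rstrip("0").rstrip(".")
        if "." not in stamp and stamp == "+":
            stamp = "+0"
        out.append(stamp.encode() + b"\x14\x14\x00" + b"".join(by_record[rec]))
    return out


def export_edf(recording: Recording, path: str | Path,
               patient_id: str = "X X X X", recording_id: str = "Startdate X X X X") -> None:
    """Export a continuous recording as an EDF+C file with annotations.

    One signal per channel, 1 s data records, physical units microvolts.
    Values are quantised to 16 bits over each channel's observed range;
    a trailing partial record is zero-padded.
    """
    n_ch, n_samp = recording.data.shape
    if n_ch + 1 > _EDF_MAX_SIGNALS:
        raise ValueError(f"too many channels for EDF export ({n_ch})")
    if len(recording.events) and recording.events.onsets[-1] >= recording.duration:
        raise ValueError("event onset beyond recording duration")
    srate = recording.srate
    if abs(srate - round(srate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    srate = int(round(srate))

    record_dur = 1.0
    n_records = int(np.ceil(n_samp / srate))
    padded = np.zeros((n_ch, n_records * srate))
    padded[:, :n_samp] = recording.data

    # per-channel symmetric physical range; floor avoids zero-width ranges
    span = np.maximum(np.max(np.abs(padded), axis=1), 1e-3)
    pmin, pmax = -span, span
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((padded - pmin[:, None]) / scale[:, None]) + dmin,
                      dmin, dmax).astype("<i2")

    tals = _annotation_records(recording.events, n_records, record_dur)
    ann_len = max(len(t) for t in tals)
    ann_len += (-ann_len) % 2          # int16-sized payload
    ann_samples = ann_len // 2

    n_sig = n_ch + 1
    header_bytes = 256 * (n_sig + 1)

    h = b""
    h += _edf_field("0", 8)
    h += _edf_field(patient_id, 80)
    h += _edf_field(recording_id, 80)
    h += _edf_field("01.01.00", 8)
    h += _edf_field("00.00.00", 8)
    h += _edf_field(str(header_bytes), 8)
    h += _edf_field("EDF+C", 44)
    h += _edf_field(str(n_records), 8)
    h += _edf_field(str(record_dur).rstrip("0").rstrip("."), 8)
    h += _edf_field(str(n_sig), 4)

    labels = [n[:16] for n in recording.layout.channel_names] + ["EDF Annotations"]
    transducer = [""] * n_ch + [""]
    phys_dim = ["uV"] * n_ch + [""]
    phys_min = [f"{v:.6g}"[:8] for v in pmin] + ["-1"]
    phys_max = [f"{v:.6g}"[:8] for v in pmax] + ["1"]
    dig_min = [str(dmin)] * n_ch + [str(dmin)]
    dig_max = [str(dmax)] * n_ch + [str(dmax)]
    prefilter = [""] * n_sig
    samples = [str(srate)] * n_ch + [str(ann_samples)]

    for column, width in ((labels, 16), (transducer, 80), (phys_dim, 8),
                          (phys_min, 8), (phys_max, 8), (dig_min, 8),
                          (dig_max, 8), (prefilter, 80), (samples, 8)):
        for v in column:
            h += _edf_field(v, width)
    h += b" " * (32 * n_sig)
    assert len(h) == header_bytes

    out = bytearray(h)
    for rec in range(n_records):
        sl = slice(rec * srate, (rec + 1) * srate)
        out += digital[:, sl].tobytes()
        out += tals[rec].ljust(ann_len, b"\x00")
    Path(path).write_bytes(bytes(out))
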