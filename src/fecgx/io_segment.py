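"""Record I/O, Fourier resampling, fixed-length segmentation and splits.

Records are read/written as a minimal WFDB-compatible subset (text ``.hea``
header plus 16-bit little-endian ``.dat``, annotations as plain-text sample
index files) or as delimited text (one column per channel).  Segmentation
cuts 1024-sample windows with a 24-sample overlap between consecutive
windows (stride 1000); the inverse operation averages the shared samples.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.signal import resample

from .synthetic import EcgRecord

__all__ = ["SegmentSet", "read_record", "write_record", "fft_resample",
           "segment", "reassemble", "make_split"]

SEGMENT_LEN = 1024
SEGMENT_OVERLAP = 24
_WFDB_GAIN = 2000.0  # ADC units per mV; int16 range covers +-16 mV


@dataclass
class SegmentSet:
    """Fixed-length windows cut from records, the unit of training/inference.

    origin rows are (record_id, channel, start_index) tuples mapping every
    segment back into its source record.
    """

    segments: np.ndarray                      # (n_segments, n)
    fs: float
    origin: list[tuple[str, int, int]] = field(default_factory=list)
    role: str = "train"

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D array")
        if len(self.origin) != len(self.segments):
            raise ValueError("origin table must have one row per segment")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n(self) -> int:
        return self.segments.shape[1]

    def record_ids(self) -> set[str]:
        return {rid for rid, _, _ in self.origin}

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("segments", data=self.segments)
            f.attrs["fs"] = self.fs
            f.attrs["role"] = self.role
            f.create_dataset("origin_record", data=np.array(
                [rid for rid, _, _ in self.origin], dtype=h5py.string_dtype()))
            f.create_dataset("origin_channel", data=np.array(
                [ch for _, ch, _ in self.origin], dtype=np.int64))
            f.create_dataset("origin_start", data=np.array(
                [st for _, _, st in self.origin], dtype=np.int64))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        with h5py.File(path, "r") as f:
            segs = f["segments"][...]
            fs = float(f.attrs["fs"])
            role = str(f.attrs["role"])
            origin = list(zip((s.decode() if isinstance(s, bytes) else str(s)
                               for s in f["origin_record"][...]),
                              (int(c) for c in f["origin_channel"][...]),
                              (int(s) for s in f["origin_start"][...])))
        return cls(segs, fs, origin, role)


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".hea", ".dat") or path.with_suffix(".hea").exists():
        return "wfdb"
    if suffix in (".csv", ".txt", ".tsv"):
        return "csv"
    if suffix == ".npy":
        return "npy"
    raise ValueError(f"cannot infer format of {path}")


def _read_annotations(base: Path, n_samples: int) -> dict[str, np.ndarray]:
    peaks: dict[str, np.ndarray] = {}
    for ann in sorted(base.parent.glob(base.name + ".*.txt")):
        label = ann.suffixes[-2].lstrip(".")
        idx = np.loadtxt(ann, dtype=np.int64, ndmin=1)
        if idx.size and (idx.min() < 0 or idx.max() >= n_samples):
            raise ValueError(
                f"annotation file {ann.name}: indices outside [0, {n_samples})")
        peaks[label] = idx
    return peaks


def read_record(path: str | Path, format: str | None = None,
                fs: float | None = None) -> EcgRecord:
    """Read an ECG record from WFDB-subset, delimited-text or .npy files.

    For headerless formats (csv/npy) the sampling rate must be supplied via
    ``fs`` (default 500 Hz).  Channels are preserved in file order; plain-text
    annotation files ``<base>.<label>.txt`` next to the record are picked up.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "wfdb":
        base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
        hea = base.with_suffix(".hea")
        if not hea.exists():
            raise FileNotFoundError(hea)
        lines = [ln for ln in hea.read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        name, n_sig, fs_hdr, n_samp = lines[0].split()[:4]
        n_sig, n_samp = int(n_sig), int(n_samp)
        gains = []
        for ln in lines[1:1 + n_sig]:
            fields = ln.split()
            gains.append(float(fields[2].split("/")[0].split("(")[0]))
        raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
        if raw.size != n_sig * n_samp:
            raise ValueError(f"{base}.dat: expected {n_sig * n_samp} samples, "
                             f"found {raw.size}")
        data = raw.reshape(n_samp, n_sig).T / np.asarray(gains)[:, None]
        return EcgRecord(data, float(fs_hdr), _read_annotations(base, n_samp),
                         meta={"source": str(base), "format": "wfdb", "name": name})
    if fmt == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as f:
            sniff = f.readline()
        delim = "\t" if "\t" in sniff else ","
        has_header = any(c.isalpha() for c in sniff.replace("e", "").replace("E", ""))
        data = np.loadtxt(path, delimiter=delim, skiprows=1 if has_header else 0,
                          ndmin=2)
        data = data.T  # file columns are channels
        base = path.with_suffix("")
        return EcgRecord(data, fs or 500.0, _read_annotations(base, data.shape[1]),
                         meta={"source": str(path), "format": "csv"})
    if fmt == "npy":
        if not path.exists():
            raise FileNotFoundError(path)
        data = np.load(path)
        data = np.atleast_2d(data)
        if data.shape[0] > data.shape[1]:  # stored as (n_samples, n_channels)
            data = data.T
        base = path.with_suffix("")
        return EcgRecord(data, fs or 500.0, _read_annotations(base, data.shape[1]),
                         meta={"source": str(path), "format": "npy"})
    raise ValueError(f"unknown format {fmt!r}")


def write_record(record: EcgRecord, base_path: str | Path,
                 format: str = "wfdb") -> list[Path]:
    """Write a record (and its annotations) to disk; returns written paths."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "wfdb":
        adc = np.clip(np.round(record.samples * _WFDB_GAIN), -32768, 32767)
        dat = base.with_suffix(".dat")
        adc.T.astype("<i2").tofile(dat)
        hea = base.with_suffix(".hea")
        lines = [f"{base.name} {record.n_channels} {record.fs:g} {record.n_samples}"]
        for ch in range(record.n_channels):
            lines.append(f"{base.name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 ch{ch}")
        hea.write_text("\n".join(lines) + "\n")
        written += [hea, dat]
    elif format == "csv":
        out = base.with_suffix(".csv")
        with open(out, "w", newline="") as f:
            w = _csv.writer(f)
            w.writerow([f"ch{i}" for i in range(record.n_channels)])
            for row in record.samples.T:
                w.writerow([repr(float(v)) for v in row])  # full-precision round trip
        written.append(out)
    else:
        raise ValueError(f"unknown format {format!r}")
    for label, idx in record.r_peaks.items():
        ann = base.parent / f"{base.name}.{label}.txt"
        np.savetxt(ann, np.asarray(idx, dtype=np.int64), fmt="%d")
        written.append(ann)
    return written


# ---------------------------------------------------------------------------
# resampling and segmentation
# ---------------------------------------------------------------------------

def fft_resample(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Fourier-domain resampling to ``target_fs``; annotations re-indexed."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == record.fs:
        return EcgRecord(record.samples.copy(), record.fs,
                         {k: v.copy() for k, v in record.r_peaks.items()},
                         dict(record.meta))
    n_out = int(round(record.n_samples * target_fs / record.fs))
    data = resample(record.samples, n_out, axis=1)
    ratio = target_fs / record.fs
    peaks = {}
    for label, idx in record.r_peaks.items():
        new = np.round(idx * ratio).astype(np.int64)
        peaks[label] = new[new < n_out]
    meta = dict(record.meta)
    meta["resampled_from_fs"] = record.fs
    return EcgRecord(data, target_fs, peaks, meta)


def segment(record: EcgRecord, n: int = SEGMENT_LEN, overlap: int = SEGMENT_OVERLAP,
            record_id: str | None = None, channels: list[int] | None = None,
            role: str = "train") -> SegmentSet:
    """Cut fixed-length windows with a shared overlap between neighbours.

    stride = n - overlap; windows start at 0, stride, 2*stride, ...; a final
    partial window is dropped.
    """
    if n <= 2 * overlap:
        raise ValueError("window length must exceed twice the overlap")
    if record.n_samples < n:
        raise ValueError(f"record length {record.n_samples} shorter than window {n}")
    rid = record_id or record.meta.get("name") or record.meta.get("source", "record")
    stride = n - overlap
    starts = range(0, record.n_samples - n + 1, stride)
    segs, origin = [], []
    for ch in (channels if channels is not None else range(record.n_channels)):
        for s in starts:
            segs.append(record.samples[ch, s:s + n])
            origin.append((rid, ch, s))
    return SegmentSet(np.asarray(segs), record.fs, origin, role)


def reassemble(segset: SegmentSet, channel: int = 0,
               record_id: str | None = None) -> np.ndarray:
    """Overlap-average segments of one channel back into a 1-D signal."""
    rows = [(i, st) for i, (rid, ch, st) in enumerate(segset.origin)
            if ch == channel and (record_id is None or rid == record_id)]
    if not rows:
        raise ValueError("no segments for the requested channel/record")
    n = segset.n
    length = max(st for _, st in rows) + n
    acc = np.zeros(length)
    cnt = np.zeros(length)
    for i, st in rows:
        acc[st:st + n] += segset.segments[i]
        cnt[st:st + n] += 1.0
    return acc / cnt


def make_split(segment_sets: list[SegmentSet] | SegmentSet, test_fraction: float,
               holdout_record_ids: set[str] | None = None,
               seed: int = 0) -> tuple[SegmentSet, SegmentSet]:
    """Deterministic train/test split with whole-record holdout.

    Whole records named in ``holdout_record_ids`` go to the test side; the
    remaining segments are shuffled (seeded) and split at ``test_fraction``.
    No segment appears on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if isinstance(segment_sets, SegmentSet):
        segment_sets = [segment_sets]
    holdout = set(holdout_record_ids or ())
    segs = np.concatenate([s.segments for s in segment_sets])
    origin = [o for s in segment_sets for o in s.origin]
    fs = segment_sets[0].fs

    held = [i for i, (rid, _, _) in enumerate(origin) if rid in holdout]
    rest = [i for i, (rid, _, _) in enumerate(origin) if rid not in holdout]
    rng = np.random.default_rng(seed)
    rest = list(rng.permutation(rest))
    n_test = int(round(test_fraction * len(rest)))
    test_idx = sorted(held + rest[:n_test])
    train_idx = sorted(rest[n_test:])
    if not train_idx or not test_idx:
        raise ValueError("split produced an empty train or test set")
    train = SegmentSet(segs[train_idx], fs, [origin[i] for i in train_idx], "train")
    test = SegmentSet(segs[test_idx], fs, [origin[i] for i in test_idx], "test")
    return train, test
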