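"""Reading and writing EEG recordings and expert spike annotations.

The canonical amplitude unit throughout the package is the microvolt (μV),
because the half-wave amplitude thresholds of the mimetic detector are stated
in μV.  EDF files store a physical dimension per signal; on read, everything
is converted to μV.  Times are seconds from the start of the recording and
sample/time conversions always use ``index = round(time * rate)`` with
0-based indexing.

Two on-disk recording formats are supported:

* EDF (European Data Format), the standard clinical exchange format — read
  through :mod:`mne`, written by a small built-in writer (16-bit integer
  records, so a write/read round trip is exact only to quantization).
* A delimited-text fallback: an optional ``# rate_hz=<float>`` comment line,
  a header row of channel labels, then one row of μV values per sample.

Annotations are plain CSV, one marker per line: ``time_seconds[,channel]``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "AnnotationSet",
    "read_recording",
    "write_delimited",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "select_average",
    "time_to_index",
    "index_to_time",
]


def time_to_index(time_s: float, rate: float, start_time: float = 0.0) -> int:
    """Convert a time in seconds to the nearest 0-based sample index."""
    return int(round((time_s - start_time) * rate))


def index_to_time(index: int, rate: float, start_time: float = 0.0) -> float:
    """Convert a 0-based sample index to time in seconds."""
    return start_time + index / rate


@dataclass
class Recording:
    """A multi-channel EEG recording at a single sampling rate.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` holding amplitudes in μV.
    labels
        Channel names (10–20 convention strings such as ``"F8"``).
    rate
        Sampling frequency in Hz (> 0).
    start_time
        Time offset of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    labels: tuple[str, ...]
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(str(l) for l in self.labels)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels × samples) array")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (have {list(self.labels)})"
            ) from None
        return self.samples[i]


@dataclass
class AnnotationSet:
    """Expert spike markers: strictly increasing times in seconds.

    ``channels`` optionally attributes each marker to an electrode.
    Duplicate times (equal to within 1 ms) are collapsed on construction.
    """

    times: np.ndarray
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(times < 0):
            raise ValueError("marker times must be non-negative")
        order = np.argsort(times, kind="stable")
        times = times[order]
        chans = None
        if self.channels is not None:
            chans = [self.channels[i] for i in order]
        # collapse markers identical to 1 ms
        keep: list[int] = []
        for i, t in enumerate(times):
            if not keep or round(t * 1000) != round(times[keep[-1]] * 1000):
                keep.append(i)
        self.times = times[keep]
        self.channels = tuple(chans[i] for i in keep) if chans is not None else None

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# delimited text format
# ---------------------------------------------------------------------------

_RATE_PREFIX = "# rate_hz="


def write_delimited(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as delimited text (rate comment, label header, rows)."""
    with open(path, "w") as fh:
        fh.write(f"{_RATE_PREFIX}{rec.rate:g}\n")
        fh.write(",".join(rec.labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.9g", delimiter=",")


def _read_delimited(path: str | os.PathLike, rate_hint: float | None) -> Recording:
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file")
        rate = rate_hint
        if first.startswith(_RATE_PREFIX):
            rate = float(first[len(_RATE_PREFIX):])
            header = fh.readline()
        else:
            header = first
        if rate is None:
            raise ValueError(
                f"{path}: no sampling rate in file header and no rate_hint given"
            )
        if not header.strip():
            raise ValueError(f"{path}: missing channel-label header row")
        labels = [c.strip() for c in header.strip().split(",")]
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed sample rows: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"{path}: no sample rows")
    if data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {len(labels)} channel labels but rows have {data.shape[1]} columns"
        )
    return Recording(samples=data.T, labels=tuple(labels), rate=float(rate))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


def _read_edf(path: str | os.PathLike) -> Recording:
    import mne  # deferred: heavy import, only needed for EDF

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne converts voltage channels to SI volts internally
    data_uv = raw.get_data() * 1e6
    # EDF labels often carry a signal-type prefix ("EEG F8"); keep the site name
    labels = tuple(
        name[4:] if name.upper().startswith("EEG ") else name
        for name in raw.ch_names
    )
    return Recording(samples=data_uv, labels=labels, rate=float(raw.info["sfreq"]))


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as a minimal EDF file.

    The signal is stored in 16-bit integer records with physical dimension
    μV; re-reading recovers the samples to within the 16-bit quantization of
    each channel's physical range.  Record duration is one second when the
    sample count divides evenly, otherwise a single record holds the whole
    signal (small fixtures); trailing samples that do not fill a record are
    zero-padded.
    """
    n = rec.n_samples
    rate = rec.rate
    if abs(rate - round(rate)) < 1e-9 and n % int(round(rate)) == 0:
        spr = int(round(rate))          # samples per record per channel
        record_dur = 1.0
        n_records = n // spr
    else:
        spr = n
        record_dur = n / rate
        n_records = 1

    ns = rec.n_channels
    pmins = rec.samples.min(axis=1)
    pmaxs = rec.samples.max(axis=1)
    flat = pmaxs - pmins < 1e-12
    pmins = np.where(flat, pmins - 1.0, pmins)
    pmaxs = np.where(flat, pmaxs + 1.0, pmaxs)
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))                 # patient id
        fh.write(_edf_field("Startdate X X X X", 80))       # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (ns + 1)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field(f"{record_dur:g}", 8))
        fh.write(_edf_field(str(ns), 4))
        for lab in rec.labels:
            fh.write(_edf_field(f"EEG {lab}", 16))
        for _ in range(ns):
            fh.write(_edf_field("", 80))                    # transducer
        for _ in range(ns):
            fh.write(_edf_field("uV", 8))
        for p in pmins:
            fh.write(_edf_field(f"{p:.8g}"[:8], 8))
        for p in pmaxs:
            fh.write(_edf_field(f"{p:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_edf_field(str(dmin), 8))
        for _ in range(ns):
            fh.write(_edf_field(str(dmax), 8))
        for _ in range(ns):
            fh.write(_edf_field("", 80))                    # prefiltering
        for _ in range(ns):
            fh.write(_edf_field(str(spr), 8))
        for _ in range(ns):
            fh.write(_edf_field("", 32))

        scale = (dmax - dmin) / (pmaxs - pmins)
        padded = np.zeros((ns, n_records * spr))
        padded[:, :n] = rec.samples
        digital = np.round((padded - pmins[:, None]) * scale[:, None] + dmin)
        digital = np.clip(digital, dmin, dmax).astype("<i2")
        for r in range(n_records):
            for ch in range(ns):
                fh.write(digital[ch, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------


def read_recording(
    path: str | os.PathLike,
    fmt: str | None = None,
    rate_hint: float | None = None,
) -> Recording:
    """Read an EEG recording from disk.

    Parameters
    ----------
    path
        File to read.
    fmt
        ``"edf"`` or ``"delimited"``; inferred from the file suffix when
        omitted (``.edf`` → EDF, anything else → delimited).
    rate_hint
        Sampling rate in Hz for delimited files that lack the rate comment.
        A missing rate is an error — never a silent default.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty file")
    if fmt is None:
        fmt = "edf" if path.lower().endswith(".edf") else "delimited"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path, rate_hint)
    raise ValueError(f"unknown recording format {fmt!r}")


_HEADER_TOKENS = {"time", "time_s", "time_seconds", "seconds"}


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read expert markers from CSV: one ``time_seconds[,channel]`` per line.

    Times come back sorted ascending with duplicates (to 1 ms) collapsed.
    A non-numeric time raises with the offending line number; an initial
    header line whose first field is a recognised time-column name is
    skipped.
    """
    times: list[float] = []
    channels: list[str] = []
    any_channel = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and parts[0].lower() in _HEADER_TOKENS:
                continue
            try:
                t = float(parts[0])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric marker time {parts[0]!r}"
                ) from None
            if t < 0:
                raise ValueError(f"{path}: line {lineno}: negative marker time {t}")
            times.append(t)
            if len(parts) > 1 and parts[1]:
                channels.append(parts[1])
                any_channel = True
            else:
                channels.append("")
    return AnnotationSet(
        times=np.asarray(times, dtype=float),
        channels=tuple(channels) if any_channel else None,
    )


def write_annotations(ann: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,channel\n")
        chans = ann.channels or ("",) * len(ann)
        for t, c in zip(ann.times, chans):
            fh.write(f"{t:.6f},{c}\n")


def select_average(rec: Recording, wanted: tuple[str, ...] | list[str]) -> np.ndarray:
    """Average the named channels into the single analysis trace.

    The two-stage detector operates on one time series obtained by averaging
    the channels on which the spikes are evident (the same channels the
    expert annotated).  A single wanted channel is returned unchanged.
    """
    if not wanted:
        raise ValueError("at least one channel must be selected")
    for lab in wanted:
        if lab not in rec.labels:
            raise KeyError(
                f"channel {lab!r} not in recording (have {list(rec.labels)})"
            )
    idx = [rec.labels.index(lab) for lab in wanted]
    if len(idx) == 1:
        return rec.samples[idx[0]].copy()
    return rec.samples[idx].mean(axis=0)
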