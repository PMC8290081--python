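"""Recording and epoch containers plus the EDF + events-TSV format layer.

EDF (16-bit) is the canonical interchange format.  Events travel in a sidecar
TSV named ``<stem>.events.tsv`` with columns ``onset_sample``, ``code`` and
``condition``.  Vendor continuous formats (e.g. NeuroScan CNT) are delegated
to :mod:`mne` when it is importable; the core never depends on it.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MODEL60, channel_kind

__all__ = [
    "RawRecording",
    "EpochSet",
    "DEFAULT_CODES",
    "MissingEventsError",
    "UnknownFormatError",
    "read_recording",
    "write_recording",
    "extract_channels",
    "epoch",
]

#: Trigger codes used by the synthetic task (external code tables are mapped
#: onto these names via the ``code_map`` argument of :func:`epoch`).
DEFAULT_CODES: dict[int, str] = {1: "neutral", 2: "smoking", 3: "animal"}


class MissingEventsError(FileNotFoundError):
    """An EDF recording was opened without its events sidecar."""


class UnknownFormatError(ValueError):
    """The requested recording format is not supported."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, acquisition order.
    events : ndarray, shape (n_events, 2)
        ``(sample_index, code)`` pairs, 0-based, sorted by sample.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        ev = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        ev = ev[np.argsort(ev[:, 0], kind="stable")]
        if ev.size and (ev[:, 0].min() < 0 or ev[:, 0].max() >= self.data.shape[1]):
            raise ValueError("event sample indices out of bounds")
        self.events = ev

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def channel_kinds(self) -> list[str]:
        """Per-channel kind (``scalp`` / ``mastoid`` / ``eog``) from the label."""
        return [channel_kind(l) for l in self.channel_labels]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def copy(self) -> "RawRecording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            events=self.events.copy(),
        )


@dataclass
class EpochSet:
    """Trials x channels x time array on a fixed millisecond timebase.

    The window convention is half-open ``[tmin, tmax)`` with 0-based sample
    indexing at the source rate, so a (-200, 1000) ms window at 250 Hz holds
    exactly 300 samples.
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    channel_labels: list[str]
    kept: np.ndarray = None  # type: ignore[assignment]
    sampling_rate: float = 250.0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x time)")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.labels) != n_tr or len(self.kept) != n_tr:
            raise ValueError("labels/kept length must equal number of trials")
        if len(self.times_ms) != n_t:
            raise ValueError("times_ms length must equal time axis")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length must equal channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            times_ms=self.times_ms,
            labels=self.labels[mask],
            channel_labels=list(self.channel_labels),
            kept=self.kept[mask],
            sampling_rate=self.sampling_rate,
        )

    def kept_only(self) -> "EpochSet":
        return self.select(self.kept)


# --------------------------------------------------------------------------
# EDF 16-bit writer / reader (continuous, one data-record per second)
# --------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF plus an events sidecar TSV."""
    path = Path(path)
    if path.suffix.lower() != ".edf":
        path = path.with_suffix(".edf")
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # one-second records
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / spr)) if n_samp else 0
    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, :n_samp] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X", 80),
            _edf_field("cueloop", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (1 + n_ch)), 8),
            _edf_field(f"NSAMP={n_samp}", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig = b"".join(_edf_field(l, 16) for l in rec.channel_labels)
    sig += b"".join(_edf_field("", 80) for _ in range(n_ch))
    sig += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_edf_field(f"{v:.6g}", 8) for v in pmin)
    sig += b"".join(_edf_field(f"{v:.6g}", 8) for v in pmax)
    sig += b"".join(_edf_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field("", 80) for _ in range(n_ch))
    sig += b"".join(_edf_field(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_edf_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        # record-major, signal-major within each record
        recs = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())

    events_df = pd.DataFrame(
        {
            "onset_sample": rec.events[:, 0],
            "code": rec.events[:, 1],
            "condition": [DEFAULT_CODES.get(int(c), str(c)) for c in rec.events[:, 1]],
        }
    )
    events_df.to_csv(_sidecar_path(path), sep="\t", index=False)
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".events.tsv")


def _slice_fields(sig: bytes, n_ch: int, byte_off: int, width: int) -> list[str]:
    return [
        sig[byte_off + i * width : byte_off + (i + 1) * width].decode("ascii").strip()
        for i in range(n_ch)
    ]


def read_recording(path: str | Path, fmt: str = "edf") -> RawRecording:
    """Read a recording.

    Parameters
    ----------
    path : path-like
        File to read.
    fmt : {"edf", "vendor"}
        ``"edf"`` reads 16-bit EDF with a ``.events.tsv`` sidecar;
        ``"vendor"`` delegates continuous vendor formats (CNT, ...) to
        :mod:`mne` if installed.
    """
    path = Path(path)
    if fmt == "vendor":
        return _read_vendor(path)
    if fmt != "edf":
        raise UnknownFormatError(f"unknown recording format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256 or not head[:8].decode("ascii", "replace").strip() == "0":
            raise UnknownFormatError(f"{path} is not a valid EDF file")
        reserved = head[192:236].decode("ascii", "replace").strip()
        n_rec = int(head[236:244])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch)
        labels = _slice_fields(sig, n_ch, 0, 16)
        dims = _slice_fields(sig, n_ch, (16 + 80) * n_ch, 8)
        o = (16 + 80 + 8) * n_ch
        pmin = np.array([float(v) for v in _slice_fields(sig, n_ch, o, 8)])
        pmax = np.array([float(v) for v in _slice_fields(sig, n_ch, o + 8 * n_ch, 8)])
        dmin = np.array([float(v) for v in _slice_fields(sig, n_ch, o + 16 * n_ch, 8)])
        dmax = np.array([float(v) for v in _slice_fields(sig, n_ch, o + 24 * n_ch, 8)])
        o2 = o + 32 * n_ch + 80 * n_ch
        spr = np.array([int(v) for v in _slice_fields(sig, n_ch, o2, 8)])
        raw = np.frombuffer(fh.read(), dtype="<i2")

    bad_units = [l for l, d in zip(labels, dims) if d.lower() not in {"uv", "µv"}]
    if bad_units:
        raise ValueError(f"expected µV units, got other units for channels: {bad_units}")
    if len(set(spr)) != 1:
        raise UnknownFormatError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    recs = raw[: n_rec * n_ch * spr0].reshape(n_rec, n_ch, spr0)
    digital = recs.transpose(1, 0, 2).reshape(n_ch, n_rec * spr0).astype(np.float64)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]

    n_samp = n_rec * spr0
    if reserved.startswith("NSAMP="):
        n_samp = min(n_samp, int(reserved.split("=", 1)[1]))
    data = data[:, :n_samp]

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingEventsError(
            f"missing events sidecar {sidecar.name} next to {path.name}"
        )
    ev_df = pd.read_csv(sidecar, sep="\t")
    events = ev_df[["onset_sample", "code"]].to_numpy(dtype=np.int64)
    return RawRecording(
        data=data, sampling_rate=float(spr0), channel_labels=labels, events=events
    )


def _read_vendor(path: Path) -> RawRecording:
    try:
        import mne  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise UnknownFormatError(
            "vendor-format ingestion requires the optional 'mne' package"
        ) from exc
    raw = mne.io.read_raw_cnt(path, preload=True, verbose="error")  # pragma: no cover
    data = raw.get_data() * 1e6  # pragma: no cover
    ev = mne.events_from_annotations(raw, verbose="error")[0]  # pragma: no cover
    events = ev[:, [0, 2]] if len(ev) else np.empty((0, 2), int)  # pragma: no cover
    return RawRecording(  # pragma: no cover
        data=data,
        sampling_rate=raw.info["sfreq"],
        channel_labels=list(raw.ch_names),
        events=events,
    )


# --------------------------------------------------------------------------
# Channel policy and epoching
# --------------------------------------------------------------------------


def extract_channels(rec: RawRecording, policy: str = "model60") -> RawRecording:
    """Reduce a recording to the decoding channel set.

    ``model60`` keeps the 60 standard channels (everything except CB1, CB2,
    HEOG and VEOG), preserving order.  Raises ``KeyError`` naming any
    required channel that is absent.
    """
    if policy != "model60":
        raise ValueError(f"unknown channel policy {policy!r}")
    upper = {l.upper(): i for i, l in enumerate(rec.channel_labels)}
    missing = [l for l in MODEL60 if l not in upper]
    if missing:
        raise KeyError(f"recording is missing required channel(s): {missing}")
    keep = [i for i, l in enumerate(rec.channel_labels) if l.upper() in set(MODEL60)]
    return RawRecording(
        data=rec.data[keep],
        sampling_rate=rec.sampling_rate,
        channel_labels=[rec.channel_labels[i] for i in keep],
        events=rec.events.copy(),
    )


def epoch(
    rec: RawRecording,
    codes: dict[int, str] | None = None,
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    baseline_ms: tuple[float, float] | None = (-200.0, 0.0),
) -> EpochSet:
    """Cut baseline-corrected trials around event onsets.

    The window is half-open ``[window_ms[0], window_ms[1])``.  Events whose
    window would fall outside the recording are dropped; the count of dropped
    trials is reported on ``EpochSet.n_dropped`` (and warned about).
    """
    codes = DEFAULT_CODES if codes is None else codes
    fs = rec.sampling_rate
    start_off = int(round(window_ms[0] * fs / 1000.0))
    stop_off = int(round(window_ms[1] * fs / 1000.0))
    n_t = stop_off - start_off
    if n_t <= 0:
        raise ValueError("empty epoch window")
    times_ms = (np.arange(start_off, stop_off) / fs) * 1000.0

    sel = [(int(s), codes[int(c)]) for s, c in rec.events if int(c) in codes]
    data, labels, dropped = [], [], 0
    for sample, cond in sel:
        a, b = sample + start_off, sample + stop_off
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        data.append(rec.data[:, a:b])
        labels.append(cond)
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) with incomplete windows")
    arr = (
        np.stack(data)
        if data
        else np.empty((0, rec.n_channels, n_t), dtype=np.float64)
    )
    if baseline_ms is not None and len(arr):
        bmask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
        if not bmask.any():
            raise ValueError("baseline interval contains no samples")
        arr = arr - arr[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=arr,
        times_ms=times_ms,
        labels=np.array(labels, dtype=object),
        channel_labels=list(rec.channel_labels),
        sampling_rate=fs,
        n_dropped=dropped,
    )
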