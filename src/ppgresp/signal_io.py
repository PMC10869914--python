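"""Reading, writing and segmenting two-channel physiological records.

A record holds a PPG waveform and, optionally, a reference respiration
waveform, both uniformly sampled.  Supported on-disk layouts:

``bidmc_csv``
    The "Signals" CSV dialect distributed with the BIDMC waveform dataset:
    a ``Time [s]`` column plus ``PLETH`` and ``RESP`` channels.  Headers in
    the distributed files carry leading spaces, so column names are matched
    after stripping whitespace.
``generic_csv``
    A plain CSV with an optional time column ``t`` (seconds) and one or two
    channel columns; the sampling rate comes from the time column or from
    ``fs_hint``.
``wfdb``
    WFDB record/header pairs, available only when the ``wfdb`` package is
    installed; CSV is the reference path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UniformSignal",
    "Record",
    "Segment",
    "FormatError",
    "DataError",
    "read_record",
    "write_record",
    "segment_record",
]


class FormatError(ValueError):
    """A file does not conform to the requested dialect."""


class DataError(ValueError):
    """File parsed but its contents violate a data precondition."""


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : ndarray
        Sample values in arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Time span covered by the samples, ``(n - 1) / fs``."""
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i / fs`` in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class Record:
    """A physiological recording: PPG plus optional reference respiration."""

    record_id: str
    ppg: UniformSignal
    resp: UniformSignal | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resp is not None:
            span_p = self.ppg.duration_s
            span_r = self.resp.duration_s
            tol = 1.0 / min(self.ppg.fs, self.resp.fs)
            if abs(span_p - span_r) > tol or abs(self.ppg.t0 - self.resp.t0) > tol:
                raise ValueError(
                    "ppg and resp must cover the same time span "
                    f"(ppg {span_p:.3f}s vs resp {span_r:.3f}s)"
                )


@dataclass
class Segment:
    """One contiguous analysis window cut from a :class:`Record`."""

    record_id: str
    index: int
    ppg: UniformSignal
    resp: UniformSignal | None
    duration_s: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BIDMC_TIME = "Time [s]"
_BIDMC_PPG = "PLETH"
_BIDMC_RESP = "RESP"


def _fs_from_time(t: np.ndarray) -> float:
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise DataError(f"time column is not strictly increasing at row {bad + 1}")
    return 1.0 / float(np.mean(dt))


def read_record(
    path: str | Path,
    dialect: str = "bidmc_csv",
    fs_hint: float | None = None,
    record_id: str | None = None,
) -> Record:
    """Read a record from disk.

    Parameters
    ----------
    path : path
        Input file (CSV for the CSV dialects, header path for ``wfdb``).
    dialect : {"bidmc_csv", "generic_csv", "wfdb"}
        On-disk layout; see the module docstring.
    fs_hint : float, optional
        Sampling rate in Hz for ``generic_csv`` files without a time column.
    record_id : str, optional
        Identifier for the returned record; defaults to the file stem.

    Returns
    -------
    Record
        Channels in original units; no filtering is applied here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rid = record_id if record_id is not None else path.stem

    if dialect == "wfdb":
        return _read_wfdb(path, rid)
    if dialect not in ("bidmc_csv", "generic_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]

    if dialect == "bidmc_csv":
        for col in (_BIDMC_TIME, _BIDMC_PPG, _BIDMC_RESP):
            if col not in df.columns:
                raise FormatError(f"BIDMC CSV is missing required column {col!r}")
        t = df[_BIDMC_TIME].to_numpy(float)
        fs = _fs_from_time(t)
        ppg = UniformSignal(df[_BIDMC_PPG].to_numpy(float), fs=fs, t0=float(t[0]))
        resp = UniformSignal(df[_BIDMC_RESP].to_numpy(float), fs=fs, t0=float(t[0]))
        return Record(rid, ppg, resp)

    # generic_csv
    cols = list(df.columns)
    t0 = 0.0
    if "t" in cols:
        t = df["t"].to_numpy(float)
        fs = _fs_from_time(t)
        t0 = float(t[0])
        cols.remove("t")
    elif fs_hint is not None:
        fs = float(fs_hint)
    else:
        raise FormatError("generic CSV needs a time column 't' or an fs_hint")
    if not cols:
        raise FormatError("generic CSV has no channel columns")
    ppg = UniformSignal(df[cols[0]].to_numpy(float), fs=fs, t0=t0)
    resp = None
    if len(cols) > 1:
        resp = UniformSignal(df[cols[1]].to_numpy(float), fs=fs, t0=t0)
    return Record(rid, ppg, resp)


def _read_wfdb(path: Path, rid: str) -> Record:
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'wfdb' dialect requires the optional wfdb package; "
            "use a CSV dialect instead"
        ) from exc
    rec = wfdb.rdrecord(str(path.with_suffix("")))  # pragma: no cover
    names = [n.strip().upper() for n in rec.sig_name]  # pragma: no cover
    sig = rec.p_signal  # pragma: no cover
    fs = float(rec.fs)  # pragma: no cover

    def channel(name: str) -> UniformSignal | None:  # pragma: no cover
        if name in names:
            return UniformSignal(sig[:, names.index(name)], fs=fs)
        return None

    ppg = channel("PLETH")  # pragma: no cover
    if ppg is None:  # pragma: no cover
        raise FormatError("WFDB record has no PLETH channel")
    return Record(rid, ppg, channel("RESP"))  # pragma: no cover


def write_record(rec: Record, path: str | Path) -> None:
    """Write a record as a generic CSV (columns ``t``, ``ppg``[, ``resp``]).

    Values are written with ``repr`` precision so a read round-trips exactly.
    """
    cols: dict[str, np.ndarray] = {"t": rec.ppg.times, "ppg": rec.ppg.values}
    if rec.resp is not None:
        cols["resp"] = rec.resp.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_record(
    rec: Record, window_s: float = 60.0, max_segments: int | None = None
) -> list[Segment]:
    """Partition a record into non-overlapping, contiguous windows.

    Windows are half-open ``[k*W, (k+1)*W)`` of ``window_s`` seconds; the
    trailing remainder that does not fill a full window is discarded.  A
    record shorter than one window yields an empty list with a warning.
    """
    fs = rec.ppg.fs
    win = int(round(window_s * fs))
    n_seg = rec.ppg.n // win
    if max_segments is not None:
        n_seg = min(n_seg, max_segments)
    if n_seg == 0:
        warnings.warn(
            f"record {rec.record_id!r} is shorter than one {window_s}-s window",
            stacklevel=2,
        )
        return []

    out: list[Segment] = []
    for k in range(n_seg):
        sl = slice(k * win, (k + 1) * win)
        t0 = rec.ppg.t0 + (k * win) / fs
        ppg = UniformSignal(rec.ppg.values[sl], fs=fs, t0=t0)
        resp = None
        if rec.resp is not None:
            rfs = rec.resp.fs
            rwin = int(round(window_s * rfs))
            rsl = slice(k * rwin, (k + 1) * rwin)
            resp = UniformSignal(rec.resp.values[rsl], fs=rfs, t0=t0)
        out.append(Segment(rec.record_id, k, ppg, resp, duration_s=win / fs))
    return out
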