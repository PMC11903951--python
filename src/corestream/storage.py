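"""Recording persistence: the CSV dialect and the SD-card binary log format.

CSV dialect (fixed so golden-file comparisons are bit-exact): comma
separated, UTF-8, LF line endings; acquisition metadata as ``#``-prefixed
``key=value`` comment lines before the header row.  Columns are ``NSeq, I1,
I2, O1, O2`` followed by one ``<CH>_raw`` column per active channel and —
unless the recording is raw-only — one ``<CH>_mv`` column per channel.
Integers are written verbatim; millivolt values with 6 significant digits.
Lost frames are absent rows (never zero-filled or interpolated); timestamp
reconstruction must consult NSeq.

SD binary log: a 16-byte header (magic ``SCIS``, u8 format version, u8
channel mask, u16-LE sampling rate, u16-LE vref mV, 6 reserved bytes)
followed by back-to-back encoded frames in the canonical codec layout.
This layout is canonical for this package, not claimed compatible with any
device's card format.  Only the two on-device acquisition modes are
writable: all six internal channels at 2000 Hz, or all internal plus one or
two external channels at 100 Hz.
"""

from __future__ import annotations

import csv
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, NamedTuple, Optional, Union

from .errors import CrcError, FormatError, ParseError
from .frames import ChannelConfig, DataFrame, decode_frame, encode_frame, frame_size

__all__ = [
    "Row",
    "Recording",
    "SdSummary",
    "write_csv",
    "read_csv",
    "write_sd",
    "read_sd",
    "convert_sd_to_csv",
    "SD_MAGIC",
    "SD_VERSION",
    "SD_HEADER_LEN",
]

SD_MAGIC = b"SCIS"
SD_VERSION = 1
SD_HEADER_LEN = 16
_SD_STRUCT = struct.Struct("<4sBBHH6x")

Dest = Union[str, Path, IO[str]]


class Row(NamedTuple):
    """One acquired frame: sequence number, digital bits, per-channel values."""

    nseq: int
    i1: int
    i2: int
    o1: int
    o2: int
    raw: tuple  # raw levels, in the recording's channel order
    mv: Optional[tuple] = None  # millivolts, same order; None when raw-only


@dataclass
class Recording:
    """An acquisition session: metadata plus one row per received frame.

    Row width is constant within a recording; rows appear in reception
    order with sequence-number gaps preserved.
    """

    channels: ChannelConfig
    sampling_rate_hz: int = 1000
    vref_mv: float = 1100.0
    attenuation: float = 1.0
    start_time: str = ""
    firmware_version: str = ""
    raw_only: bool = False
    truncated: bool = False
    metadata_missing: bool = False
    rows: list = field(default_factory=list)
    extra_columns: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def timestamps(self, drift_model=None):
        """Per-row timestamps reconstructed as NSeq / SR, in seconds.

        The streaming protocol carries no clock, so timestamps assume each
        frame is spaced by exactly 1/SR; wraparound of the 12-bit NSeq is
        unwrapped by detecting backward jumps.  Passing a fitted
        :class:`~corestream.timing.DriftModel` additionally applies the
        linear drift compensation ``t' = t + |f(t)|``.
        """
        import numpy as np

        seqs = np.array([r.nseq for r in self.rows], dtype=np.int64)
        if len(seqs):
            wraps = np.concatenate([[0], np.cumsum(np.diff(seqs) < 0)])
            seqs = seqs + 4096 * wraps
        t = seqs / float(self.sampling_rate_hz)
        if drift_model is not None:
            from .timing import compensate_timestamps

            t = compensate_timestamps(t, drift_model)
        return t


def _columns(recording: Recording) -> list[str]:
    cols = ["NSeq", "I1", "I2", "O1", "O2"]
    cols += [f"{ch}_raw" for ch in recording.channels.channels]
    if not recording.raw_only:
        cols += [f"{ch}_mv" for ch in recording.channels.channels]
    cols += list(recording.extra_columns)
    return cols


def _open_dest(dest: Dest, mode: str):
    if isinstance(dest, (str, Path)):
        return open(dest, mode, newline="" if "b" not in mode else None), True
    return dest, False


def write_csv(recording: Recording, dest: Dest) -> int:
    """Write the recording; returns the number of data rows written."""
    fh, close = _open_dest(dest, "w")
    try:
        meta = {
            "channels": ",".join(recording.channels.channels),
            "sampling_rate_hz": recording.sampling_rate_hz,
            "vref_mv": f"{recording.vref_mv:g}",
            "attenuation": f"{recording.attenuation:g}",
            "start_time": recording.start_time,
            "firmware_version": recording.firmware_version,
            "raw_only": int(recording.raw_only),
        }
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_columns(recording))
        count = 0
        for row in recording.rows:
            out = [row.nseq, row.i1, row.i2, row.o1, row.o2]
            out += [int(v) for v in row.raw]
            if not recording.raw_only:
                out += [format(v, ".6g") for v in row.mv]
            for name in recording.extra_columns:
                out.append(recording.extra_columns[name][count])
            writer.writerow(out)
            count += 1
        return count
    finally:
        if close:
            fh.close()


def read_csv(source: Dest) -> Recording:
    """Inverse of :func:`write_csv`; tolerates missing metadata comments.

    A file without the ``#`` metadata block is read with default metadata
    and flagged via ``metadata_missing``.  Unknown extra columns are
    preserved opaquely (as strings) in ``extra_columns``.
    """
    fh, close = _open_dest(source, "r")
    try:
        meta: dict[str, str] = {}
        header = None
        line_no = 0
        lines = iter(fh)
        for line in lines:
            line_no += 1
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, value = body.split("=", 1)
                    meta[key.strip()] = value
                continue
            header = line
            break
        if header is None:
            raise ParseError("no header row found", line_no)
        columns = next(csv.reader(io.StringIO(header)))
        base = ["NSeq", "I1", "I2", "O1", "O2"]
        if columns[: len(base)] != base:
            raise ParseError(
                f"header must start with {','.join(base)}; got {header!r}", line_no
            )
        raw_cols = [c for c in columns if c.endswith("_raw")]
        mv_cols = [c for c in columns if c.endswith("_mv")]
        known = set(base) | set(raw_cols) | set(mv_cols)
        extra_names = [c for c in columns if c not in known]
        channels = ChannelConfig.from_channels([c[:-4] for c in raw_cols])
        if mv_cols and [c[:-3] for c in mv_cols] != list(channels.channels):
            raise ParseError("mV columns do not match raw columns", line_no)

        rec = Recording(
            channels=channels,
            sampling_rate_hz=int(meta.get("sampling_rate_hz", 1000)),
            vref_mv=float(meta.get("vref_mv", 1100.0)),
            attenuation=float(meta.get("attenuation", 1.0)),
            start_time=meta.get("start_time", ""),
            firmware_version=meta.get("firmware_version", ""),
            raw_only=not mv_cols,
            metadata_missing="sampling_rate_hz" not in meta,
            extra_columns={name: [] for name in extra_names},
        )
        idx = {name: columns.index(name) for name in columns}
        n_ch = len(raw_cols)
        for line in lines:
            line_no += 1
            if not line.strip():
                continue
            values = next(csv.reader(io.StringIO(line)))
            if len(values) != len(columns):
                raise ParseError(
                    f"expected {len(columns)} fields, got {len(values)}", line_no
                )
            try:
                raw = tuple(int(values[idx[c]]) for c in raw_cols)
                mv = (
                    tuple(float(values[idx[c]]) for c in mv_cols) if mv_cols else None
                )
                rec.rows.append(
                    Row(
                        nseq=int(values[0]),
                        i1=int(values[1]),
                        i2=int(values[2]),
                        o1=int(values[3]),
                        o2=int(values[4]),
                        raw=raw,
                        mv=mv,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), line_no)
            for name in extra_names:
                rec.extra_columns[name].append(values[idx[name]])
        return rec
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# SD binary log


class SdSummary(NamedTuple):
    rows: int
    crc_failures: int
    truncated: bool


def _sd_mode_ok(channels: ChannelConfig, sr: int) -> bool:
    all_internal = len(channels.internal) == 6
    if all_internal and not channels.external and sr == 2000:
        return True
    if all_internal and channels.external and sr == 100:
        return True
    return False


def write_sd(recording: Recording, dest: Union[str, Path, IO[bytes]]) -> int:
    """Write an SD binary log; returns the number of frames written.

    Only the two supported on-card acquisition modes are accepted: all six
    internal channels at 2000 Hz, or all internal plus one/two external
    channels at 100 Hz.
    """
    if not _sd_mode_ok(recording.channels, recording.sampling_rate_hz):
        raise FormatError(
            "SD logging supports only: 6 internal @ 2000 Hz, or "
            "6 internal + 1-2 external @ 100 Hz"
        )
    header = _SD_STRUCT.pack(
        SD_MAGIC,
        SD_VERSION,
        recording.channels.to_mask(),
        recording.sampling_rate_hz,
        int(round(recording.vref_mv)),
    )
    fh, close = _open_dest(dest, "wb")
    try:
        fh.write(header)
        n_int = len(recording.channels.internal)
        for row in recording.rows:
            frame = DataFrame(
                seq=row.nseq % 4096,
                internal=dict(zip(recording.channels.internal, row.raw[:n_int])),
                external=dict(zip(recording.channels.external, row.raw[n_int:])),
                i1=row.i1,
                i2=row.i2,
                o1=row.o1,
                o2=row.o2,
            )
            fh.write(encode_frame(frame, recording.channels))
        return len(recording.rows)
    finally:
        if close:
            fh.close()


def read_sd(source: Union[str, Path, IO[bytes]]) -> tuple[Recording, SdSummary]:
    """Decode an SD binary log into a raw-only Recording.

    Frames failing their CRC are skipped and counted; a truncated trailing
    frame stops conversion at the last whole frame and sets the truncation
    flag.
    """
    fh, close = _open_dest(source, "rb")
    try:
        blob = fh.read()
    finally:
        if close:
            fh.close()
    if len(blob) < SD_HEADER_LEN:
        raise FormatError(f"file too short for a {SD_HEADER_LEN}-byte header")
    magic, version, mask, sr, vref = _SD_STRUCT.unpack(blob[:SD_HEADER_LEN])
    if magic != SD_MAGIC:
        raise FormatError(f"bad magic {magic!r}")
    if version != SD_VERSION:
        raise FormatError(f"unsupported format version {version}")
    channels = ChannelConfig.from_mask(mask)
    fsize = frame_size(channels)
    body = blob[SD_HEADER_LEN:]
    n_whole, remainder = divmod(len(body), fsize)
    rec = Recording(
        channels=channels,
        sampling_rate_hz=sr,
        vref_mv=float(vref),
        raw_only=True,
        truncated=remainder > 0,
    )
    crc_failures = 0
    for i in range(n_whole):
        chunk = body[i * fsize : (i + 1) * fsize]
        try:
            frame = decode_frame(chunk, channels)
        except CrcError:
            crc_failures += 1
            continue
        raw = tuple(frame.internal[c] for c in channels.internal) + tuple(
            frame.external[c] for c in channels.external
        )
        rec.rows.append(
            Row(frame.seq, frame.i1, frame.i2, frame.o1, frame.o2, raw, None)
        )
    return rec, SdSummary(len(rec.rows), crc_failures, remainder > 0)


def convert_sd_to_csv(source, dest: Dest) -> SdSummary:
    """Decode an SD binary log and write it in the CSV dialect."""
    rec, summary = read_sd(source)
    write_csv(rec, dest)
    return summary
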