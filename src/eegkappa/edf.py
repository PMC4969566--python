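"""Compact EDF (European Data Format) codec.

EDF stores an ASCII header (256 bytes plus 256 per signal, field-major)
followed by data records of little-endian int16 samples that map linearly
onto a physical range. This codec reads and writes that layout directly so
the physical unit label of each channel survives a round trip untouched —
kappa values are unit-dependent, so the reader must hand back samples in
the file's native units rather than rescaling to SI.

The writer targets test fixtures and `simulate` output: one or more
channels at a common sampling rate, whole data records only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

_DIG_MIN = -32768
_DIG_MAX = 32767


@dataclass(frozen=True)
class EdfChannel:
    label: str
    samples: np.ndarray  # physical units
    units: str
    fs: float


def _field(value: str, width: int) -> bytes:
    raw = value.encode("ascii", errors="replace")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def write_edf(
    path,
    channels: list[tuple[str, np.ndarray]],
    fs: float,
    units: str = "mV",
    record_duration_s: float = 1.0,
    patient_id: str = "X",
    recording_id: str = "Startdate 01-JAN-2000 synthetic",
) -> None:
    """Write channels sharing one sampling rate to an EDF file.

    The sample count must be a whole number of data records
    (``fs * record_duration_s`` samples each). Amplitudes are quantized to
    the 16-bit digital range spanning each channel's physical min/max.
    """
    if not channels:
        raise ParameterError("write_edf requires at least one channel")
    spr = fs * record_duration_s
    if abs(spr - round(spr)) > 1e-9 or round(spr) < 1:
        raise ParameterError(
            f"fs * record_duration_s must be a positive integer, got {spr}"
        )
    spr = int(round(spr))
    n = len(channels[0][1])
    if any(len(sig) != n for _, sig in channels):
        raise ParameterError("all channels must have equal length")
    if n % spr != 0:
        raise ParameterError(
            f"sample count {n} is not a whole number of {spr}-sample records"
        )
    n_records = n // spr
    ns = len(channels)

    phys_ranges = []
    dig_blocks = []
    for _, sig in channels:
        sig = np.asarray(sig, dtype=float)
        if not np.all(np.isfinite(sig)):
            raise ParameterError("non-finite samples cannot be written to EDF")
        pmin, pmax = float(sig.min()), float(sig.max())
        if pmax == pmin:  # constant channel: open a token range
            pmax = pmin + 1.0
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((sig - pmin) * scale + _DIG_MIN).astype("<i2")
        phys_ranges.append((pmin, pmax))
        dig_blocks.append(dig)

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(f"{record_duration_s:g}", 8),
            _field(str(ns), 4),
        ]
    )
    # signal header block is field-major: all labels, then all transducers, ...
    per_signal = [
        b"".join(_field(label, 16) for label, _ in channels),
        b"".join(_field("", 80) for _ in channels),
        b"".join(_field(units, 8) for _ in channels),
        b"".join(_field(f"{pmin:.8g}"[:8], 8) for pmin, _ in phys_ranges),
        b"".join(_field(f"{pmax:.8g}"[:8], 8) for _, pmax in phys_ranges),
        b"".join(_field(str(_DIG_MIN), 8) for _ in channels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in channels),
        b"".join(_field("", 80) for _ in channels),
        b"".join(_field(str(spr), 8) for _ in channels),
        b"".join(_field("", 32) for _ in channels),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_records):
            for dig in dig_blocks:
                fh.write(dig[r * spr : (r + 1) * spr].tobytes())


def _read_fields(buf: bytes, width: int, count: int, offset: int) -> list[str]:
    return [
        buf[offset + i * width : offset + (i + 1) * width].decode("ascii").strip()
        for i in range(count)
    ]


def read_edf(path, channel: str | int = 0) -> EdfChannel:
    """Read one channel from an EDF/EDF+ file, in its native physical units."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(256)
            if len(head) < 256:
                raise InputError(f"{path}: truncated EDF header")
            try:
                n_records = int(head[236:244].decode("ascii").strip())
                record_dur = float(head[244:252].decode("ascii").strip())
                ns = int(head[252:256].decode("ascii").strip())
            except ValueError as exc:
                raise InputError(f"{path}: malformed EDF header") from exc
            sig_head = fh.read(256 * ns)
            data = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc

    labels = _read_fields(sig_head, 16, ns, 0)
    units = _read_fields(sig_head, 8, ns, ns * (16 + 80))
    off = ns * (16 + 80 + 8)
    phys_min = [float(v) for v in _read_fields(sig_head, 8, ns, off)]
    phys_max = [float(v) for v in _read_fields(sig_head, 8, ns, off + 8 * ns)]
    dig_min = [int(v) for v in _read_fields(sig_head, 8, ns, off + 16 * ns)]
    dig_max = [int(v) for v in _read_fields(sig_head, 8, ns, off + 24 * ns)]
    spr = [
        int(v)
        for v in _read_fields(sig_head, 8, ns, off + 32 * ns + 80 * ns)
    ]

    if isinstance(channel, int):
        if not 0 <= channel < ns:
            raise InputError(f"{path}: channel index {channel} out of range (ns={ns})")
        idx = channel
    else:
        try:
            idx = labels.index(channel)
        except ValueError as exc:
            raise InputError(
                f"{path}: no channel named {channel!r}; available: {labels}"
            ) from exc

    rec_len = sum(spr)
    raw = np.frombuffer(data, dtype="<i2", count=n_records * rec_len)
    raw = raw.reshape(n_records, rec_len)
    start = sum(spr[:idx])
    dig = raw[:, start : start + spr[idx]].reshape(-1).astype(float)

    dspan = dig_max[idx] - dig_min[idx]
    if dspan == 0:
        raise InputError(f"{path}: channel {labels[idx]!r} has zero digital span")
    gain = (phys_max[idx] - phys_min[idx]) / dspan
    phys = (dig - dig_min[idx]) * gain + phys_min[idx]
    if record_dur <= 0:
        raise InputError(f"{path}: non-positive record duration")
    return EdfChannel(
        label=labels[idx],
        samples=phys,
        units=units[idx],
        fs=spr[idx] / record_dur,
    )
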