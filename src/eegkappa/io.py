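"""Recording input and epoch segmentation.

Voltage recordings are read from EDF/EDF+ (the polysomnography standard)
or from a two-column CSV dialect (``time_s,voltage``) that keeps the whole
pipeline testable with plain-text fixtures. Stage annotations are a TSV of
half-open ``[start_s, end_s)`` intervals with a free-text stage label, the
shape of a clinical hypnogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from .errors import InputError, ParameterError

log = logging.getLogger(__name__)

#: relative tolerance for declaring a CSV time base uniform
CSV_UNIFORMITY_RTOL = 1e-4


@dataclass(frozen=True)
class VoltageSegment:
    """A labeled stretch of single-channel voltage samples.

    Samples stay in the recording's native physical units; kappa is the
    log of a dimensional voltage difference, so the unit label travels
    with the data and into every report.
    """

    samples: np.ndarray
    fs: float
    units: str = "mV"
    subject_id: str = ""
    state: str = ""
    segment_id: str = ""
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterError("a segment needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InputError("segment contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StageAnnotation:
    """Non-overlapping half-open intervals ``(start_s, end_s, stage)``."""

    intervals: tuple[tuple[float, float, str], ...] = field(default_factory=tuple)

    def __post_init__(self):
        ivs = tuple(
            (float(a), float(b), str(lab)) for a, b, lab in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        for a, b, _ in ivs:
            if not b > a:
                raise InputError(f"annotation interval [{a}, {b}) is empty or reversed")
        ordered = sorted(ivs)
        for (a0, b0, _), (a1, _, _) in zip(ordered, ordered[1:]):
            if a1 < b0:
                raise InputError(
                    f"annotation intervals overlap near t={a1:g} s"
                )

    def __len__(self) -> int:
        return len(self.intervals)


def read_annotations(path) -> StageAnnotation:
    """Read a ``start_s<TAB>end_s<TAB>stage`` TSV (header optional)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), parts[2]))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise InputError(f"{path}:{lineno}: non-numeric interval bounds")
    if not rows:
        raise InputError(f"{path}: no annotation intervals")
    return StageAnnotation(intervals=tuple(rows))


def write_annotations(ann: StageAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tstage\n")
        for a, b, lab in ann.intervals:
            fh.write(f"{a:.6g}\t{b:.6g}\t{lab}\n")


def _read_csv_recording(path: Path, units: str) -> VoltageSegment:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if list(df.columns[:2]) != ["time_s", "voltage"]:
        raise InputError(
            f"{path}: expected header 'time_s,voltage', got {list(df.columns[:2])}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InputError(f"{path}: fewer than 2 samples")
    if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
        raise InputError(f"{path}: non-finite samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise InputError(f"{path}: time column is not increasing")
    if np.max(np.abs(dt - med)) > CSV_UNIFORMITY_RTOL * med:
        raise InputError(f"{path}: non-uniform time base")
    fs = 1.0 / med
    if abs(fs - round(fs)) < 1e-6 * fs:  # undo decimal-printing jitter
        fs = float(round(fs))
    return VoltageSegment(
        samples=v,
        fs=fs,
        units=units,
        subject_id=path.stem,
        segment_id=path.stem,
        t0=float(t[0]),
    )


def read_recording(path, channel: str | int = 0, units: str = "mV") -> VoltageSegment:
    """Read a full-length recording as one :class:`VoltageSegment`.

    EDF files supply their own sampling rate and physical unit label;
    for CSV the rate is inferred from the median time step (which must be
    uniform to one part in 10^4) and ``units`` labels the voltage column.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"recording not found: {path}")
    if path.suffix.lower() == ".edf":
        ch = edf.read_edf(path, channel)
        if not np.all(np.isfinite(ch.samples)):
            raise InputError(f"{path}: non-finite samples")
        return VoltageSegment(
            samples=ch.samples,
            fs=ch.fs,
            units=ch.units or "arb",
            subject_id=path.stem,
            segment_id=path.stem,
            t0=0.0,
        )
    return _read_csv_recording(path, units)


def write_csv_recording(seg: VoltageSegment, path) -> None:
    """Write a segment in the two-column CSV dialect, time at µs precision."""
    t = seg.t0 + np.arange(seg.n_samples) / seg.fs
    df = pd.DataFrame({"time_s": t, "voltage": seg.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def segment_recording(
    rec: VoltageSegment, ann: StageAnnotation, epoch_s: float = 60.0
) -> list[VoltageSegment]:
    """Tile each annotated interval into fixed-length labeled epochs.

    Epochs start at the interval start, do not overlap, and trailing
    partial epochs are dropped; every output has exactly
    ``round(epoch_s * fs)`` samples and carries the interval's stage label
    plus a sequential segment id.
    """
    if epoch_s <= 0:
        raise ParameterError(f"epoch_s must be positive, got {epoch_s}")
    if len(ann) == 0:
        raise InputError("empty annotation")
    epoch_n = int(round(epoch_s * rec.fs))
    if epoch_n < 2:
        raise ParameterError("epoch shorter than 2 samples")
    rec_end = rec.t0 + rec.n_samples / rec.fs
    out: list[VoltageSegment] = []
    counter = 0
    for start, end, stage in ann.intervals:
        if start < rec.t0 - 0.5 / rec.fs or end > rec_end + 0.5 / rec.fs:
            raise InputError(
                f"annotation [{start:g}, {end:g}) s exceeds recording "
                f"[{rec.t0:g}, {rec_end:g}) s"
            )
        n_epochs = int(np.floor((end - start) / epoch_s + 1e-9))
        i0 = int(round((start - rec.t0) * rec.fs))
        for k in range(n_epochs):
            a = i0 + k * epoch_n
            b = a + epoch_n
            if b > rec.n_samples:
                break
            out.append(
                replace(
                    rec,
                    samples=rec.samples[a:b],
                    state=stage,
                    segment_id=f"seg{counter:03d}",
                    t0=rec.t0 + a / rec.fs,
                )
            )
            counter += 1
    if not out:
        log.warning(
            "no interval holds a complete %g s epoch; returning no segments", epoch_s
        )
    return out
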