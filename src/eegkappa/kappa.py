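"""Per-instant information-transfer constants and segment summaries.

The core feature is the instantaneous information-transfer constant

    kappa(t; dt) = ln|V(t + dt) - V(t)| / ln(dt),    dt in seconds,

the exponent that would relate a voltage change to the elapsed time under
a power law |dV| ~ dt^kappa. Instants where V(t + dt) = V(t) have no
defined log difference and are excluded and counted, never imputed.
kappa depends on the voltage unit (the numerator is the log of a
dimensional quantity): rescaling voltages by a factor a shifts every
kappa by ln(a)/ln(dt), so summaries always carry the unit label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .io import VoltageSegment

#: the canonical decade grid of evaluation time scales, in seconds
DEFAULT_DELTA_TS: tuple[float, ...] = (0.004, 0.04, 0.4, 4.0)

#: kappa below this is read as "low information transfer"
DEFAULT_LOW_THRESHOLD = 0.2

#: relative lag-rounding error beyond which fs*delta_t is rejected
LAG_ROUNDING_RTOL = 1e-6

#: E[ln|Z|] for standard normal Z = -(euler_gamma + ln 2)/2
E_LN_ABS_STD_NORMAL = -(np.euler_gamma + math.log(2.0)) / 2.0


@dataclass(frozen=True)
class KappaSeries:
    """kappa at every retained instant of one segment, at one time scale."""

    delta_t_s: float
    lag_samples: int
    values: np.ndarray
    n_total: int
    n_excluded: int
    subject_id: str = ""
    state: str = ""
    segment_id: str = ""
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        assert len(self.values) == self.n_total - self.n_excluded


@dataclass(frozen=True)
class SegmentSummary:
    """Mean kappa and low-information-transfer fraction for one segment/scale."""

    kappa_avg: float
    low_it_fraction: float
    n_values: int
    n_excluded: int
    delta_t_s: float
    subject_id: str = ""
    state: str = ""
    segment_id: str = ""
    units: str = ""


def kappa_series(
    seg: VoltageSegment, delta_t_s: float, *, allow_lag_rounding: bool = False
) -> KappaSeries:
    """Compute kappa at every instant of ``seg`` for one time interval.

    ``delta_t_s`` is in seconds (the log in the denominator is taken of
    seconds); the sample lag is ``round(delta_t_s * fs)`` and must round
    exactly (to 1e-6 relative) unless ``allow_lag_rounding`` is set.
    """
    if delta_t_s <= 0:
        raise ParameterError(f"delta_t must be positive, got {delta_t_s} s")
    if delta_t_s == 1.0:
        raise ParameterError("delta_t = 1 s is invalid: ln(delta_t) = 0")
    exact = delta_t_s * seg.fs
    lag = int(round(exact))
    if lag < 1:
        raise ParameterError(
            f"delta_t = {delta_t_s} s rounds to a zero-sample lag at fs = {seg.fs} Hz"
        )
    if abs(lag - exact) > LAG_ROUNDING_RTOL * exact and not allow_lag_rounding:
        raise ParameterError(
            f"delta_t = {delta_t_s} s is {exact} samples at fs = {seg.fs} Hz; "
            "pass allow_lag_rounding to round to the nearest sample"
        )
    v = seg.samples
    if lag >= v.size:
        raise ParameterError(
            f"lag of {lag} samples is not shorter than the segment ({v.size} samples)"
        )
    dv = np.abs(v[lag:] - v[:-lag])
    retained = dv > 0.0
    values = np.log(dv[retained]) / math.log(delta_t_s)
    n_total = v.size - lag
    return KappaSeries(
        delta_t_s=float(delta_t_s),
        lag_samples=lag,
        values=values,
        n_total=n_total,
        n_excluded=int(n_total - retained.sum()),
        subject_id=seg.subject_id,
        state=seg.state,
        segment_id=seg.segment_id,
        units=seg.units,
    )


def kappa_summary(
    ks: KappaSeries, low_threshold: float = DEFAULT_LOW_THRESHOLD
) -> SegmentSummary:
    """Reduce a kappa series to its mean and low-transfer fraction.

    The mean runs over retained values only — an instant excluded for a
    zero voltage difference contributes nothing to the average rather than
    an implicit zero — and the excluded count is reported alongside.
    """
    if ks.values.size == 0:
        raise DegenerateDataError(
            f"degenerate segment {ks.segment_id!r}: all {ks.n_total} instants "
            f"excluded at delta_t = {ks.delta_t_s} s"
        )
    values = ks.values
    return SegmentSummary(
        kappa_avg=float(values.mean()),
        low_it_fraction=float((values < low_threshold).mean()),
        n_values=int(values.size),
        n_excluded=ks.n_excluded,
        delta_t_s=ks.delta_t_s,
        subject_id=ks.subject_id,
        state=ks.state,
        segment_id=ks.segment_id,
        units=ks.units,
    )


def multiscale_summaries(
    seg: VoltageSegment,
    delta_ts: tuple[float, ...] = DEFAULT_DELTA_TS,
    low_threshold: float = DEFAULT_LOW_THRESHOLD,
    *,
    allow_lag_rounding: bool = False,
) -> list[SegmentSummary]:
    """One :class:`SegmentSummary` per time scale, errors tagged by scale."""
    out = []
    for dt in delta_ts:
        try:
            ks = kappa_series(seg, dt, allow_lag_rounding=allow_lag_rounding)
            out.append(kappa_summary(ks, low_threshold))
        except (ParameterError, DegenerateDataError) as exc:
            raise type(exc)(f"at delta_t = {dt} s: {exc}") from exc
    return out


def summaries_to_frame(summaries: list[SegmentSummary]) -> pd.DataFrame:
    """Long per-segment summary table, one row per (segment, delta_t)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "state": s.state,
                "segment_id": s.segment_id,
                "delta_t_s": s.delta_t_s,
                "kappa_avg": s.kappa_avg,
                "low_it_fraction": s.low_it_fraction,
                "n_values": s.n_values,
                "n_excluded": s.n_excluded,
                "units": s.units,
            }
            for s in summaries
        ]
    )


def expected_kappa_gaussian_increment(
    increment_sd: float, delta_t_s: float
) -> float:
    """E[kappa] when V(t+dt)-V(t) ~ N(0, increment_sd^2).

    E[ln|dV|] = ln(increment_sd) + E[ln|Z|] with E[ln|Z|] = -(gamma+ln2)/2;
    closed-form anchor for white-noise and fBm surrogates.
    """
    if increment_sd <= 0:
        raise ParameterError("increment_sd must be positive")
    return (math.log(increment_sd) + E_LN_ABS_STD_NORMAL) / math.log(delta_t_s)


def expected_kappa_fbm(hurst: float, sigma: float, delta_t_s: float) -> float:
    """E[kappa] for fractional Brownian motion with Var[dV] = sigma^2 dt^(2H).

    Equals H + (ln(sigma) + E[ln|Z|]) / ln(dt): the Hurst exponent plus a
    unit/scale offset that vanishes as |ln dt| grows.
    """
    return hurst + (math.log(sigma) + E_LN_ABS_STD_NORMAL) / math.log(delta_t_s)


def expected_kappa_white_noise(sigma: float, delta_t_s: float) -> float:
    """E[kappa] for iid N(0, sigma^2) samples: dV ~ N(0, 2 sigma^2)."""
    return expected_kappa_gaussian_increment(math.sqrt(2.0) * sigma, delta_t_s)


def hurst_regression(
    seg: VoltageSegment, delta_ts: tuple[float, ...] = DEFAULT_DELTA_TS
) -> float:
    """Scaling exponent from regressing mean ln|dV| on ln(dt).

    Since kappa_avg = mean(ln|dV|) / ln(dt) at each scale, the regression
    slope across scales is the Hurst exponent of a self-similar signal
    (|dV| ~ dt^H); the amplitude offset lands in the intercept.
    """
    if len(delta_ts) < 2:
        raise ParameterError("Hurst regression needs at least 2 time scales")
    log_dt, mean_log_dv = [], []
    for dt in delta_ts:
        ks = kappa_series(seg, dt)
        if ks.values.size == 0:
            raise DegenerateDataError(f"all instants excluded at delta_t = {dt} s")
        log_dt.append(math.log(dt))
        mean_log_dv.append(float(ks.values.mean()) * math.log(dt))
    slope, _ = np.polyfit(log_dt, mean_log_dv, 1)
    return float(slope)
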