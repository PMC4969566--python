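"""Periodicity of the kappa-value probability density.

A segment's kappa sample often shows comb-like structure: preferred kappa
magnitudes enhanced at roughly even spacing. To quantify it, the kappa
sample is turned into a kernel density estimate on an even grid, the
mean-subtracted density is treated as a signal over the kappa axis, and
its normalized Lomb-Scargle periodogram is summed over frequencies whose
peak significance clears p <= p_cut under the classical
M-independent-frequencies null, with M taken as twice the number of PDF
grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .errors import DegenerateDataError, ParameterError

DEFAULT_N_GRID = 512
DEFAULT_OVERSAMPLE = 4.0
DEFAULT_HIFAC = 1.0
DEFAULT_P_CUT = 0.01
MIN_PDF_SAMPLE = 10


@dataclass(frozen=True)
class PdfEstimate:
    """Gaussian-kernel density of a kappa sample on an even grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def n_grid(self) -> int:
        return self.grid.size

    @property
    def span(self) -> float:
        return float(self.grid[-1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class PeriodogramResult:
    """Normalized Lomb-Scargle power over the kappa-frequency grid.

    ``frequencies`` are in cycles per unit kappa. Threshold fields are
    ``None`` until :func:`significant_power` fills them.
    """

    frequencies: np.ndarray
    power: np.ndarray
    m_independent: int | None = None
    z_threshold: float | None = None
    significant_power: float | None = None

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[np.argmax(self.power)])


def rule_of_thumb_bandwidth(values: np.ndarray) -> float:
    """0.9 * min(SD, IQR/1.34) * n^(-1/5), SD falling back when IQR is 0."""
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("sample has zero spread; no density estimate")
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-0.2)


def estimate_pdf(values: np.ndarray, n_grid: int = DEFAULT_N_GRID) -> PdfEstimate:
    """Gaussian KDE on ``n_grid`` even points spanning data +/- 3 bandwidths."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < MIN_PDF_SAMPLE:
        raise DegenerateDataError(
            f"need at least {MIN_PDF_SAMPLE} finite values, got {values.size}"
        )
    if n_grid < 8:
        raise ParameterError(f"n_grid must be at least 8, got {n_grid}")
    bw = rule_of_thumb_bandwidth(values)
    # gaussian_kde's factor multiplies the data SD (ddof=1)
    kde = stats.gaussian_kde(values, bw_method=bw / values.std(ddof=1))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    density = kde(grid)
    return PdfEstimate(grid=grid, density=density, bandwidth=bw)


def lomb_scargle(
    pdf: PdfEstimate,
    oversample: float = DEFAULT_OVERSAMPLE,
    hifac: float = DEFAULT_HIFAC,
) -> PeriodogramResult:
    """Classical variance-normalized Lomb-Scargle periodogram of the density.

    The mean-subtracted density is the signal and the kappa grid the
    abscissa; frequencies run from 1/(span*oversample) up to
    hifac * n_grid / (2*span) in steps of 1/(span*oversample). Under a
    Gaussian white-noise signal each power is asymptotically Exp(1).
    """
    if oversample < 1:
        raise ParameterError(f"oversample must be >= 1, got {oversample}")
    if hifac <= 0:
        raise ParameterError(f"hifac must be positive, got {hifac}")
    y = pdf.density - pdf.density.mean()
    var = float(y.var(ddof=1))
    if var == 0.0:
        raise DegenerateDataError("constant density: zero variance after centering")
    span = pdf.span
    df = 1.0 / (span * oversample)
    f_max = hifac * pdf.n_grid / (2.0 * span)
    freqs = np.arange(df, f_max + 0.5 * df, df)
    raw = signal.lombscargle(pdf.grid, y, 2.0 * math.pi * freqs)
    return PeriodogramResult(frequencies=freqs, power=raw / var)


def significant_power(
    pg: PeriodogramResult, pdf_points: int, p_cut: float = DEFAULT_P_CUT
) -> PeriodogramResult:
    """Fill threshold fields: sum power over peaks significant at ``p_cut``.

    The false-alarm level solves p = 1 - (1 - e^(-z))^M for
    M = 2 * pdf_points independent frequencies (a deliberately generous
    count); power exactly at the threshold counts as significant.
    """
    if not 0.0 < p_cut < 1.0:
        raise ParameterError(f"p_cut must be in (0, 1), got {p_cut}")
    if pdf_points < 1:
        raise ParameterError("pdf_points must be positive")
    m = 2 * int(pdf_points)
    z = -math.log(1.0 - (1.0 - p_cut) ** (1.0 / m))
    sig = float(pg.power[pg.power >= z].sum())
    return replace(pg, m_independent=m, z_threshold=z, significant_power=sig)


def kappa_pdf_power(
    values: np.ndarray,
    n_grid: int = DEFAULT_N_GRID,
    oversample: float = DEFAULT_OVERSAMPLE,
    hifac: float = DEFAULT_HIFAC,
    p_cut: float = DEFAULT_P_CUT,
) -> tuple[PdfEstimate, PeriodogramResult]:
    """Full chain: kappa sample -> PDF -> periodogram -> significant power."""
    pdf = estimate_pdf(values, n_grid)
    pg = lomb_scargle(pdf, oversample, hifac)
    return pdf, significant_power(pg, pdf.n_grid, p_cut)
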