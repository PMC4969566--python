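"""Synthetic voltage segments and cohorts with known ground truth.

The generators emulate the study conditions the pipeline targets —
250 Hz single-channel recordings cut into one-minute segments, grouped by
subject and state of consciousness — using signal families whose kappa
statistics have closed forms:

``ramp``
    V(t) = slope * t; every kappa equals 1 + ln(slope)/ln(dt).
``alternating``
    0, a, 0, a, ...; at odd lags every kappa is ln(a)/ln(dt).
``white_noise``
    iid N(0, sigma^2) samples.
``fbm``
    fractional Brownian motion with Hurst exponent H and scale sigma,
    Var[V(t+dt) - V(t)] = sigma^2 dt^(2H) (dt in seconds), synthesized by
    exact circulant embedding of the increment covariance.
``sinusoid_mix``
    a sum of sinusoids with seeded random phases.
``powerlaw_increment``
    a square wave built so |V(t+lag) - V(t)| = c * dt^(kappa0) exactly at
    one declared lag, giving a machine-precision power-law oracle.

Cohorts perturb one state parameter per subject (a Gaussian offset shared
across that subject's states) so repeated-measures comparisons see true
between-subject variation, and record every realized parameter in a truth
table. Default amplitudes are mV-like (order 0.01-1) so the 4-second
scale drives kappa negative, exercising the sign flip of ln(dt) > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any
import logging

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import StageAnnotation, VoltageSegment
from .kappa import expected_kappa_fbm, expected_kappa_white_noise

log = logging.getLogger(__name__)

KINDS = (
    "ramp",
    "alternating",
    "white_noise",
    "fbm",
    "sinusoid_mix",
    "powerlaw_increment",
)

DEFAULT_FS = 250.0
DEFAULT_DURATION_S = 60.0
HURST_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic segment."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    fs: float = DEFAULT_FS
    duration_s: float = DEFAULT_DURATION_S
    seed: int = 0
    units: str = "mV"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"unknown signal kind {self.kind!r}; one of {KINDS}")
        if self.duration_s * self.fs < 2:
            raise ParameterError("duration_s * fs must be at least 2 samples")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a multi-subject, multi-state cohort.

    ``states`` maps a stage label to a SynthSpec template; ``effect_param``
    names the template parameter that receives the per-subject Gaussian
    offset (default: ``hurst`` for fbm templates, ``sigma`` otherwise).
    """

    n_subjects: int
    segments_per_state: int
    states: tuple[tuple[str, SynthSpec], ...]
    subject_effect_sd: float = 0.0
    effect_param: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ParameterError("a cohort needs at least 2 subjects")
        if self.segments_per_state < 1:
            raise ParameterError("segments_per_state must be >= 1")
        if not self.states:
            raise ParameterError("a cohort needs at least one state")


@dataclass(frozen=True)
class Cohort:
    segments: list[VoltageSegment]
    truth: pd.DataFrame


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Exact-covariance (Davies-Harte) synthesis: the fGn autocovariance is
    embedded in a circulant matrix whose eigenvalues come from one FFT;
    for H in (0, 1) they are nonnegative up to rounding.
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)
    c = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n-2
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        raise ParameterError(f"circulant embedding failed for H={hurst}")
    lam = np.clip(lam, 0.0, None)
    m = lam.size
    half = m // 2
    e = np.empty(m, dtype=complex)
    e[0] = math.sqrt(lam[0]) * rng.standard_normal()
    body = rng.standard_normal((half - 1, 2))
    e[1:half] = np.sqrt(lam[1:half] / 2.0) * (body[:, 0] + 1j * body[:, 1])
    e[half] = math.sqrt(lam[half]) * rng.standard_normal()
    e[half + 1 :] = np.conj(e[1:half][::-1])
    x = np.fft.fft(e).real / math.sqrt(m)
    return x[:n]


def fbm(
    n: int, hurst: float, sigma: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """fBm path of n samples with Var[V(t+dt)-V(t)] = sigma^2 dt^(2H), dt in s."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    step_sd = sigma * (1.0 / fs) ** hurst
    return np.cumsum(step_sd * fgn(n, hurst, rng))


def generate_segment(spec: SynthSpec) -> VoltageSegment:
    """Deterministically realize one segment from its spec."""
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    t = np.arange(n) / spec.fs
    if spec.kind == "ramp":
        v = p.get("slope", 1.0) * t + p.get("intercept", 0.0)
    elif spec.kind == "alternating":
        a = p.get("amplitude", 2.0)
        v = np.where(np.arange(n) % 2 == 0, 0.0, a)
    elif spec.kind == "white_noise":
        sigma = p.get("sigma", 1.0)
        if sigma <= 0:
            raise ParameterError("sigma must be positive")
        v = sigma * rng.standard_normal(n)
    elif spec.kind == "fbm":
        v = fbm(n, p.get("hurst", 0.5), p.get("sigma", 0.1), spec.fs, rng)
    elif spec.kind == "sinusoid_mix":
        freqs = np.atleast_1d(p.get("frequencies", [10.0]))
        amps = np.atleast_1d(p.get("amplitudes", [0.1] * len(freqs)))
        if len(freqs) != len(amps):
            raise ParameterError("frequencies and amplitudes differ in length")
        phases = p.get("phases")
        phases = (
            rng.uniform(0, 2 * math.pi, len(freqs))
            if phases is None
            else np.atleast_1d(phases)
        )
        v = sum(
            a * np.sin(2 * math.pi * f * t + ph)
            for f, a, ph in zip(freqs, amps, phases)
        )
    elif spec.kind == "powerlaw_increment":
        # square wave of period 2*lag: |V(t+lag)-V(t)| = c*dt^kappa0 at every t
        dt = p.get("delta_t_s", 0.004)
        lag = int(round(dt * spec.fs))
        if lag < 1:
            raise ParameterError("declared delta_t_s rounds to a zero-sample lag")
        d = p.get("c", 1.0) * dt ** p.get("kappa0", 0.5)
        phase = int(rng.integers(0, 2 * lag))
        sign = np.where((np.arange(n) + phase) // lag % 2 == 0, 1.0, -1.0)
        v = 0.5 * d * sign
    else:  # pragma: no cover - guarded in __post_init__
        raise ParameterError(f"unknown kind {spec.kind!r}")
    return VoltageSegment(
        samples=np.asarray(v, dtype=float),
        fs=spec.fs,
        units=spec.units,
        segment_id="synthetic",
    )


def _perturbed(template: SynthSpec, param: str, offset: float) -> tuple[SynthSpec, float, bool]:
    """Apply a subject offset to one template parameter, clipping to validity."""
    params = dict(template.params)
    if param == "hurst":
        base = params.get("hurst", 0.5)
        value = base + offset
        clipped = not HURST_CLIP[0] <= value <= HURST_CLIP[1]
        value = min(max(value, HURST_CLIP[0]), HURST_CLIP[1])
    else:
        base = params.get(param, 1.0)
        value = base + offset
        clipped = value < 1e-6
        value = max(value, 1e-6)
    params[param] = value
    return (
        SynthSpec(
            kind=template.kind,
            params=params,
            fs=template.fs,
            duration_s=template.duration_s,
            seed=template.seed,
            units=template.units,
        ),
        value,
        clipped,
    )


def generate_cohort(cs: CohortSpec) -> Cohort:
    """Realize a cohort: labeled segments plus a parameter truth table.

    Each subject draws one N(0, subject_effect_sd) offset applied to the
    effect parameter of every state template (shared across states, so the
    subject is a genuine repeated measure), then ``segments_per_state``
    independent segments per state.
    """
    root = np.random.SeedSequence(cs.seed)
    subject_seqs = root.spawn(cs.n_subjects)
    effect_rng = np.random.default_rng(root.spawn(1)[0])
    segments: list[VoltageSegment] = []
    rows = []
    n_clipped = 0
    for i, sseq in enumerate(subject_seqs):
        subject_id = f"subj{i:02d}"
        offset = float(effect_rng.normal(0.0, cs.subject_effect_sd))
        state_seqs = sseq.spawn(len(cs.states))
        for (label, template), stseq in zip(cs.states, state_seqs):
            param = cs.effect_param or (
                "hurst" if template.kind == "fbm" else "sigma"
            )
            spec_i, realized, clipped = _perturbed(template, param, offset)
            n_clipped += clipped
            seg_seeds = stseq.generate_state(cs.segments_per_state) % (2**31)
            for j in range(cs.segments_per_state):
                spec_j = SynthSpec(
                    kind=spec_i.kind,
                    params=spec_i.params,
                    fs=spec_i.fs,
                    duration_s=spec_i.duration_s,
                    seed=int(seg_seeds[j]),
                    units=spec_i.units,
                )
                seg = generate_segment(spec_j)
                seg = VoltageSegment(
                    samples=seg.samples,
                    fs=seg.fs,
                    units=seg.units,
                    subject_id=subject_id,
                    state=label,
                    segment_id=f"seg{j:02d}",
                    t0=0.0,
                )
                segments.append(seg)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "state": label,
                        "segment_id": f"seg{j:02d}",
                        "kind": spec_j.kind,
                        "effect_param": param,
                        "param_value": realized,
                        "subject_offset": offset,
                        "seed": spec_j.seed,
                        "fs": spec_j.fs,
                        "duration_s": spec_j.duration_s,
                        **{f"param_{k}": v for k, v in spec_j.params.items()
                           if np.isscalar(v)},
                    }
                )
    n_cells = cs.n_subjects * len(cs.states)
    if n_clipped > 0.1 * n_cells:
        log.warning(
            "subject-effect clipping hit %d of %d subject/state cells; "
            "consider a smaller subject_effect_sd",
            n_clipped,
            n_cells,
        )
    return Cohort(segments=segments, truth=pd.DataFrame(rows))


def expected_kappa(row: pd.Series, delta_t_s: float) -> float:
    """Closed-form E[kappa] for a truth-table row (fbm and white noise)."""
    if row["kind"] == "fbm":
        return expected_kappa_fbm(
            row["param_value"] if row["effect_param"] == "hurst" else row["param_hurst"],
            row.get("param_sigma", 0.1),
            delta_t_s,
        )
    if row["kind"] == "white_noise":
        sigma = (
            row["param_value"]
            if row["effect_param"] == "sigma"
            else row.get("param_sigma", 1.0)
        )
        return expected_kappa_white_noise(sigma, delta_t_s)
    raise ParameterError(f"no closed-form kappa for kind {row['kind']!r}")


def cohort_to_recordings(
    cohort: Cohort,
) -> dict[str, tuple[VoltageSegment, StageAnnotation]]:
    """Concatenate each subject's segments into one recording + hypnogram.

    Segments are laid back-to-back on a continuous time axis in state
    order, so `segment_recording` recovers them exactly; used by the
    `simulate` CLI to emit CSV + annotation TSV pairs.
    """
    out: dict[str, tuple[VoltageSegment, StageAnnotation]] = {}
    for subject_id in sorted({s.subject_id for s in cohort.segments}):
        segs = [s for s in cohort.segments if s.subject_id == subject_id]
        samples = np.concatenate([s.samples for s in segs])
        fs = segs[0].fs
        intervals = []
        t = 0.0
        for s in segs:
            intervals.append((t, t + s.duration_s, s.state))
            t += s.duration_s
        # merge adjacent intervals of one state into hypnogram-like bouts
        merged: list[tuple[float, float, str]] = []
        for a, b, lab in intervals:
            if merged and merged[-1][2] == lab and abs(merged[-1][1] - a) < 1e-9:
                merged[-1] = (merged[-1][0], b, lab)
            else:
                merged.append((a, b, lab))
        rec = VoltageSegment(
            samples=samples,
            fs=fs,
            units=segs[0].units,
            subject_id=subject_id,
            segment_id=subject_id,
            t0=0.0,
        )
        out[subject_id] = (rec, StageAnnotation(intervals=tuple(merged)))
    return out
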