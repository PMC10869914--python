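"""Synthetic respiration-modulated PPG records with ground truth.

The generator renders a quasi-periodic pulse train whose amplitude,
baseline and beat-to-beat interval are all modulated at the respiratory
frequency — the three mechanisms by which breathing imprints itself on
a real PPG — plus additive white noise, random pulse drops (sensor or
perfusion failures) and a deterministic irregular-rhythm mode (a
doubled interpulse interval every k-th beat).  Every stage of the RR
pipeline is therefore testable against known ground truth without any
external recording.

Construction, for mean heart rate ``hr_bpm`` and respiratory frequency
``f_r = rr_bpm / 60``:

1. instantaneous beat frequency
   ``f_h(t) = (hr_bpm/60) * (1 + m_rifv * sin(2*pi*f_r*t + phi_f))``;
   beat times are the integer crossings of the integrated phase (the
   integral has a closed form, solved per beat);
2. each beat renders a fixed asymmetric single-lobe pulse template
   (sharp ~0.12 s systolic upslope, slower decay) scaled by
   ``1 + m_riav * sin(2*pi*f_r*t_beat + phi_a)``;
3. a baseline ``m_riiv * sin(2*pi*f_r*t + phi_b)`` is added;
4. white noise of standard deviation ``noise_sd`` is added;
5. each beat is independently dropped with probability ``p_missing``;
6. the reference respiration channel is ``sin(2*pi*f_r*t)`` at the
   same sampling rate.

What it does *not* emulate: pulse-shape changes with vascular tone,
dicrotic notches, motion artefacts, or amplitude-dependent noise — so
clean-simulation results bound detector behaviour on well-perfused,
stationary recordings only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .signal_io import Record, UniformSignal

__all__ = ["SimParams", "GroundTruth", "pulse_template", "generate_record", "clean_params"]


@dataclass(frozen=True)
class SimParams:
    """Simulator settings.

    Parameters
    ----------
    duration_s : float
        Record length in seconds (default 480 s = 8 min, the analysis
        length used throughout).
    fs : float
        Sampling rate in Hz (default 125).
    hr_bpm : float
        Mean heart rate in beats/min; must exceed ``2 * rr_bpm`` so the
        respiratory modulation is identifiable from the beat series.
    rr_bpm : float
        Ground-truth respiratory rate in breaths/min.
    m_riav : float
        Pulse-amplitude modulation depth, in [0, 1).
    m_riiv : float
        Baseline modulation amplitude, in signal units (pulse height 1).
    m_rifv : float
        Beat-interval modulation depth, in [0, 0.5).
    noise_sd : float
        Additive white-noise standard deviation, signal units.
    p_missing : float
        Independent per-beat drop probability, in [0, 1].
    irregular_rhythm : bool
        Deterministically drop every ``irregular_every``-th beat, doubling
        that interpulse interval.
    irregular_every : int
        Spacing of the deterministic drops (default 12).
    phase_a, phase_b, phase_f : float
        Relative phases (rad) of the amplitude, baseline and frequency
        modulations; physiologically unspecified, default 0, and peak-
        frequency RR estimation must not depend on them.
    seed : int
        Seed for noise and random drops; identical params give
        bit-identical records.
    """

    duration_s: float = 480.0
    fs: float = 125.0
    hr_bpm: float = 80.0
    rr_bpm: float = 15.0
    m_riav: float = 0.1
    m_riiv: float = 0.1
    m_rifv: float = 0.05
    noise_sd: float = 0.01
    p_missing: float = 0.0
    irregular_rhythm: bool = False
    irregular_every: int = 12
    phase_a: float = 0.0
    phase_b: float = 0.0
    phase_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_bpm <= 2 * self.rr_bpm:
            raise ValueError("need hr_bpm > 2 * rr_bpm for identifiable modulation")
        if not 0 <= self.m_riav < 1:
            raise ValueError("m_riav must be in [0, 1)")
        if not 0 <= self.m_rifv < 0.5:
            raise ValueError("m_rifv must be in [0, 0.5)")
        if not 0 <= self.p_missing <= 1:
            raise ValueError("p_missing must be in [0, 1]")
        if self.duration_s <= 0 or self.fs <= 0 or self.rr_bpm <= 0:
            raise ValueError("duration_s, fs and rr_bpm must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: the oracle for every pipeline stage."""

    beat_times: np.ndarray  # rendered (post-drop) pulse-maximum times, s
    dropped_beat_times: np.ndarray  # beats removed by p_missing / irregular rhythm
    rr_bpm: float
    resp_phase: np.ndarray  # 2*pi*f_r*t on the sample grid


def pulse_template(rise_s: float = 0.12, fall_s: float = 0.23) -> Callable:
    """Asymmetric single-lobe pulse, unit height, maximum at t = 0.

    A raised-cosine upslope of ``rise_s`` seconds and a slower
    raised-cosine decay of ``fall_s`` seconds: one systolic maximum and
    a sharp upslope, which is what the counter detector keys on.
    """

    def shape(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        up = (t >= -rise_s) & (t <= 0)
        out[up] = 0.5 * (1 + np.cos(np.pi * t[up] / rise_s))
        dn = (t > 0) & (t <= fall_s)
        out[dn] = 0.5 * (1 + np.cos(np.pi * t[dn] / fall_s))
        return out

    return shape


def _beat_times(p: SimParams) -> np.ndarray:
    """Integer crossings of the integrated instantaneous beat frequency.

    The phase integral of ``f_h(t)`` is closed-form:
    ``Phi(t) = f0*t - f0*m*(cos(w t + phi) - cos(phi)) / w`` with
    ``f0 = hr/60``, ``w = 2*pi*f_r``; each beat time solves Phi(t) = k.
    """
    f0 = p.hr_bpm / 60.0
    if p.m_rifv == 0.0:
        n = int(np.floor(p.duration_s * f0))
        return np.arange(n + 1) / f0

    w = 2.0 * np.pi * p.rr_bpm / 60.0
    phi = p.phase_f

    def Phi(t: float) -> float:
        return f0 * t - f0 * p.m_rifv * (np.cos(w * t + phi) - np.cos(phi)) / w

    total = Phi(p.duration_s)
    ts: list[float] = []
    lo = 0.0
    # Phi is strictly increasing (m_rifv < 0.5 < 1), so bracketed bisection
    # per integer level is safe; the mean interval bounds the bracket.
    step = 1.0 / (f0 * (1.0 - p.m_rifv))
    k = 0
    while k <= total:
        hi = min(lo + 2.0 * step, p.duration_s)
        while Phi(hi) < k and hi < p.duration_s:
            hi = min(hi + step, p.duration_s)
        if Phi(hi) < k:
            break
        ts.append(brentq(lambda t: Phi(t) - k, lo, hi, xtol=1e-10))
        lo = ts[-1]
        k += 1
    return np.asarray(ts)


def generate_record(
    p: SimParams, template: Callable | None = None
) -> tuple[Record, GroundTruth]:
    """Generate one synthetic record and its ground truth.

    Deterministic given ``p`` (including ``p.seed``).  Returns the
    two-channel :class:`Record` (PPG + reference respiration) and the
    :class:`GroundTruth` with rendered and dropped beat times.
    """
    rng = np.random.default_rng(p.seed)
    if template is None:
        template = pulse_template()
    f_r = p.rr_bpm / 60.0
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs

    beats = _beat_times(p)
    # keep beats whose template support fits the record
    beats = beats[(beats > 0.2) & (beats < p.duration_s - 0.4)]

    keep = np.ones(beats.size, dtype=bool)
    if p.irregular_rhythm and beats.size:
        keep[p.irregular_every - 1 :: p.irregular_every] = False
    if p.p_missing > 0:
        keep &= rng.random(beats.size) >= p.p_missing
    kept, dropped = beats[keep], beats[~keep]

    ppg = np.zeros(n)
    for tb in kept:
        amp = 1.0 + p.m_riav * np.sin(2 * np.pi * f_r * tb + p.phase_a)
        i0 = max(0, int(np.floor((tb - 0.2) * p.fs)))
        i1 = min(n, int(np.ceil((tb + 0.4) * p.fs)) + 1)
        ppg[i0:i1] += amp * template(t[i0:i1] - tb)

    ppg += p.m_riiv * np.sin(2 * np.pi * f_r * t + p.phase_b)
    if p.noise_sd > 0:
        ppg += rng.normal(0.0, p.noise_sd, size=n)

    resp = np.sin(2 * np.pi * f_r * t)
    rec = Record(
        record_id=f"sim-{p.seed}",
        ppg=UniformSignal(ppg, fs=p.fs),
        resp=UniformSignal(resp, fs=p.fs),
        metadata={"synthetic": "true", "seed": str(p.seed)},
    )
    truth = GroundTruth(
        beat_times=kept,
        dropped_beat_times=dropped,
        rr_bpm=p.rr_bpm,
        resp_phase=2 * np.pi * f_r * t,
    )
    return rec, truth


def clean_params(**overrides) -> SimParams:
    """Convenience: a noiseless, drop-free parameter set for oracles."""
    base = SimParams(noise_sd=0.0, p_missing=0.0)
    return replace(base, **overrides)
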