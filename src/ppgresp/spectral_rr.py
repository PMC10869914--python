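"""Respiratory rate from the Lomb-Scargle peak frequency, plus fusion.

RR is read off as the frequency of maximum Lomb-Scargle power over a
band of 0.067-0.5 Hz (4-30 breaths/min), computed directly on the
unevenly sampled beat-domain series — the Lomb-Scargle periodogram is a
per-frequency least-squares sinusoid fit, so no interpolation or
resampling is needed.  The uniformly sampled reference respiration goes
through the identical path (uniform times are just a special case), so
reference and estimates share code.

Fusion averages three single-feature estimates (after Karlen et al.):
AIF = mean(RIAV, RIIV, RIFV), SIF = mean(RISSDV, RIIV, RIFV),
ASF = mean(RIAV, RISSDV, RIFV), AIS = mean(RIAV, RIIV, RISSDV).
A fused estimate is valid only when all three constituents are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle

from .riv_extraction import RIVSeries
from .signal_io import UniformSignal

__all__ = [
    "FrequencyBand",
    "PowerSpectrum",
    "RREstimate",
    "SegmentEstimates",
    "FUSION_COMBOS",
    "lomb_scargle",
    "estimate_rr",
    "fuse_estimates",
]

#: fusion name -> the three single-RIV constituents averaged
FUSION_COMBOS: dict[str, tuple[str, str, str]] = {
    "AIF": ("RIAV", "RIIV", "RIFV"),
    "SIF": ("RISSDV", "RIIV", "RIFV"),
    "ASF": ("RIAV", "RISSDV", "RIFV"),
    "AIS": ("RIAV", "RIIV", "RISSDV"),
}


@dataclass(frozen=True)
class FrequencyBand:
    """Analysis band and grid for the periodogram.

    Defaults cover 0.067-0.5 Hz (4-30 breaths/min) at 0.001 Hz spacing
    (0.06 bpm granularity), fine enough that grid quantization is
    negligible on the breaths-per-minute error scale.
    """

    f_lo: float = 0.067
    f_hi: float = 0.5
    step: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def freqs(self) -> np.ndarray:
        n = int(np.floor((self.f_hi - self.f_lo) / self.step + 0.5)) + 1
        return self.f_lo + self.step * np.arange(n)

    @property
    def rr_range_bpm(self) -> tuple[float, float]:
        return 60.0 * self.f_lo, 60.0 * self.f_hi


@dataclass(frozen=True)
class PowerSpectrum:
    """Lomb-Scargle power on a frequency grid; ``kind`` tags the source."""

    freqs: np.ndarray
    power: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.size != self.power.size:
            raise ValueError("freqs and power must have equal lengths")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def peak_frequency(self) -> float:
        """Frequency of maximum power; the lowest such frequency on ties."""
        return float(self.freqs[int(np.argmax(self.power))])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"freq_hz": self.freqs, "power": self.power}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RREstimate:
    """One RR estimate: ``rr_bpm = 60 * f_peak`` when ``valid``."""

    rr_bpm: float
    f_peak: float
    method: str
    valid: bool = True


@dataclass
class SegmentEstimates:
    """All RR estimates for one analysis segment, keyed by method tag."""

    record_id: str
    segment_index: int
    estimates: dict[str, RREstimate] = field(default_factory=dict)


def lomb_scargle(
    times: np.ndarray,
    values: np.ndarray,
    band: FrequencyBand = FrequencyBand(),
    kind: str = "",
) -> PowerSpectrum | None:
    """Classical Lomb-Scargle periodogram of mean-subtracted values.

    Returns ``None`` for fewer than 4 points (no meaningful spectrum);
    an all-constant series yields identically zero power.  The peak
    *location* is invariant to amplitude scaling and to adding a
    constant, which downstream RR extraction relies on.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        return None
    if times[-1] - times[0] < 1.0 / band.f_lo:
        warnings.warn(
            f"series span {times[-1] - times[0]:.1f} s is below one period "
            f"of f_lo={band.f_lo} Hz; spectrum may be unreliable",
            stacklevel=2,
        )
    y = values - values.mean()
    freqs = band.freqs
    if np.ptp(y) == 0.0:
        return PowerSpectrum(freqs, np.zeros_like(freqs), kind)
    power = _scipy_lombscargle(times, y, 2.0 * np.pi * freqs, normalize=False)
    return PowerSpectrum(freqs, power, kind)


def _invalid(method: str) -> RREstimate:
    return RREstimate(rr_bpm=np.nan, f_peak=np.nan, method=method, valid=False)


def estimate_rr(
    source: RIVSeries | UniformSignal,
    band: FrequencyBand = FrequencyBand(),
    method: str | None = None,
) -> RREstimate:
    """Peak-frequency RR estimate from a RIV series or a uniform signal.

    ``rr_bpm = 60 * argmax`` frequency of the Lomb-Scargle power, hence
    always inside ``[60 * f_lo, 60 * f_hi]``; invalid (not clamped, not
    imputed) when the spectrum cannot be formed or is identically zero.
    """
    if isinstance(source, UniformSignal):
        times, values = source.times, source.values
        tag = method if method is not None else "REF"
    else:
        times, values = source.times, source.values
        tag = method if method is not None else source.kind
    spec = lomb_scargle(times, values, band, kind=tag)
    if spec is None or not np.any(spec.power > 0):
        return _invalid(tag)
    f = spec.peak_frequency()
    return RREstimate(rr_bpm=60.0 * f, f_peak=f, method=tag, valid=True)


def fuse_estimates(
    est: SegmentEstimates, combos: dict[str, tuple[str, str, str]] | None = None
) -> SegmentEstimates:
    """Add three-feature average estimates to a segment (in place).

    Each fused estimate is the arithmetic mean of three single-RIV
    estimates and is valid only when all three are; an invalid
    constituent is never imputed.
    """
    if combos is None:
        combos = FUSION_COMBOS
    for name, parts in combos.items():
        members = [est.estimates.get(p) for p in parts]
        if all(m is not None and m.valid for m in members):
            rr = float(np.mean([m.rr_bpm for m in members]))  # type: ignore[union-attr]
            est.estimates[name] = RREstimate(
                rr_bpm=rr, f_peak=rr / 60.0, method=name, valid=True
            )
        else:
            est.estimates[name] = RREstimate(
                rr_bpm=np.nan, f_peak=np.nan, method=name, valid=False
            )
    return est
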