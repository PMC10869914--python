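"""Counter-based systolic peak/trough detection with an adaptive refractory period.

The detector walks the band-passed PPG sample by sample and counts
consecutive rising samples.  When a local maximum terminates an upslope
whose length reached ``count_threshold`` samples, the maximum is a peak
candidate and the sample where the upslope began is its trough; shorter
upslopes are ignored and the counter resets.  After the first accepted
pulse, a candidate is accepted only if the interpulse interval (IPI)
exceeds a refractory period that is continually re-estimated from recent
IPIs, which suppresses over-detection of dicrotic or noisy secondary
maxima.  A watchdog restarts detection when no pulse has been accepted
for much longer than the expected IPI (e.g. across a run of missing
pulses), so the next pulse is treated as the first and the adaptive
state is rebuilt rather than locking out real beats.

Amplitude enters only through sample-to-sample comparisons, so fiducial
*times* are invariant to any positive rescaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import UniformSignal

__all__ = [
    "DetectorParams",
    "FiducialSeries",
    "detect_fiducials",
    "trim_fiducials",
    "fiducials_to_csv",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable constants of the counter detector.

    Parameters
    ----------
    count_threshold : int or None
        Minimum upslope length in samples for a pulse to be accepted.
        ``None`` (default) resolves to ``round(0.04 * fs)`` at run time
        (5 samples at 125 Hz), sized so that clean systolic upslopes of
        ~0.1-0.2 s always pass.
    refractory_init_s : float
        Initial refractory period in seconds; 0.33 s corresponds to a
        180 beats/min ceiling.
    refractory_update : float
        Exponential-smoothing weight in (0, 1] for the running refractory
        estimate.
    refractory_fraction : float
        The refractory period tracks this fraction of the running IPI.
    restart_factor : float
        Watchdog multiple: detection restarts when the time since the
        last accepted peak exceeds ``restart_factor`` times the expected
        IPI (default 1.75).
    restart_mode : {"time", "counter"}
        "time" is the watchdog above; "counter" is the literal reading in
        which the upslope counter itself exceeding ``restart_factor *
        count_threshold`` triggers the restart.
    min_prominence : float or None
        Amplitude guard: a candidate's trough-to-peak rise must be at
        least this fraction of the running (exponentially smoothed)
        rise of accepted pulses.  Rejects the small rebound ripples the
        band-pass filter leaves after each pulse and spurious wiggles
        inside pulse gaps; relative, so fiducial times stay invariant
        to amplitude rescaling.  ``None`` disables the guard.
    """

    count_threshold: int | None = None
    refractory_init_s: float = 0.33
    refractory_update: float = 0.25
    refractory_fraction: float = 0.6
    restart_factor: float = 1.75
    restart_mode: str = "time"
    min_prominence: float | None = 0.3

    def __post_init__(self) -> None:
        if self.count_threshold is not None and self.count_threshold < 2:
            raise ValueError("count_threshold must be >= 2")
        if self.restart_factor <= 1:
            raise ValueError("restart_factor must be > 1")
        if not 0 < self.refractory_update <= 1:
            raise ValueError("refractory_update must be in (0, 1]")
        if self.restart_mode not in ("time", "counter"):
            raise ValueError(f"unknown restart_mode {self.restart_mode!r}")

    def resolve_count_threshold(self, fs: float) -> int:
        if self.count_threshold is not None:
            return self.count_threshold
        return max(2, int(round(0.04 * fs)))


@dataclass
class FiducialSeries:
    """Detected pulses: one (trough, peak) pair per accepted pulse.

    ``refractory_at_accept`` records the refractory period that was in
    force when each peak was accepted, so the refractory invariant
    (every IPI exceeds it) is externally checkable.
    """

    peak_times: np.ndarray
    peak_amps: np.ndarray
    trough_times: np.ndarray
    trough_amps: np.ndarray
    refractory_at_accept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amps = np.asarray(self.peak_amps, dtype=float)
        self.trough_times = np.asarray(self.trough_times, dtype=float)
        self.trough_amps = np.asarray(self.trough_amps, dtype=float)
        if self.refractory_at_accept is None:
            self.refractory_at_accept = np.full(self.peak_times.shape, np.nan)
        n = self.peak_times.size
        if not (self.peak_amps.size == self.trough_times.size == self.trough_amps.size == n):
            raise ValueError("fiducial arrays must have equal lengths")
        if n:
            if np.any(np.diff(self.peak_times) <= 0):
                raise ValueError("peak times must be strictly increasing")
            if np.any(self.trough_times >= self.peak_times):
                raise ValueError("each trough must precede its peak")

    @property
    def n_pulses(self) -> int:
        return self.peak_times.size

    def __len__(self) -> int:
        return self.n_pulses


def _empty_fiducials() -> FiducialSeries:
    z = np.empty(0)
    return FiducialSeries(z, z.copy(), z.copy(), z.copy(), z.copy())


def detect_fiducials(ppg: UniformSignal, params: DetectorParams = DetectorParams()) -> FiducialSeries:
    """Run the counter detector over a band-passed PPG.

    Returns one (trough, peak) pair per accepted pulse; an empty series
    (with a warning) when the signal is too short to contain one.
    """
    x = ppg.values
    fs = ppg.fs
    thr = params.resolve_count_threshold(fs)
    if x.size < 2 * thr:
        warnings.warn("signal too short for peak detection", stacklevel=2)
        return _empty_fiducials()

    peaks_i: list[int] = []
    troughs_i: list[int] = []
    refr_at: list[float] = []

    counter = 0
    upslope_start = 0
    refractory = params.refractory_init_s
    ipi_est: float | None = None  # running expected interpulse interval
    last_peak_i: int | None = None
    rise_est: float | None = None  # running rise of accepted pulses
    w = params.refractory_update
    frac = params.refractory_fraction

    def restart_state() -> None:
        # timing state is rebuilt from scratch; the amplitude scale
        # (rise_est) survives so post-gap ripples stay non-prominent
        nonlocal refractory, ipi_est, last_peak_i
        refractory = params.refractory_init_s
        ipi_est = None
        last_peak_i = None

    for i in range(1, x.size):
        if x[i] > x[i - 1]:
            if counter == 0:
                upslope_start = i - 1
            counter += 1
            if params.restart_mode == "counter" and counter > params.restart_factor * thr:
                restart_state()
            continue
        if x[i] == x[i - 1]:
            # plateaus neither extend nor break an upslope
            continue

        # falling sample: x[i-1] was a local maximum terminating the upslope
        if counter >= thr:
            cand_i = i - 1
            rise = x[cand_i] - x[upslope_start]
            prominent = (
                params.min_prominence is None
                or rise_est is None
                or rise >= params.min_prominence * rise_est
            )
            if prominent:
                if last_peak_i is None:
                    accept = True
                else:
                    ipi = (cand_i - last_peak_i) / fs
                    accept = ipi > refractory
                if accept:
                    if last_peak_i is not None:
                        ipi = (cand_i - last_peak_i) / fs
                        ipi_est = ipi if ipi_est is None else (1 - w) * ipi_est + w * ipi
                        refractory = (1 - w) * refractory + w * (frac * ipi)
                    refr_at.append(refractory)
                    peaks_i.append(cand_i)
                    troughs_i.append(upslope_start)
                    last_peak_i = cand_i
                    rise_est = rise if rise_est is None else (1 - w) * rise_est + w * rise
        counter = 0

        # time-based watchdog: too long without an accepted pulse -> restart
        if (
            params.restart_mode == "time"
            and last_peak_i is not None
            and ipi_est is not None
            and (i - last_peak_i) / fs > params.restart_factor * ipi_est
        ):
            restart_state()

    if not peaks_i:
        return _empty_fiducials()
    pk = np.asarray(peaks_i)
    tr = np.asarray(troughs_i)
    refr = np.asarray(refr_at)
    if params.min_prominence is not None and pk.size >= 3:
        # the online guard has no amplitude scale until the first pulse is
        # accepted, so noise wiggles before the first real pulse slip in;
        # prune against the median rise of everything accepted
        rises = x[pk] - x[tr]
        keep = rises >= params.min_prominence * np.median(rises)
        pk, tr, refr = pk[keep], tr[keep], refr[keep]
    return FiducialSeries(
        peak_times=ppg.t0 + pk / fs,
        peak_amps=x[pk],
        trough_times=ppg.t0 + tr / fs,
        trough_amps=x[tr],
        refractory_at_accept=refr,
    )


def trim_fiducials(fid: FiducialSeries, t_lo: float, t_hi: float) -> FiducialSeries:
    """Drop pulses whose trough or peak falls outside ``[t_lo, t_hi]``.

    Used to exclude fiducials inside the flagged edge-transient guard of
    a filtered segment (kept by default in the pipeline).
    """
    keep = (fid.trough_times >= t_lo) & (fid.peak_times <= t_hi)
    return FiducialSeries(
        fid.peak_times[keep],
        fid.peak_amps[keep],
        fid.trough_times[keep],
        fid.trough_amps[keep],
        fid.refractory_at_accept[keep],
    )


def fiducials_to_csv(fid: FiducialSeries, path) -> None:
    """Export fiducials as CSV, one row per pulse."""
    import pandas as pd

    pd.DataFrame(
        {
            "trough_time_s": fid.trough_times,
            "trough_amp": fid.trough_amps,
            "peak_time_s": fid.peak_times,
            "peak_amp": fid.peak_amps,
        }
    ).to_csv(path, index=False)
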