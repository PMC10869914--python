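"""Shared fixtures: synthetic records and small CSV files on disk."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ppgresp as pr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_record():
    """A 60-s noiseless, drop-free record with all three modulations on."""
    return pr.generate_record(
        pr.clean_params(duration_s=60.0, hr_bpm=80.0, rr_bpm=15.0)
    )


@pytest.fixture(scope="session")
def clean_segment(clean_record):
    rec, _ = clean_record
    return pr.segment_record(rec, window_s=60.0)[0]


@pytest.fixture(scope="session")
def clean_fiducials(clean_record):
    rec, _ = clean_record
    seg = pr.preprocess_segment(pr.segment_record(rec)[0])
    return pr.detect_fiducials(seg.ppg)


@pytest.fixture()
def bidmc_csv(tmp_path):
    """A tiny CSV in the BIDMC 'Signals' dialect (125 Hz, padded headers)."""
    fs = 125.0
    t = np.arange(int(10 * fs)) / fs
    ppg = np.sin(2 * np.pi * 1.2 * t)
    resp = np.sin(2 * np.pi * 0.25 * t)
    path = tmp_path / "bidmc_01_Signals.csv"
    with open(path, "w") as fh:
        fh.write("Time [s], PLETH, RESP\n")
        for ti, p, r in zip(t, ppg, resp):
            fh.write(f"{ti:.8f},{p:.6f},{r:.6f}\n")
    return path


def detection_scores(
    fid: pr.FiducialSeries,
    true_beats: np.ndarray,
    t_lo: float,
    t_hi: float,
    tol_s: float = 0.04,
) -> tuple[float, float]:
    """Sensitivity and PPV of detected peaks against true beat times.

    Fiducials are trimmed to [t_lo, t_hi]; truth is counted over an
    inner window one tolerance narrower, so boundary pulses are not
    scored against truth outside the trimmed span.
    """
    fid = pr.trim_fiducials(fid, t_lo, t_hi)
    truth = true_beats[(true_beats > t_lo + 0.5) & (true_beats < t_hi - 0.5)]
    if truth.size == 0 or fid.n_pulses == 0:
        return 0.0, 0.0
    d = np.abs(fid.peak_times[:, None] - truth[None, :])
    sens = float((d.min(axis=0) <= tol_s).mean())
    ppv_mask = (fid.peak_times > t_lo + 0.5) & (fid.peak_times < t_hi - 0.5)
    ppv = float((d.min(axis=1)[ppv_mask] <= tol_s).mean())
    return sens, ppv
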