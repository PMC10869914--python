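"""Error metrics, rank-based multi-comparison, and Bland-Altman agreement.

Estimated RR values are compared with the reference-respiration RR via

    RMSE = sqrt(mean((RR_est - RR_ref)^2)),   MAE = mean(|RR_est - RR_ref|)

in breaths/min.  Method error distributions are compared with a
Kruskal-Wallis test followed by pairwise two-sided Mann-Whitney tests
with Bonferroni correction.  Agreement is summarised Bland-Altman
style: bias = mean(est - ref), limits of agreement bias +/- 1.96 * SD
of the differences, and a t-based 95% confidence interval of the bias —
when that interval contains zero (the line of equality) there is no
significant systematic difference.

The unit of observation for the rank tests is the per-record error
(RMSE or MAE over that record's segments): segments within a record are
not independent, and Kruskal-Wallis assumes independent observations.
A per-segment mode is available for exploration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peak_detection import DetectorParams, detect_fiducials
from .preprocessing import FilterDesign, preprocess_record, preprocess_segment
from .riv_extraction import RIV_KINDS, compute_rivs
from .signal_io import Record, segment_record
from .spectral_rr import (
    FUSION_COMBOS,
    FrequencyBand,
    SegmentEstimates,
    estimate_rr,
    fuse_estimates,
)

__all__ = [
    "EvaluationPair",
    "ErrorSummary",
    "RankTestReport",
    "BlandAltmanResult",
    "DatasetReport",
    "METHODS",
    "rmse",
    "mae",
    "compare_methods",
    "bland_altman",
    "estimate_segment",
    "evaluate_dataset",
]

#: the eight PPG-derived methods, in reporting order
METHODS = RIV_KINDS + tuple(FUSION_COMBOS)


@dataclass(frozen=True)
class EvaluationPair:
    """Matched estimated/reference RR arrays (breaths per minute)."""

    rr_est: np.ndarray
    rr_ref: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rr_est", np.asarray(self.rr_est, dtype=float))
        object.__setattr__(self, "rr_ref", np.asarray(self.rr_ref, dtype=float))
        if self.rr_est.shape != self.rr_ref.shape or self.rr_est.ndim != 1:
            raise ValueError("rr_est and rr_ref must be 1-D of equal length")
        if self.n < 1:
            raise ValueError("need at least one observation")
        if not (np.all(np.isfinite(self.rr_est)) and np.all(np.isfinite(self.rr_ref))):
            raise ValueError("RR values must be finite")

    @property
    def n(self) -> int:
        return self.rr_est.size

    @property
    def diffs(self) -> np.ndarray:
        """Differences est - ref (the reporting direction throughout)."""
        return self.rr_est - self.rr_ref


def rmse(pair: EvaluationPair) -> float:
    """Root-mean-squared error in breaths/min."""
    return float(np.sqrt(np.mean(pair.diffs**2)))


def mae(pair: EvaluationPair) -> float:
    """Mean absolute error in breaths/min."""
    return float(np.mean(np.abs(pair.diffs)))


@dataclass
class ErrorSummary:
    method: str
    rmse: float
    mae: float
    per_record: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pairs: int = 0
    n_excluded: int = 0


@dataclass
class RankTestReport:
    """Kruskal-Wallis H plus Bonferroni-adjusted pairwise Mann-Whitney p."""

    H: float
    df: int
    p_global: float
    pairwise: dict[tuple[str, str], float]
    metric: str = ""

    def pairwise_p(self, a: str, b: str) -> float:
        return self.pairwise[(a, b)] if (a, b) in self.pairwise else self.pairwise[(b, a)]


def compare_methods(
    errors: dict[str, np.ndarray], metric: str = ""
) -> RankTestReport | None:
    """Rank-based multi-comparison of per-record error distributions.

    Global Kruskal-Wallis (df = #methods - 1), then all pairwise
    two-sided Mann-Whitney tests with Bonferroni multiplier equal to the
    number of pairs, adjusted p capped at 1.  SciPy's ``mannwhitneyu``
    uses the exact null distribution for small tie-free groups and the
    tie-corrected normal approximation otherwise.  Methods with fewer
    than 2 values are excluded with a warning; returns ``None`` when
    fewer than 2 methods remain.
    """
    groups: dict[str, np.ndarray] = {}
    for m, v in errors.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            warnings.warn(f"method {m!r} has < 2 values; excluded from rank tests", stacklevel=2)
            continue
        groups[m] = v
    if len(groups) < 2:
        warnings.warn("fewer than 2 methods with enough data; rank tests skipped", stacklevel=2)
        return None

    names = list(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        # every observation identical: no rank separation by definition
        H, p_global = 0.0, 1.0
    else:
        H, p_global = stats.kruskal(*groups.values())
    pairs = list(itertools.combinations(names, 2))
    bonf = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairwise[(a, b)] = min(1.0, float(p) * bonf)
    return RankTestReport(
        H=float(H), df=len(names) - 1, p_global=float(p_global),
        pairwise=pairwise, metric=metric,
    )


@dataclass
class BlandAltmanResult:
    """Bias, limits of agreement, and the bias's 95% confidence interval."""

    bias: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    ci_lo: float
    ci_hi: float
    n: int

    @property
    def equality_line_contained(self) -> bool:
        """True when 0 lies inside the bias CI (no systematic difference)."""
        return self.ci_lo <= 0.0 <= self.ci_hi


def bland_altman(
    pair: EvaluationPair, ci_method: str = "t", loa_factor: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of est - ref differences.

    ``sd_diff`` uses the n-1 denominator; LOA = bias +/- 1.96 * sd_diff.
    The bias CI is t-based by default (small-sample correct); the
    normal-approximation variant is available with ``ci_method="normal"``.
    """
    if pair.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pair.diffs
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if ci_method == "t":
        crit = float(stats.t.ppf(0.975, pair.n - 1))
    elif ci_method == "normal":
        crit = float(stats.norm.ppf(0.975))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    half = crit * sd / np.sqrt(pair.n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lo=bias - loa_factor * sd,
        loa_hi=bias + loa_factor * sd,
        ci_lo=bias - half,
        ci_hi=bias + half,
        n=pair.n,
    )


# ---------------------------------------------------------------------------
# full-pipeline evaluation
# ---------------------------------------------------------------------------


def estimate_segment(
    seg,
    detector: DetectorParams = DetectorParams(),
    band: FrequencyBand = FrequencyBand(),
    design: FilterDesign = FilterDesign(),
    preprocess: bool = True,
) -> SegmentEstimates:
    """Run the full per-segment pipeline: filter, detect, RIVs, LS, fuse.

    Produces the four single-RIV estimates, the four fusions, and REF
    when a reference respiration channel is present.
    """
    if preprocess:
        seg = preprocess_segment(seg, design=design)
    fid = detect_fiducials(seg.ppg, detector)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse fiducials warn per kind
        rivs = compute_rivs(fid)
    est = SegmentEstimates(seg.record_id, seg.index)
    for kind in RIV_KINDS:
        est.estimates[kind] = estimate_rr(rivs[kind], band)
    fuse_estimates(est)
    if seg.resp is not None:
        est.estimates["REF"] = estimate_rr(seg.resp, band, method="REF")
    return est


@dataclass
class DatasetReport:
    """Everything :func:`evaluate_dataset` computes."""

    summaries: dict[str, ErrorSummary]
    rank_rmse: RankTestReport | None
    rank_mae: RankTestReport | None
    bland_altman: dict[str, BlandAltmanResult | None]
    exclusions: dict[str, int]
    segment_estimates: list[SegmentEstimates] = field(default_factory=list)


def evaluate_dataset(
    records: list[Record],
    window_s: float = 60.0,
    max_segments: int | None = 8,
    detector: DetectorParams = DetectorParams(),
    band: FrequencyBand = FrequencyBand(),
    design: FilterDesign = FilterDesign(),
    aggregation: str = "record",
) -> DatasetReport:
    """Run the whole pipeline over a dataset and summarise performance.

    Every record needs a reference respiration channel.  Per-record
    RMSE/MAE are computed over that record's segments; rank tests run
    over the methods' per-record (default) or per-segment error
    distributions, once for RMSE and once for MAE; Bland-Altman is
    pooled over all segments per method.  Segments where a method's
    estimate (or REF) is invalid are excluded from that method's pairs
    and tallied.
    """
    if aggregation not in ("record", "segment"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    for rec in records:
        if rec.resp is None:
            raise ValueError(f"record {rec.record_id!r} has no reference respiration")

    all_est: list[SegmentEstimates] = []
    pairs: dict[str, list[tuple[str, float, float]]] = {m: [] for m in METHODS}
    exclusions: dict[str, int] = {m: 0 for m in METHODS}
    for rec in records:
        filtered = preprocess_record(rec, design=design)
        for seg in segment_record(filtered, window_s=window_s, max_segments=max_segments):
            est = estimate_segment(seg, detector, band, design, preprocess=False)
            all_est.append(est)
            ref = est.estimates.get("REF")
            if ref is None or not ref.valid:
                for m in METHODS:
                    exclusions[m] += 1
                continue
            for m in METHODS:
                e = est.estimates[m]
                if e.valid:
                    pairs[m].append((rec.record_id, e.rr_bpm, ref.rr_bpm))
                else:
                    exclusions[m] += 1

    summaries: dict[str, ErrorSummary] = {}
    per_record_rmse: dict[str, np.ndarray] = {}
    per_record_mae: dict[str, np.ndarray] = {}
    ba: dict[str, BlandAltmanResult | None] = {}
    for m in METHODS:
        rows = pairs[m]
        if not rows:
            summaries[m] = ErrorSummary(m, np.nan, np.nan, {}, 0, exclusions[m])
            ba[m] = None
            continue
        rids = [r for r, _, _ in rows]
        est_v = np.array([e for _, e, _ in rows])
        ref_v = np.array([r for _, _, r in rows])
        pooled = EvaluationPair(est_v, ref_v)
        per_rec: dict[str, tuple[float, float]] = {}
        for rid in dict.fromkeys(rids):  # preserve order, unique
            sel = np.array([r == rid for r in rids])
            p = EvaluationPair(est_v[sel], ref_v[sel])
            per_rec[rid] = (rmse(p), mae(p))
        summaries[m] = ErrorSummary(
            m, rmse(pooled), mae(pooled), per_rec, pooled.n, exclusions[m]
        )
        ba[m] = bland_altman(pooled) if pooled.n >= 2 else None
        if aggregation == "record":
            per_record_rmse[m] = np.array([v[0] for v in per_rec.values()])
            per_record_mae[m] = np.array([v[1] for v in per_rec.values()])
        else:
            per_record_rmse[m] = np.abs(pooled.diffs)  # per-segment |error| proxy
            per_record_mae[m] = np.abs(pooled.diffs)

    rank_rmse = compare_methods(per_record_rmse, metric="RMSE")
    rank_mae = compare_methods(per_record_mae, metric="MAE")
    return DatasetReport(
        summaries=summaries,
        rank_rmse=rank_rmse,
        rank_mae=rank_mae,
        bland_altman=ba,
        exclusions=exclusions,
        segment_estimates=all_est,
    )
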