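"""Reliability diagnostics for nonequilibrium work distributions.

Nonzero overlap between the forward and (negated) reverse work
distributions is necessary for unbiased bidirectional estimates.  The
overlap coefficient is the area of intersection of the two normalized
distributions; the distance is the gap between their inner extremes, which
remains informative when the overlap is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import FreeEnergyEstimate, WorkSet, require_min_samples
from .exceptions import DegenerateInputError

#: Suggested reliability thresholds: standard error and distance (kcal/mol).
SE_THRESHOLD = 0.5
DISTANCE_THRESHOLD = 0.0


@dataclass(frozen=True)
class DiagnosticsReport:
    """Shape and reliability diagnostics of one work set."""

    overlap_coefficient: float
    distance: float
    skewness: float
    excess_kurtosis: float
    n_fwd: int
    n_rev: int
    degenerate: bool = False
    bin_rule: str = "freedman-diaconis(min 10 bins), shared edges"

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_coefficient <= 1.0):
            raise ValueError("overlap coefficient must lie in [0, 1]")


def _paired_samples(ws: WorkSet) -> tuple[np.ndarray, np.ndarray]:
    """Forward works and negated reverse works on a common axis."""
    wf = ws.works("forward")
    wr = -ws.works("reverse")
    return wf, wr


def shared_bin_edges(pooled: np.ndarray, min_bins: int = 10) -> np.ndarray:
    """Shared histogram edges: Freedman–Diaconis width, at least 10 bins."""
    lo, hi = float(pooled.min()), float(pooled.max())
    iqr = float(np.subtract(*np.percentile(pooled, [75, 25])))
    width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
    span = hi - lo
    if width > 0:
        n_bins = max(min_bins, int(np.ceil(span / width)))
    else:
        n_bins = min_bins
    return np.linspace(lo, hi, n_bins + 1)


def overlap_coefficient(ws: WorkSet) -> float:
    """Area of intersection of the forward and negated-reverse distributions.

    Both samples are histogrammed on shared bins spanning the pooled range
    (Freedman–Diaconis width, minimum 10 bins), normalized to unit area;
    the coefficient is Σ_b min(p_f, p_r)·Δ_b, clipped to [0, 1].  1 means
    identical distributions, 0 means no overlap.  A degenerate pooled
    range (all values equal) returns 1.0.
    """
    wf, wr = _paired_samples(ws)
    if wf.size < 2 or wr.size < 2:
        raise DegenerateInputError("need >= 2 works in each direction")
    pooled = np.concatenate([wf, wr])
    if np.ptp(pooled) == 0.0:
        return 1.0
    edges = shared_bin_edges(pooled)
    pf, _ = np.histogram(wf, bins=edges, density=True)
    pr, _ = np.histogram(wr, bins=edges, density=True)
    widths = np.diff(edges)
    return float(np.clip(np.sum(np.minimum(pf, pr) * widths), 0.0, 1.0))


def work_distance(ws: WorkSet) -> float:
    """Gap between the inner extremes of the two work distributions.

    distance = min(forward works) − max(negated reverse works): positive
    values measure the gap between non-overlapping ranges; negative values
    mean the ranges interleave (outliers can produce negative distances
    even at zero histogram overlap).
    """
    wf, wr = _paired_samples(ws)
    if wf.size < 1 or wr.size < 1:
        raise DegenerateInputError("need >= 1 work in each direction")
    return float(wf.min() - wr.max())


def moment_diagnostics(values: Sequence[float], bias: bool = True) -> tuple[float, float]:
    """Skewness and excess kurtosis of a ΔG or work sample.

    Population (biased) central-moment estimators by default:
    skew = m₃/m₂^{3/2}, excess kurtosis = m₄/m₂² − 3.  Set ``bias=False``
    for the sample-adjusted variants.
    """
    arr = require_min_samples(values, 4, "moment diagnostics")
    if np.ptp(arr) == 0.0 or arr.std() == 0.0:
        raise DegenerateInputError("zero variance; moments undefined")
    skew = float(stats.skew(arr, bias=bias))
    kurt = float(stats.kurtosis(arr, fisher=True, bias=bias))
    return skew, kurt


def reliability_flags(
    est: FreeEnergyEstimate,
    diag: DiagnosticsReport | None = None,
    se_threshold: float = SE_THRESHOLD,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> dict:
    """Reliability criteria: precision and (for NEQ) distribution overlap.

    ``precision_ok`` is stderr ≤ ``se_threshold`` (boundary inclusive);
    ``overlap_ok`` is distance ≤ ``distance_threshold`` when diagnostics
    are supplied, and None for equilibrium estimates without diagnostics.
    """
    if not (np.isfinite(se_threshold) and np.isfinite(distance_threshold)):
        raise ValueError("thresholds must be finite")
    flags: dict = {"precision_ok": bool(est.stderr <= se_threshold)}
    flags["overlap_ok"] = (
        bool(diag.distance <= distance_threshold) if diag is not None else None
    )
    return flags


def diagnose(ws: WorkSet) -> DiagnosticsReport:
    """Full diagnostics of a bidirectional work set."""
    wf, wr = _paired_samples(ws)
    pooled = np.concatenate([wf, wr])
    degenerate = bool(np.ptp(pooled) == 0.0)
    if degenerate or pooled.size < 4 or pooled.std() == 0.0:
        skew, kurt = float("nan"), float("nan")
    else:
        skew, kurt = moment_diagnostics(pooled)
    report = DiagnosticsReport(
        overlap_coefficient=overlap_coefficient(ws),
        distance=work_distance(ws),
        skewness=skew if np.isfinite(skew) else 0.0,
        excess_kurtosis=kurt if np.isfinite(kurt) else 0.0,
        n_fwd=int(wf.size),
        n_rev=int(wr.size),
        degenerate=degenerate,
    )
    return report
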