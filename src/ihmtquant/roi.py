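"""ROI statistics on ihMTR maps, contrast metrics, protocol selection and
small-sample inference.

The study design behind these tools: three manually drawn regions of interest
— the free-running Purkinje-fiber segment (label 1), the Purkinje-myocardial
junction (PMJ, label 2) and working myocardium (label 3) — are evaluated on
each ihMTR map.  Candidate saturation protocols are screened by the mean
ihMTR of the free-running region and by two contrast metrics, the absolute
differences of the free-running ROI mean against myocardium and against the
PMJ.  ihMTR in the fiber also rises roughly linearly with sample temperature,
so a least-squares slope (% per °C) is provided, and region comparisons
across samples use a paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import IhMTRMap, ProtocolParams
from .errors import DegenerateFitError, EmptyRegionError, SelectionError

__all__ = [
    "FREE_RUNNING", "PMJ", "MYOCARDIUM",
    "RegionMask", "RegionStats", "ContrastPair",
    "region_stats", "contrasts",
    "AcquisitionResult", "ProtocolScore", "select_protocols",
    "TemperatureFit", "temperature_sensitivity",
    "PairedTTestResult", "paired_t_test",
]

FREE_RUNNING = 1
PMJ = 2
MYOCARDIUM = 3

REGION_NAMES = {FREE_RUNNING: "free_running", PMJ: "pmj", MYOCARDIUM: "myocardium"}


@dataclass
class RegionMask:
    """Integer label image on the map grid.

    Coding: 0 unassigned/background, 1 free-running fiber, 2 PMJ,
    3 myocardium.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        extra = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if extra:
            raise ValueError(f"unexpected labels in RegionMask: {sorted(extra)}")

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class RegionStats:
    """Mean and sample SD (n-1 denominator) of ihMTR over one ROI."""

    label: int
    mean_ihmtr: float
    sd_ihmtr: float
    n_voxels: int


class ContrastPair(NamedTuple):
    """Absolute ROI-mean differences, in absolute ihMTR units (%)."""

    contrast_fr_myo: float
    contrast_fr_pmj: float


def region_stats(ihmtr: IhMTRMap, mask: RegionMask, label: int) -> RegionStats:
    """Mean/SD of valid map voxels carrying ``label``.

    SD uses the n-1 denominator; a single-voxel region reports SD 0.
    """
    if isinstance(mask, np.ndarray):
        mask = RegionMask(mask)
    sel = mask.region(label) & ihmtr.valid
    values = ihmtr.values[sel]
    if values.size == 0:
        raise EmptyRegionError(
            f"region label {label} ({REGION_NAMES.get(label, '?')}) has no valid voxels")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return RegionStats(label=label, mean_ihmtr=mean, sd_ihmtr=sd,
                       n_voxels=int(values.size))


def contrasts(stats_fr: RegionStats, stats_pmj: RegionStats,
              stats_myo: RegionStats) -> ContrastPair:
    """Free-running-vs-myocardium and free-running-vs-PMJ contrasts."""
    return ContrastPair(
        contrast_fr_myo=abs(stats_fr.mean_ihmtr - stats_myo.mean_ihmtr),
        contrast_fr_pmj=abs(stats_fr.mean_ihmtr - stats_pmj.mean_ihmtr))


class AcquisitionResult(NamedTuple):
    """ROI statistics of one acquisition during protocol screening."""

    protocol: ProtocolParams
    free_running: RegionStats
    pmj: RegionStats
    myocardium: RegionStats


@dataclass
class ProtocolScore:
    """One ranked acquisition with full score provenance."""

    protocol: ProtocolParams
    mean_fr: float
    contrast_fr_myo: float
    contrast_fr_pmj: float
    z_mean_fr: float
    z_contrast_fr_myo: float
    z_contrast_fr_pmj: float
    score: float
    input_index: int


def _zscores(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def select_protocols(per_acquisition: Sequence[AcquisitionResult | tuple],
                     exclusion_threshold: float | None = None,
                     k: int = 3,
                     weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
                     ) -> list[ProtocolScore]:
    """Screen and rank candidate saturation protocols.

    Acquisitions whose free-running mean ihMTR falls below
    ``exclusion_threshold`` (default: the median free-running mean across the
    grid — the qualitative "low baseline" rule made explicit) are removed.
    Survivors are ranked by a transparent composite score, the weighted sum
    of z-scores of the free-running mean and the two contrasts; ties break on
    higher free-running-vs-PMJ contrast, then input order.  Returns the top
    ``k`` with all score components.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not per_acquisition:
        raise SelectionError("no acquisitions supplied")
    acqs = [AcquisitionResult(*a) if not isinstance(a, AcquisitionResult) else a
            for a in per_acquisition]
    mean_fr = np.array([a.free_running.mean_ihmtr for a in acqs])
    c_pair = [contrasts(a.free_running, a.pmj, a.myocardium) for a in acqs]
    c_myo = np.array([c.contrast_fr_myo for c in c_pair])
    c_pmj = np.array([c.contrast_fr_pmj for c in c_pair])

    if exclusion_threshold is None:
        exclusion_threshold = float(np.median(mean_fr))
    keep = mean_fr >= exclusion_threshold
    if not keep.any():
        raise SelectionError(
            f"every acquisition falls below exclusion threshold "
            f"{exclusion_threshold}; lower the threshold")

    idx = np.flatnonzero(keep)
    z_fr = _zscores(mean_fr[idx])
    z_myo = _zscores(c_myo[idx])
    z_pmj = _zscores(c_pmj[idx])
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    scores = w[0] * z_fr + w[1] * z_myo + w[2] * z_pmj

    ranked = [ProtocolScore(protocol=acqs[i].protocol, mean_fr=float(mean_fr[i]),
                            contrast_fr_myo=float(c_myo[i]),
                            contrast_fr_pmj=float(c_pmj[i]),
                            z_mean_fr=float(z_fr[j]),
                            z_contrast_fr_myo=float(z_myo[j]),
                            z_contrast_fr_pmj=float(z_pmj[j]),
                            score=float(scores[j]), input_index=int(i))
              for j, i in enumerate(idx)]
    ranked.sort(key=lambda r: (-r.score, -r.contrast_fr_pmj, r.input_index))
    return ranked[:k]


@dataclass
class TemperatureFit:
    """OLS line of ROI-mean ihMTR against sample temperature."""

    slope_pct_per_c: float
    intercept_pct: float
    slope_stderr: float
    n_points: int


def temperature_sensitivity(points: Sequence[tuple[float, float]]) -> TemperatureFit:
    """Least-squares slope (absolute ihMTR % per °C) of (temperature, ihMTR)
    points; requires at least two distinct temperatures."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (temperature, ihMTR) points")
    temps, values = pts[:, 0], pts[:, 1]
    if np.unique(temps).size < 2:
        raise DegenerateFitError("all temperatures identical; slope undefined")
    res = stats.linregress(temps, values)
    stderr = float(res.stderr) if pts.shape[0] > 2 else float("nan")
    return TemperatureFit(slope_pct_per_c=float(res.slope),
                          intercept_pct=float(res.intercept),
                          slope_stderr=stderr, n_points=int(pts.shape[0]))


@dataclass
class PairedTTestResult:
    """Two-sided paired t-test on differences d = a - b."""

    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> PairedTTestResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1, two-sided p.

    Zero-variance differences with nonzero mean give an infinite t and p
    reported as 0 with the ``degenerate`` flag set; identical pairs give
    t = 0, p = 1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0)
        t = math.inf if mean > 0 else -math.inf
        return PairedTTestResult(t=t, df=df, p=0.0, mean_diff=mean, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTTestResult(t=float(t), df=df, p=p, mean_diff=mean)
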