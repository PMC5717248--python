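"""Omega-angle statistics: cis/trans/twisted classification, normalized
1-degree distributions, windowed circular means, and distance-omega
correlation.

The peptide-bond omega angle sits near 180 deg (trans) or 0 deg (cis) at
equilibrium; the isomerisation transition state is a 90-deg twist.  The
classifier therefore labels |omega| near 90 (within a configurable margin,
default +/-30 deg) as "twisted", smaller magnitudes as "cis" and larger as
"trans".

Distributions follow the snapshot-counting procedure: each snapshot's omega
falls into a 1-degree bin [k, k+1), and bin counts are divided by the total
number of snapshots, so heights always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .geometry import ContactTimeSeries, OmegaSeries, wrap_angle

BOND_STATES = ("cis", "trans", "twisted")


def classify_omega(
    omega: float, twist_center: float = 90.0, twist_margin: float = 30.0
) -> str:
    """Label an omega angle (degrees) as cis, trans or twisted.

    |omega| < center - margin -> cis; |omega| > center + margin -> trans;
    otherwise twisted.  Symmetric in sign.
    """
    if not (-180.0 < omega <= 180.0):
        raise ValidationError(f"omega must lie in (-180, 180], got {omega}")
    a = abs(omega)
    if a < twist_center - twist_margin:
        return "cis"
    if a > twist_center + twist_margin:
        return "trans"
    return "twisted"


@dataclass
class OmegaDistribution:
    """Normalized 1-degree-binned omega distribution.

    ``edges`` are the 361 integer bin edges -180..180; ``heights[k]`` is the
    fraction of snapshots with omega in [edges[k], edges[k]+1) (the single
    value +180 counts in the last bin).
    """

    edges: np.ndarray     # (361,)
    heights: np.ndarray   # (360,), sums to 1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(self.heights < 0):
            raise ValidationError("distribution heights must be non-negative")
        if abs(self.heights.sum() - 1.0) > 1e-12:
            raise ValidationError("distribution heights must sum to 1")

    def mean(self) -> float:
        """Circular mean of the distribution using bin centres (degrees)."""
        centres = np.radians(self.edges[:-1] + 0.5)
        s = (self.heights * np.sin(centres)).sum()
        c = (self.heights * np.cos(centres)).sum()
        return wrap_angle(np.degrees(np.arctan2(s, c)))


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(len(times), dtype=bool)
    t0, t1 = window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValidationError(f"no snapshots inside window [{t0}, {t1}]")
    return mask


def omega_distribution(series: OmegaSeries, window=None) -> OmegaDistribution:
    """Normalized 1-degree histogram of an omega series over a time window."""
    angles = series.angles[_window_mask(series.times, window)]
    idx = np.floor(angles).astype(int)
    idx[idx == 180] = 179          # +180 maps to the last bin [179, 180)
    counts = np.bincount(idx + 180, minlength=360).astype(float)
    return OmegaDistribution(
        edges=np.arange(-180, 181, dtype=float), heights=counts / len(angles)
    )


def circular_mean(angles) -> float:
    """Directional mean of angles in degrees, reported in (-180, 180]."""
    m = float(stats.circmean(np.asarray(angles, dtype=float), high=180.0, low=-180.0))
    if m <= -180.0 + 1e-9:
        m += 360.0
    return wrap_angle(m)


def windowed_mean_omega(series: OmegaSeries, windows: Sequence) -> np.ndarray:
    """Circular mean omega (degrees) for each (t0, t1) window."""
    return np.array(
        [circular_mean(series.angles[_window_mask(series.times, w)]) for w in windows]
    )


def distance_omega_correlation(
    dist: ContactTimeSeries,
    omega: OmegaSeries,
    window_snapshots: int = 100,
) -> float:
    """Pearson correlation between windowed mean distance and mean omega.

    The two series must share timestamps.  They are cut into non-overlapping
    windows of ``window_snapshots`` snapshots (at least 3 full windows are
    required); the per-window arithmetic-mean distance is correlated with
    the per-window circular-mean omega.  Returns NaN when either windowed
    series has zero variance (correlation undefined).
    """
    if len(dist.times) != len(omega.times) or not np.allclose(dist.times, omega.times):
        raise ValidationError("distance and omega series must share timestamps")
    if window_snapshots < 1:
        raise ValidationError("window_snapshots must be >= 1")
    n_win = len(dist.times) // window_snapshots
    if n_win < 3:
        raise ValidationError(
            f"need >= 3 full windows, got {n_win} "
            f"({len(dist.times)} snapshots / {window_snapshots} per window)"
        )
    d_means = np.empty(n_win)
    o_means = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * window_snapshots, (k + 1) * window_snapshots)
        d_means[k] = dist.min_distance[sl].mean()
        o_means[k] = circular_mean(omega.angles[sl])
    if np.ptp(d_means) == 0 or np.ptp(o_means) == 0:
        return float("nan")
    return float(stats.pearsonr(d_means, o_means).statistic)
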