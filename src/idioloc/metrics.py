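"""Localization performance metrics.

The central quantity is the place stability index I_p of a particle
ensemble against the true position:

    I_p = 1 - D_post / (2 D_unif)

where D_post is the weighted mean Euclidean distance from the particles to
the true position and D_unif is the mean distance from a uniformly random
point of the traversable space to the true position (evaluated by
Monte Carlo quadrature, cached per arena).  The definition pins the two
anchors used throughout: a uniform ensemble scores 0.5 (chance) and a
point mass at the truth scores 1 (perfect); values below 0 mean worse than
chance and are not clamped.

For an arena with n-fold rotational symmetry the n rotated images of the
true position are geometrically indistinguishable, so the adjusted index
I_p* replaces the distance by the minimum over those n rotations (n = 1
reduces to I_p).

Directional performance across trials uses the circular variance
V = 1 - R of per-trial heading errors (0 = no error, -> 1 = uniformly
random), and convergence kinetics are summarized by t90, the time for the
median I_p series to complete 90% of its change from start to plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .arena import Arena
from .motion import wrap_diff

__all__ = [
    "MetricSeries",
    "KineticsResult",
    "place_stability_index",
    "adjusted_place_stability",
    "circular_variance",
    "t90",
    "heading_error",
    "uniform_quadrature_points",
    "mmss",
]

_QUADRATURE_N = 100_000
_QUADRATURE_SEED = 0x1D10C  # fixed: quadrature nodes are a numerical choice


def uniform_quadrature_points(arena: Arena, n: int = _QUADRATURE_N) -> np.ndarray:
    """Cached uniform sample of the traversable space used as quadrature
    nodes for the D_unif normalizer."""
    cached = getattr(arena, "_unif_quadrature", None)
    if cached is None or len(cached) < n:
        rng = np.random.default_rng(_QUADRATURE_SEED)
        cached = arena.sample_uniform(n, rng)
        arena._unif_quadrature = cached
        arena._unif_quadrature_xy = (np.ascontiguousarray(cached[:, 0]),
                                     np.ascontiguousarray(cached[:, 1]))
    return cached[:n]


def _quadrature_xy(arena: Arena) -> tuple[np.ndarray, np.ndarray]:
    uniform_quadrature_points(arena)
    return arena._unif_quadrature_xy


def _mean_dist_to(x: np.ndarray, y: np.ndarray, p: np.ndarray,
                  w: Optional[np.ndarray] = None) -> float:
    dx = x - p[0]
    dy = y - p[1]
    d = np.sqrt(dx * dx + dy * dy)
    return float(d.mean() if w is None else w @ d)


def _ens_arrays(ens) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(ens, "xy"):
        return ens.xy, ens.weights
    xy = np.asarray(ens, dtype=float)
    return xy, np.full(len(xy), 1.0 / len(xy))


def place_stability_index(ens, true_pos, arena: Arena) -> float:
    """I_p of an ensemble: 1 at a point mass on the truth, 0.5 for a
    uniform ensemble, unbounded below."""
    xy, w = _ens_arrays(ens)
    if len(xy) == 0:
        raise ValueError("empty ensemble")
    p = np.asarray(true_pos, dtype=float)
    d_post = _mean_dist_to(xy[:, 0], xy[:, 1], p, w)
    qx, qy = _quadrature_xy(arena)
    d_unif = _mean_dist_to(qx, qy, p)
    return 1.0 - d_post / (2.0 * d_unif)


def _rotations_of(p: np.ndarray, center: np.ndarray, n: int) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    c, s = np.cos(ang), np.sin(ang)
    v = p - center
    return np.stack([center[0] + c * v[0] - s * v[1],
                     center[1] + s * v[0] + c * v[1]], axis=1)


def adjusted_place_stability(ens, true_pos, arena: Arena, n: int = 1) -> float:
    """I_p* for an n-fold rotationally symmetric arena: distances are taken
    to the nearest of the n rotated images of the true position about the
    traversable centroid (normalizer recomputed the same way)."""
    if n < 1:
        raise ValueError("symmetry order n must be >= 1")
    if n == 1:
        return place_stability_index(ens, true_pos, arena)
    xy, w = _ens_arrays(ens)
    p = np.asarray(true_pos, dtype=float)
    targets = _rotations_of(p, arena.centroid, n)  # (n, 2)
    d_post = float(w @ np.linalg.norm(xy[:, None, :] - targets[None, :, :],
                                      axis=2).min(axis=1))
    q = uniform_quadrature_points(arena)
    d_unif = float(np.linalg.norm(q[:, None, :] - targets[None, :, :],
                                  axis=2).min(axis=1).mean())
    return 1.0 - d_post / (2.0 * d_unif)


def circular_variance(heading_errors) -> float:
    """V = 1 - R: 0 when all errors vanish, -> 1 for uniform errors."""
    e = np.asarray(heading_errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one heading error")
    r = math.hypot(float(np.cos(e).mean()), float(np.sin(e).mean()))
    return 1.0 - r


def heading_error(ens, true_theta: float) -> float:
    """Ensemble circular-mean heading minus the true heading, in (-pi, pi]."""
    from .pfilter import estimate_pose

    est = estimate_pose(ens)
    return float(wrap_diff(est.theta, true_theta))


@dataclass
class MetricSeries:
    """Across-trial localization metrics on a shared time grid."""

    t: np.ndarray
    Ip_median: np.ndarray
    Ip_q25: np.ndarray
    Ip_q75: np.ndarray
    V_theta: np.ndarray
    trials: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "Ip_median": self.Ip_median,
                             "Ip_q25": self.Ip_q25, "Ip_q75": self.Ip_q75,
                             "V_theta": self.V_theta})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_trials(cls, t: np.ndarray, ip: np.ndarray,
                    heading_errors: Optional[np.ndarray] = None) -> "MetricSeries":
        """Aggregate per-trial I_p curves ``ip`` of shape (trials, T) and
        optional per-trial heading errors of the same shape."""
        ip = np.asarray(ip, dtype=float)
        if heading_errors is None:
            v = np.full(ip.shape[1], np.nan)
        else:
            he = np.asarray(heading_errors, dtype=float)
            r = np.hypot(np.cos(he).mean(axis=0), np.sin(he).mean(axis=0))
            v = 1.0 - r
        return cls(t=np.asarray(t, dtype=float),
                   Ip_median=np.median(ip, axis=0),
                   Ip_q25=np.quantile(ip, 0.25, axis=0),
                   Ip_q75=np.quantile(ip, 0.75, axis=0),
                   V_theta=v, trials=ip.shape[0])


@dataclass
class KineticsResult:
    """Convergence kinetics of a median I_p series."""

    t90: float
    start_value: float
    plateau_value: float

    def __str__(self) -> str:
        return (f"t90 = {mmss(self.t90)} (start {self.start_value:.3f}, "
                f"plateau {self.plateau_value:.3f})")


def mmss(seconds: float) -> str:
    if not math.isfinite(seconds):
        return str(seconds)
    m, s = divmod(int(round(seconds)), 60)
    return f"{m}:{s:02d}"


def t90(series: Union[MetricSeries, np.ndarray],
        t: Optional[np.ndarray] = None) -> KineticsResult:
    """Time for the median I_p series to complete 90% of its change.

    The plateau is the median of the last 10% of the series; t90 is the
    first time the series moves at least 0.9 of the start-to-plateau
    change away from its start.  A flat series yields t90 = 0.
    """
    if isinstance(series, MetricSeries):
        y = series.Ip_median
        tt = series.t
    else:
        y = np.asarray(series, dtype=float)
        tt = np.asarray(t, dtype=float) if t is not None else np.arange(len(y), dtype=float)
    if len(y) < 10:
        raise ValueError("series must have at least 10 points")
    tail = max(1, int(math.ceil(0.1 * len(y))))
    plateau = float(np.median(y[-tail:]))
    start = float(y[0])
    delta = abs(plateau - start)
    if delta < 1e-12:
        return KineticsResult(t90=0.0, start_value=start, plateau_value=plateau)
    hit = np.flatnonzero(np.abs(y - start) >= 0.9 * delta)
    t_hit = float(tt[hit[0]]) if len(hit) else float(tt[-1])
    return KineticsResult(t90=t_hit, start_value=start, plateau_value=plateau)
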