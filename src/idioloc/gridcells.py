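"""Grid-cell spike simulation and spatial firing-field analysis.

A simulated grid cell fires as an inhomogeneous Poisson process whose rate
decreases with the distance between the agent's *estimated* position and
the nearest node of a hexagonal lattice (Gaussian tuning of width
``sigma_f`` around each node).  Spikes are georeferenced to the *true*
position, exactly as an experimenter plots them — so spatially regular
firing fields emerge only when the position estimate tracks the truth.
This turns time-averaged localization performance into the familiar
pictures of grid-cell physiology.

Analysis follows standard practice: occupancy-normalized, Gaussian-
smoothed rate maps; the spatial autocorrelogram with the rotational
gridness score (correlation at 60/120 degrees minus correlation at
30/90/150 degrees, over an annulus excluding the central peak); Skaggs
spatial information in bits/spike; and an optimal-rescaling search between
two rate maps used to quantify grid rescaling under arena deformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage, signal

from .motion import TrueTrajectory, as_rng

__all__ = [
    "GridModel",
    "SpikeList",
    "RateMap",
    "simulate_spikes",
    "rate_map",
    "autocorrelogram",
    "gridness",
    "spatial_information",
    "optimal_rescaling",
]


@dataclass
class GridModel:
    """Hexagonal-lattice Gaussian tuning model of a grid cell.

    spacing: lattice constant (cm); orientation: lattice rotation (rad);
    phase: 2-vector lattice offset (cm); lambda_max: peak rate (Hz);
    sigma_f: field width (cm).
    """

    spacing: float = 30.0
    orientation: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)
    lambda_max: float = 20.0
    sigma_f: float = 6.0

    def __post_init__(self):
        if self.spacing <= 0 or self.sigma_f <= 0:
            raise ValueError("spacing and sigma_f must be positive")

    @classmethod
    def random_cell(cls, rng, spacing: float = 30.0, **kw) -> "GridModel":
        """A cell with random lattice orientation and phase."""
        rng = as_rng(rng)
        phase = rng.uniform(0.0, spacing, size=2)
        return cls(spacing=spacing, orientation=rng.uniform(0, math.pi / 3),
                   phase=(float(phase[0]), float(phase[1])), **kw)

    def nodes(self, bounds: tuple[float, float, float, float],
              margin: Optional[float] = None) -> np.ndarray:
        """Lattice nodes covering a bounding box (x0, y0, x1, y1)."""
        x0, y0, x1, y1 = bounds
        m = self.spacing if margin is None else margin
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        v1 = self.spacing * np.array([c, s])
        v2 = self.spacing * np.array([math.cos(self.orientation + math.pi / 3.0),
                                      math.sin(self.orientation + math.pi / 3.0)])
        r = math.hypot(max(abs(x0), abs(x1)) + m, max(abs(y0), abs(y1)) + m)
        k = int(math.ceil(r / self.spacing)) + 2
        i, j = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
        pts = (i.ravel()[:, None] * v1 + j.ravel()[:, None] * v2
               + np.asarray(self.phase))
        keep = ((pts[:, 0] >= x0 - m) & (pts[:, 0] <= x1 + m)
                & (pts[:, 1] >= y0 - m) & (pts[:, 1] <= y1 + m))
        return pts[keep]

    def rate_at(self, positions: np.ndarray,
                bounds: Optional[tuple] = None) -> np.ndarray:
        """Firing rate (Hz) at positions: Gaussian of distance to the
        nearest lattice node."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if bounds is None:
            x0, y0 = positions.min(axis=0)
            x1, y1 = positions.max(axis=0)
            bounds = (x0, y0, x1, y1)
        nodes = self.nodes(bounds)
        d2 = ((positions[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        return self.lambda_max * np.exp(-d2 / (2.0 * self.sigma_f ** 2))


@dataclass
class SpikeList:
    """Spike times with the true positions at which they occurred."""

    t: np.ndarray
    xy: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.t, "x_true": self.xy[:, 0],
                      "y_true": self.xy[:, 1]}).to_csv(path, index=False)


def simulate_spikes(est_positions: np.ndarray, true_positions: np.ndarray,
                    gm: GridModel, dt: float,
                    seed: Union[int, np.random.Generator, None] = None,
                    times: Optional[np.ndarray] = None) -> SpikeList:
    """Poisson spikes driven by the estimated position, georeferenced to
    the true position.

    Per step the count is Poisson(lambda dt) with lambda the grid-tuned
    rate at the *estimated* position; each spike is recorded at the *true*
    position of that step.
    """
    est = np.atleast_2d(np.asarray(est_positions, dtype=float))
    tru = np.atleast_2d(np.asarray(true_positions, dtype=float))
    if len(est) != len(tru):
        raise ValueError("estimated and true position sequences must align")
    rng = as_rng(seed)
    if gm.lambda_max <= 0:
        return SpikeList(t=np.empty(0), xy=np.empty((0, 2)))
    allpos = np.concatenate([est, tru], axis=0)
    x0, y0 = allpos.min(axis=0)
    x1, y1 = allpos.max(axis=0)
    lam = gm.rate_at(est, bounds=(x0, y0, x1, y1))
    counts = rng.poisson(lam * dt)
    if times is None:
        times = np.arange(len(est)) * dt
    rep = np.repeat(np.arange(len(est)), counts)
    return SpikeList(t=times[rep], xy=tru[rep])


@dataclass
class RateMap:
    """Occupancy-normalized spatial firing map on a pixel grid.

    ``rate`` is NaN on unvisited pixels; ``occupancy`` is seconds per
    pixel; raw ``spike_counts`` are conserved against the spike list.
    """

    rate: np.ndarray          # (ny, nx), Hz, NaN where unvisited
    occupancy: np.ndarray     # (ny, nx), s
    spike_counts: np.ndarray  # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    pixel_size: float

    @property
    def mask(self) -> np.ndarray:
        return self.occupancy > 0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x_edges[0], self.x_edges[-1], self.y_edges[0], self.y_edges[-1])


def rate_map(spikes: SpikeList, traj: TrueTrajectory, pixel_size: float = 2.0,
             smoothing_sd: float = 1.0,
             extent: Optional[tuple] = None) -> RateMap:
    """Bin spikes and occupancy on a pixel grid and smooth.

    Smoothing divides the Gaussian-filtered spike counts by the equally
    filtered occupancy (restricted to visited pixels), the standard
    adaptive treatment that avoids bleeding rate into unvisited space.
    ``smoothing_sd`` is in pixels; 0 disables smoothing.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if extent is None:
        x0, y0 = traj.xy.min(axis=0)
        x1, y1 = traj.xy.max(axis=0)
    else:
        x0, y0, x1, y1 = extent
    xe = np.arange(x0, x1 + pixel_size, pixel_size)
    ye = np.arange(y0, y1 + pixel_size, pixel_size)
    occ, _, _ = np.histogram2d(traj.xy[:, 1], traj.xy[:, 0], bins=[ye, xe])
    occ *= traj.dt
    cnt, _, _ = np.histogram2d(spikes.xy[:, 1], spikes.xy[:, 0], bins=[ye, xe])
    mask = occ > 0
    if smoothing_sd > 0:
        sm_cnt = ndimage.gaussian_filter(cnt * mask, smoothing_sd)
        sm_occ = ndimage.gaussian_filter(occ * mask, smoothing_sd)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(mask & (sm_occ > 0), sm_cnt / np.maximum(sm_occ, 1e-12), np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(mask, cnt / np.maximum(occ, 1e-12), np.nan)
    return RateMap(rate=rate, occupancy=occ, spike_counts=cnt,
                   x_edges=xe, y_edges=ye, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Autocorrelogram and gridness
# ---------------------------------------------------------------------------

def autocorrelogram(rmap: Union[RateMap, np.ndarray]) -> np.ndarray:
    """Masked-Pearson spatial autocorrelogram.

    At each spatial lag the correlation is the Pearson coefficient over
    the pixels where both shifted copies are defined; lags supported by
    fewer than 20 pixel pairs are NaN.
    """
    f = rmap.rate if isinstance(rmap, RateMap) else np.asarray(rmap, dtype=float)
    mask = np.isfinite(f).astype(float)
    z = np.nan_to_num(f, nan=0.0)

    def xcorr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = xcorr(mask, mask)
    sx = xcorr(z, mask)
    sy = xcorr(mask, z)
    sxy = xcorr(z, z)
    sxx = xcorr(z * z, mask)
    syy = xcorr(mask, z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt(np.maximum(n * sxx - sx ** 2, 0.0)
                      * np.maximum(n * syy - sy ** 2, 0.0))
        ac = num / den
    ac[n < 20] = np.nan
    return ac


def _annulus(ac: np.ndarray) -> Optional[tuple[np.ndarray, float, float]]:
    """Annulus isolating the six nearest autocorrelogram side peaks.

    Inner radius = extent of the central peak (first radius where the
    azimuthal mean correlation drops below 0.1); outer radius = 1.25x the
    modal side-peak distance.  Returns None when fewer than 3 side peaks
    are detectable.
    """
    cy, cx = np.array(ac.shape) // 2
    yy, xx = np.indices(ac.shape)
    r = np.hypot(yy - cy, xx - cx)
    rmax = int(r[np.isfinite(ac)].max()) if np.isfinite(ac).any() else 0
    prof = np.array([np.nanmean(ac[(r >= k) & (r < k + 1)])
                     if np.isfinite(ac[(r >= k) & (r < k + 1)]).any() else np.nan
                     for k in range(rmax)])
    below = np.flatnonzero(prof < 0.1)
    if len(below) == 0:
        return None
    r_inner = float(below[0])
    # side peaks: local maxima outside the central peak
    acz = np.nan_to_num(ac, nan=-1.0)
    local_max = (ndimage.maximum_filter(acz, size=5) == acz) & (acz > 0.1) & (r > r_inner)
    py, px = np.nonzero(local_max)
    if len(py) < 3:
        return None
    dists = np.hypot(py - cy, px - cx)
    order = np.argsort(dists)
    near = dists[order[:min(6, len(order))]]
    modal = float(np.median(near))
    r_outer = 1.25 * modal
    annulus = (r >= r_inner) & (r <= r_outer)
    return annulus, r_inner, r_outer


def gridness(rmap: Union[RateMap, np.ndarray]) -> float:
    """Rotational gridness score of a rate map.

    min(correlation at 60, 120 deg) - max(correlation at 30, 90, 150 deg)
    between the autocorrelogram and its rotations, over the side-peak
    annulus.  Returns NaN when fewer than 3 side peaks are detectable.
    """
    ac = autocorrelogram(rmap) if not (isinstance(rmap, np.ndarray)
                                       and rmap.ndim == 2 and _looks_like_ac(rmap)) else rmap
    res = _annulus(ac)
    if res is None:
        return float("nan")
    annulus, _, _ = res
    base = np.nan_to_num(ac, nan=0.0)
    valid0 = np.isfinite(ac)

    def rot_corr(angle):
        rot = ndimage.rotate(base, angle, reshape=False, order=1, cval=0.0)
        vrot = ndimage.rotate(valid0.astype(float), angle, reshape=False,
                              order=1, cval=0.0) > 0.5
        sel = annulus & valid0 & vrot
        a, b = base[sel], rot[sel]
        if len(a) < 20 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    on = [rot_corr(60), rot_corr(120)]
    off = [rot_corr(30), rot_corr(90), rot_corr(150)]
    if any(np.isnan(on)) or any(np.isnan(off)):
        return float("nan")
    return min(on) - max(off)


def _looks_like_ac(a: np.ndarray) -> bool:
    # heuristically: an autocorrelogram has a ~1.0 central value and odd-ish
    # full-correlation shape; rate maps passed here are never centred at 1
    cy, cx = np.array(a.shape) // 2
    v = a[cy, cx]
    return np.isfinite(v) and abs(v - 1.0) < 1e-6


def spatial_information(rmap: RateMap) -> float:
    """Skaggs information content in bits per spike:
    sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar)."""
    m = rmap.mask & np.isfinite(rmap.rate)
    p = rmap.occupancy[m] / rmap.occupancy[m].sum()
    lam = rmap.rate[m]
    lbar = float((p * lam).sum())
    if lbar <= 0:
        raise ValueError("mean rate must be positive")
    ratio = lam / lbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.maximum(ratio, 1e-300)), 0.0)
    return float(terms.sum())


def optimal_rescaling(test_map: RateMap, reference_map: RateMap,
                      s_range: tuple[float, float, float] = (0.8, 1.3, 0.01)
                      ) -> tuple[float, float, float]:
    """Scale factors (sx, sy) maximizing the normalized correlation between
    the reference map and the test map rescaled about its centre.

    Returns (sx, sy, peak correlation); raises on flat maps.
    """
    lo, hi, step = s_range
    scales = np.round(np.arange(lo, hi + step / 2, step), 10)
    ref = reference_map.rate
    tst = test_map.rate
    if np.nanstd(ref) == 0 or np.nanstd(tst) == 0:
        raise ValueError("flat rate map: rescaling undefined")
    ny, nx = ref.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.indices((ny, nx)).astype(float)
    ty, tx = np.array(tst.shape, dtype=float)
    tcy, tcx = (ty - 1) / 2.0, (tx - 1) / 2.0
    px_ratio = test_map.pixel_size / reference_map.pixel_size
    best = (1.0, 1.0, -np.inf)
    tz = np.nan_to_num(tst, nan=np.nan)
    for sx in scales:
        for sy in scales:
            # (sx, sy) is the test map's stretch relative to the reference:
            # a feature at reference coordinate u sits at test coordinate
            # sx * u, so sample the test there
            sample_x = (xx - cx) * sx / px_ratio + tcx
            sample_y = (yy - cy) * sy / px_ratio + tcy
            samp = ndimage.map_coordinates(np.nan_to_num(tz, nan=-1e9),
                                           [sample_y, sample_x], order=1,
                                           cval=-1e9)
            sel = np.isfinite(ref) & (samp > -1e8)
            if sel.sum() < 20:
                continue
            a, b = ref[sel], samp[sel]
            if a.std() == 0 or b.std() == 0:
                continue
            c = float(np.corrcoef(a, b)[0, 1])
            if c > best[2]:
                best = (float(sx), float(sy), c)
    if not np.isfinite(best[2]):
        raise ValueError("no valid overlap between maps")
    return best
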