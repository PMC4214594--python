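"""Trajectory generation and the rodent self-motion error model.

True trajectories are discrete-time pose sequences generated under a
movement policy (correlated random walk, or thigmotactic wall following).
They are then corrupted into the self-motion streams an agent would
perceive:

* iPI (idiothetic path integration): per-step heading *change* plus a
  Wiener-process drift — heading-error variance grows linearly in time at
  intensity ``sigma_theta**2`` (rad^2/s), matching head-direction drift
  recorded in darkness.
* aPI (allothetic / compass-aided PI): the absolute heading is reported
  exactly each step (a compass resets orientation error), leaving only
  step-length noise.

Step lengths carry multiplicative Gaussian noise of fractional SD
``sigma_step`` in both modes.  Optional channels: sparse compass readings
(Poisson-timed, Gaussian heading error) and boundary-contact flags.

The error model carries separate ``filter_*`` noise parameters so the
particle filter's assumed uncertainty can be deliberately mismatched from
the generative one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
from shapely.geometry import Polygon

from .arena import Arena, BodyShape, POINT_BODY

__all__ = [
    "MotionConfig",
    "ErrorModel",
    "TrueTrajectory",
    "DisplacementEstimate",
    "DisplacementStream",
    "generate_trajectory",
    "corrupt",
    "detect_contacts",
    "wrap_angle",
    "as_rng",
]


def wrap_angle(theta):
    """Wrap angles to [0, 2 pi)."""
    return np.mod(theta, 2.0 * np.pi)


def wrap_diff(a, b):
    """Signed smallest angular difference a - b in (-pi, pi]."""
    return (np.asarray(a) - np.asarray(b) + np.pi) % (2.0 * np.pi) - np.pi


def as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MotionConfig:
    """Movement policy parameters.

    dt: step interval (s).  speed_mean: mean running speed (cm/s).
    turn_sd: per-step turning SD (rad) of the correlated random walk.
    policy: 'random' or 'thigmotactic'.  wall_offset: distance from the
    boundary tracked by the thigmotactic policy (cm).
    """

    dt: float = 0.5
    speed_mean: float = 15.0
    turn_sd: float = math.radians(30.0)
    policy: str = "random"
    wall_offset: float = 5.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.speed_mean < 0:
            raise ValueError("speed_mean must be nonnegative")
        if self.policy not in ("random", "thigmotactic"):
            raise ValueError(f"unknown policy {self.policy!r}")


_DEFAULTS_RESOURCE = "error_defaults.json"


def _load_calibrated_defaults() -> dict:
    try:
        text = resources.files("idioloc").joinpath("data", _DEFAULTS_RESOURCE).read_text()
        return json.loads(text)
    except (FileNotFoundError, ModuleNotFoundError):
        return {"sigma_theta": 0.15, "sigma_step": 0.2}


@dataclass
class ErrorModel:
    """Self-motion noise model.

    sigma_theta: Wiener heading-drift intensity (rad * s^-1/2); the
    per-step heading-change error is N(0, sigma_theta^2 * dt).
    sigma_step: fractional step-length noise SD.
    mode: 'iPI' (heading changes reported) or 'aPI' (absolute heading
    reported exactly each step).
    compass_rate: mean compass readings per second (0 = never);
    compass_sd: compass reading error SD (rad).
    contact_enabled / contact_tol: emit boundary-contact flags when the
    body perimeter comes within contact_tol cm of a boundary.
    filter_sigma_theta / filter_sigma_step: the noise the particle filter
    assumes; default None means matched to the generative values.
    """

    sigma_theta: float = 0.15
    sigma_step: float = 0.2
    mode: str = "iPI"
    compass_rate: float = 0.0
    compass_sd: float = math.radians(15.0)
    contact_enabled: bool = False
    contact_tol: float = 2.0
    filter_sigma_theta: Optional[float] = None
    filter_sigma_step: Optional[float] = None

    def __post_init__(self):
        if min(self.sigma_theta, self.sigma_step, self.compass_sd) < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.mode not in ("iPI", "aPI"):
            raise ValueError(f"mode must be 'iPI' or 'aPI', got {self.mode!r}")

    @property
    def assumed_sigma_theta(self) -> float:
        return self.sigma_theta if self.filter_sigma_theta is None else self.filter_sigma_theta

    @property
    def assumed_sigma_step(self) -> float:
        return self.sigma_step if self.filter_sigma_step is None else self.filter_sigma_step

    @classmethod
    def calibrated(cls, mode: str = "iPI", **overrides) -> "ErrorModel":
        """Packaged calibrated noise defaults (see experiments.calibrate_noise)."""
        d = _load_calibrated_defaults()
        kw = dict(sigma_theta=d["sigma_theta"], sigma_step=d["sigma_step"], mode=mode)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrueTrajectory:
    """Discrete-time pose sequence: t (s), xy (cm), theta (rad, wrapped)."""

    t: np.ndarray
    xy: np.ndarray
    theta: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.xy, axis=0), axis=1)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.t, "x": self.xy[:, 0], "y": self.xy[:, 1],
                      "theta": self.theta}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrueTrajectory":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(),
                   xy=df[["x", "y"]].to_numpy(),
                   theta=df["theta"].to_numpy())


@dataclass
class DisplacementEstimate:
    """One step's self-motion report (iPI: dtheta_hat; aPI: theta_hat)."""

    t: float
    step_hat: float
    dtheta_hat: Optional[float] = None
    theta_hat: Optional[float] = None
    compass_obs: Optional[float] = None
    contact_obs: Optional[bool] = None


@dataclass
class DisplacementStream:
    """Struct-of-arrays sequence of per-step displacement estimates.

    ``heading`` holds dtheta_hat (mode iPI) or absolute theta_hat (aPI).
    ``compass_obs`` is NaN at steps without a compass reading;
    ``contact_obs`` is a float array (1.0 contact, 0.0 no contact, NaN when
    no contact channel is observed at that step).
    """

    t: np.ndarray
    heading: np.ndarray
    step_hat: np.ndarray
    mode: str
    compass_obs: Optional[np.ndarray] = None
    contact_obs: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> DisplacementEstimate:
        return DisplacementEstimate(
            t=float(self.t[i]),
            step_hat=float(self.step_hat[i]),
            dtheta_hat=float(self.heading[i]) if self.mode == "iPI" else None,
            theta_hat=float(self.heading[i]) if self.mode == "aPI" else None,
            compass_obs=(None if self.compass_obs is None or np.isnan(self.compass_obs[i])
                         else float(self.compass_obs[i])),
            contact_obs=(None if self.contact_obs is None or np.isnan(self.contact_obs[i])
                         else bool(self.contact_obs[i])),
        )

    def to_csv(self, path, seed=None) -> None:
        import pandas as pd

        col = "dtheta_hat" if self.mode == "iPI" else "theta_hat"
        d = {"t": self.t, col: self.heading, "step_hat": self.step_hat}
        if self.compass_obs is not None:
            d["compass_obs"] = self.compass_obs
        if self.contact_obs is not None:
            d["contact_obs"] = self.contact_obs
        pd.DataFrame(d).to_csv(path, index=False)
        if seed is not None:
            Path(str(path) + ".json").write_text(json.dumps({"seed": seed, "mode": self.mode}))


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _pose_valid(arena: Arena, p, theta, body: BodyShape, n_perimeter: int = 24) -> bool:
    geom = arena.geometry
    if not geom.contains_points(np.asarray(p, float)[None, :])[0]:
        return False
    if body.is_point:
        return True
    pts = body.perimeter_points(np.asarray(p, float), theta, n=n_perimeter)
    return bool(geom.contains_points(pts).all())


def _move_blocked(arena: Arena, p0, th0, p1, th1, body: BodyShape,
                  n_sweep: int = 16) -> bool:
    """True when moving the body from pose (p0, th0) to (p1, th1) crosses a
    boundary, sweeping sampled perimeter points along straight paths."""
    geom = arena.geometry
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if body.is_point:
        return bool(geom.segments_cross(p0[None, :], p1[None, :])[0])
    a = body.perimeter_points(p0, th0, n=n_sweep)
    b = body.perimeter_points(p1, th1, n=n_sweep)
    if geom.segments_cross(a, b).any():
        return True
    return bool(geom.segments_cross(p0[None, :], p1[None, :])[0])


def _sample_start(arena: Arena, body: BodyShape, rng: np.random.Generator):
    for _ in range(5000):
        p = arena.sample_uniform(1, rng)[0]
        th = rng.uniform(0.0, 2.0 * np.pi)
        if _pose_valid(arena, p, th, body):
            return p, th
    raise ValueError("body cannot fit in arena")


def _redraw_inward(arena: Arena, p, body: BodyShape, step: float,
                   rng: np.random.Generator, tries: int = 60):
    """Draw a heading uniformly until a short probe step stays inside."""
    probe = min(step, 2.0)
    for _ in range(tries):
        th = rng.uniform(0.0, 2.0 * np.pi)
        q = p + probe * np.array([math.cos(th), math.sin(th)])
        if (_pose_valid(arena, q, th, body)
                and not _move_blocked(arena, p, th, q, th, body)):
            return th
    return None


def _generate_random(arena: Arena, cfg: MotionConfig, body: BodyShape,
                     n_steps: int, rng: np.random.Generator,
                     start=None) -> TrueTrajectory:
    xy = np.empty((n_steps + 1, 2))
    th = np.empty(n_steps + 1)
    if start is None:
        p, heading = _sample_start(arena, body, rng)
    else:
        p = np.asarray(start, dtype=float)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        if not _pose_valid(arena, p, heading, body):
            raise ValueError("requested start pose does not fit in the arena")
    xy[0], th[0] = p, heading
    # the recorded heading is always the direction of the net per-step
    # displacement, so (heading change, step length) streams are exactly
    # invertible by straight-line propagation; the policy keeps its own
    # heading state to steer proposals (they differ only at wall steps)
    h_policy = heading
    mean_step = cfg.speed_mean * cfg.dt
    for i in range(n_steps):
        dth = rng.normal(0.0, cfg.turn_sd)
        length = max(rng.normal(mean_step, 0.25 * mean_step), 0.0)
        new_th = wrap_angle(h_policy + dth)
        u = np.array([math.cos(new_th), math.sin(new_th)])
        q = xy[i] + length * u
        if _pose_valid(arena, q, new_th, body) and not _move_blocked(
                arena, xy[i], th[i], q, new_th, body):
            xy[i + 1], th[i + 1] = q, new_th
            h_policy = new_th
            continue
        # wall encounter: truncate the step at the wall, redraw an inward
        # heading, and spend the remaining step length in the new direction
        f_used = 0.0
        stop = xy[i]
        for f in (0.85, 0.65, 0.45, 0.25, 0.1):
            q = xy[i] + f * length * u
            if _pose_valid(arena, q, new_th, body) and not _move_blocked(
                    arena, xy[i], th[i], q, new_th, body):
                stop, f_used = q, f
                break
        redraw = _redraw_inward(arena, stop, body, length, rng)
        end = stop
        rest = (1.0 - f_used) * length
        if redraw is not None and rest > 0:
            v = np.array([math.cos(redraw), math.sin(redraw)])
            q = stop + rest * v
            if _pose_valid(arena, q, redraw, body) and not _move_blocked(
                    arena, stop, redraw, q, redraw, body):
                end = q
        net = end - xy[i]
        if np.hypot(net[0], net[1]) > 1e-9:
            th_net = wrap_angle(math.atan2(net[1], net[0]))
        else:
            th_net = th[i]
        if end is not stop and not body.is_point and not _pose_valid(
                arena, end, th_net, body):
            # body oriented along the net direction would poke outside:
            # keep only the truncated segment (net direction = new_th)
            end, th_net = stop, (new_th if f_used > 0 else th[i])
        xy[i + 1] = end
        th[i + 1] = th_net
        h_policy = redraw if redraw is not None else th[i + 1]
    t = np.arange(n_steps + 1) * cfg.dt
    return TrueTrajectory(t=t, xy=xy, theta=wrap_angle(th))


def _offset_ring(arena: Arena, offset: float) -> np.ndarray:
    eroded = arena.region.buffer(-offset)
    if eroded.is_empty:
        raise ValueError(f"wall offset {offset} cm leaves no traversable ring")
    if eroded.geom_type == "MultiPolygon":
        eroded = max(eroded.geoms, key=lambda g: g.area)
    ring = np.asarray(eroded.exterior.coords)
    if not Polygon(ring).exterior.is_ccw:
        ring = ring[::-1]
    return ring


def _generate_thigmotactic(arena: Arena, cfg: MotionConfig, body: BodyShape,
                           n_steps: int, rng: np.random.Generator) -> TrueTrajectory:
    ring = _offset_ring(arena, cfg.wall_offset)
    seg = np.diff(ring, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    direction = 1.0 if rng.random() < 0.5 else -1.0
    s = rng.uniform(0.0, total)
    mean_step = cfg.speed_mean * cfg.dt
    xy = np.empty((n_steps + 1, 2))
    th = np.empty(n_steps + 1)
    cen = arena.centroid
    for i in range(n_steps + 1):
        s_mod = s % total
        j = min(np.searchsorted(cum, s_mod, side="right") - 1, len(seg) - 1)
        frac = (s_mod - cum[j]) / max(seg_len[j], 1e-12)
        p = ring[j] + frac * seg[j]
        tangent = math.atan2(seg[j][1], seg[j][0])
        heading = wrap_angle(tangent if direction > 0 else tangent + math.pi)
        # finite bodies at sharp offset-ring corners can poke outside: nudge
        # toward the centroid until the pose fits
        for _ in range(8):
            if _pose_valid(arena, p, heading, body):
                break
            p = p + 0.15 * (cen - p) / max(np.linalg.norm(cen - p), 1e-9)
        xy[i] = p
        s += direction * max(rng.normal(mean_step, 0.15 * mean_step), 0.0)
    # recorded headings are net per-step displacement directions (chords of
    # the offset ring), keeping displacement streams exactly invertible
    d = np.diff(xy, axis=0)
    moved = np.hypot(d[:, 0], d[:, 1]) > 1e-9
    th[1:] = np.where(moved, np.arctan2(d[:, 1], d[:, 0]), 0.0)
    for i in range(1, n_steps + 1):
        if not moved[i - 1]:
            th[i] = th[i - 1]
    th[0] = th[1] if n_steps >= 1 else 0.0
    t = np.arange(n_steps + 1) * cfg.dt
    return TrueTrajectory(t=t, xy=xy, theta=wrap_angle(th))


def generate_trajectory(arena: Arena, cfg: MotionConfig, body: BodyShape = POINT_BODY,
                        duration: float = 60.0,
                        seed: Union[int, np.random.Generator, None] = None,
                        start=None) -> TrueTrajectory:
    """Generate a true pose sequence of ``duration`` seconds at ``cfg.dt`` spacing.

    The random policy is a correlated random walk whose steps are truncated
    at walls with the heading redrawn from inward directions; the
    thigmotactic policy follows the boundary at ``cfg.wall_offset`` with
    small heading noise.  Every pose keeps the body inside the traversable
    space.  ``start`` optionally fixes the initial position (random policy
    only; the initial heading stays random).
    """
    if duration < cfg.dt:
        raise ValueError("duration must be at least one step interval")
    rng = as_rng(seed)
    n_steps = int(round(duration / cfg.dt))
    if cfg.policy == "random":
        return _generate_random(arena, cfg, body, n_steps, rng, start=start)
    return _generate_thigmotactic(arena, cfg, body, n_steps, rng)


# ---------------------------------------------------------------------------
# Corruption into self-motion streams
# ---------------------------------------------------------------------------

def corrupt(traj: TrueTrajectory, em: ErrorModel,
            seed: Union[int, np.random.Generator, None] = None,
            arena: Optional[Arena] = None,
            body: BodyShape = POINT_BODY) -> DisplacementStream:
    """Corrupt a true trajectory into the agent's perceived motion stream.

    iPI reports per-step heading changes with additive Wiener increments
    N(0, sigma_theta^2 dt); aPI reports the absolute heading exactly.  Both
    report step lengths with multiplicative noise 1 + N(0, sigma_step^2).
    Compass observations are emitted at Poisson(compass_rate * dt) events
    with Gaussian error; contact flags need ``arena`` and use the true
    body-to-boundary distance.
    """
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least 2 poses")
    rng = as_rng(seed)
    dt = traj.dt
    n = len(traj) - 1
    true_dtheta = wrap_diff(traj.theta[1:], traj.theta[:-1])
    true_len = traj.step_lengths()
    if em.mode == "iPI":
        heading = true_dtheta + rng.normal(0.0, em.sigma_theta * math.sqrt(dt), size=n)
    else:
        heading = traj.theta[1:].copy()
    step_hat = np.maximum(true_len * (1.0 + rng.normal(0.0, em.sigma_step, size=n)), 0.0)
    compass = None
    if em.compass_rate > 0:
        events = rng.poisson(em.compass_rate * dt, size=n) > 0
        compass = np.full(n, np.nan)
        k = int(events.sum())
        compass[events] = wrap_angle(traj.theta[1:][events]
                                     + rng.normal(0.0, em.compass_sd, size=k))
    contact = None
    if em.contact_enabled:
        if arena is None:
            raise ValueError("contact_enabled requires the arena")
        contact = detect_contacts(traj, arena, body, em.contact_tol)[1:].astype(float)
    return DisplacementStream(t=traj.t[1:].copy(), heading=heading,
                              step_hat=step_hat, mode=em.mode,
                              compass_obs=compass, contact_obs=contact)


def detect_contacts(traj: TrueTrajectory, arena: Arena,
                    body: BodyShape = POINT_BODY, tol: float = 2.0,
                    n_perimeter: int = 24) -> np.ndarray:
    """Boolean flag per pose: body perimeter within ``tol`` cm of a boundary."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    geom = arena.geometry
    if body.is_point:
        return geom.distance_to_boundary(traj.xy) <= tol
    pts = body.perimeter_points(traj.xy, traj.theta, n=n_perimeter)  # (T, K, 2)
    d = geom.distance_to_boundary(pts.reshape(-1, 2)).reshape(len(traj), n_perimeter)
    return d.min(axis=1) <= tol
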