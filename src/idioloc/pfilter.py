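"""Sequential Monte Carlo pose estimation against a remembered boundary map.

The filter maintains N weighted pose hypotheses ("particles").  Each step,
every particle independently tracks the reported displacement, perturbed by
the filter's assumed motion noise.  Particles whose movement is
incompatible with the remembered arena are culled and the survivors are
multinomially cloned back to N, so localization emerges purely from the
interplay of diffusive uncertainty growth (self-motion noise) and
hypothesis culling (boundary-map constraint) — no external cue is sensed.

Three boundary models are available:

* ``crossing`` — a particle is culled when its step segment crosses the
  outer boundary, a barrier or a void boundary (the full internal model of
  boundary crossing);
* ``discrete_endpoint`` — only the step endpoint must lie in traversable
  space (ignores barrier crossings, the degraded discrete-step model);
* ``none`` — no boundary test (pure path integration).

Retrospective inference is provided two ways: offline reverse replay of a
stored displacement sequence from the final ensemble, and online backward
inference via per-particle ancestral lineage records, which needs no
stored displacements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .arena import Arena, BodyShape, POINT_BODY
from .motion import (DisplacementEstimate, DisplacementStream, ErrorModel,
                     as_rng, wrap_angle)

__all__ = [
    "ParticleEnsemble",
    "FilterConfig",
    "PoseEstimate",
    "init_ensemble",
    "step",
    "apply_compass",
    "apply_contact",
    "estimate_pose",
    "run_filter",
    "propagate_pure_pi",
    "reverse_replay",
    "backward_inference_online",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger("idioloc")


@dataclass
class ParticleEnsemble:
    """N weighted pose hypotheses, with optional ancestral-pose lineage.

    ``lineage_xy``/``lineage_theta`` record, per particle, the pose its
    ancestor held at time 0; cloning copies the record, so at any time the
    lineage distribution is a Monte Carlo estimate of the time-0 posterior
    given all evidence so far.
    """

    xy: np.ndarray            # (N, 2)
    theta: np.ndarray         # (N,)
    weights: np.ndarray       # (N,), nonnegative, sum 1
    t: float = 0.0
    lineage_xy: Optional[np.ndarray] = None
    lineage_theta: Optional[np.ndarray] = None
    n_reinits: int = 0        # total-cull reinitializations seen so far

    @property
    def n(self) -> int:
        return len(self.theta)

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(
            xy=self.xy.copy(), theta=self.theta.copy(), weights=self.weights.copy(),
            t=self.t,
            lineage_xy=None if self.lineage_xy is None else self.lineage_xy.copy(),
            lineage_theta=None if self.lineage_theta is None else self.lineage_theta.copy(),
            n_reinits=self.n_reinits)

    def lineage_ensemble(self) -> "ParticleEnsemble":
        """The time-0 pose distribution implied by surviving lineages."""
        if self.lineage_xy is None:
            raise ValueError("lineage tracking was not enabled")
        return ParticleEnsemble(xy=self.lineage_xy.copy(),
                                theta=self.lineage_theta.copy(),
                                weights=self.weights.copy(), t=0.0)


@dataclass
class FilterConfig:
    """Particle filter configuration.

    ``map_arena`` is the remembered map, which may differ from the arena
    the agent actually moves in.  ``error_model`` supplies the process
    noise the filter assumes (its ``filter_sigma_*`` fields, enabling
    deliberate mismatch with the generative noise).
    """

    map_arena: Arena
    n_particles: int = 10_000
    boundary_mode: str = "crossing"
    body: BodyShape = POINT_BODY
    error_model: ErrorModel = field(default_factory=ErrorModel)
    n_sweep: int = 16
    track_lineage: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_particles < 100:
            raise ValueError("n_particles must be at least 100")
        if self.boundary_mode not in ("crossing", "discrete_endpoint", "none"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class PoseEstimate:
    """Point estimate from an ensemble: weighted mean position, circular
    mean heading.  ``heading_defined`` is False when the heading resultant
    is negligible (e.g. uniform headings)."""

    x: float
    y: float
    theta: float
    heading_resultant: float
    heading_defined: bool


def save_ensemble(ens: ParticleEnsemble, path) -> None:
    """Write an ensemble snapshot as a numpy archive
    (x, y, theta, weight and any lineage records)."""
    data = {"xy": ens.xy, "theta": ens.theta, "weights": ens.weights,
            "t": np.array([ens.t])}
    if ens.lineage_xy is not None:
        data["lineage_xy"] = ens.lineage_xy
        data["lineage_theta"] = ens.lineage_theta
    np.savez(path, **data)


def load_ensemble(path) -> ParticleEnsemble:
    with np.load(path) as z:
        return ParticleEnsemble(
            xy=z["xy"], theta=z["theta"], weights=z["weights"],
            t=float(z["t"][0]),
            lineage_xy=z["lineage_xy"] if "lineage_xy" in z else None,
            lineage_theta=z["lineage_theta"] if "lineage_theta" in z else None)


def init_ensemble(cfg: FilterConfig, mode: str = "disoriented",
                  true_pose=None,
                  rng: Union[int, np.random.Generator, None] = None) -> ParticleEnsemble:
    """Create the initial ensemble.

    ``oriented``: all particles at the true pose (perfect initial
    information).  ``disoriented``: positions uniform over the remembered
    map's traversable space, headings uniform on [0, 2 pi).
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    n = cfg.n_particles
    if mode == "oriented":
        if true_pose is None:
            raise ValueError("oriented init requires the true pose")
        x, y, th = true_pose
        xy = np.tile([x, y], (n, 1)).astype(float)
        theta = np.full(n, float(th))
    elif mode == "disoriented":
        xy = cfg.map_arena.sample_uniform(n, rng)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    ens = ParticleEnsemble(xy=xy, theta=theta, weights=np.full(n, 1.0 / n), t=0.0)
    if cfg.track_lineage:
        ens.lineage_xy = xy.copy()
        ens.lineage_theta = theta.copy()
    return ens


def _body_sweep_crossed(cfg: FilterConfig, xy0, th0, xy1, th1) -> np.ndarray:
    """Per-particle crossing flag for a finite body: centre path plus
    sampled perimeter-point paths."""
    geom = cfg.map_arena.geometry
    crossed = geom.segments_cross(xy0, xy1)
    k = cfg.n_sweep
    a = cfg.body.perimeter_points(xy0, th0, n=k).reshape(-1, 2)
    b = cfg.body.perimeter_points(xy1, th1, n=k).reshape(-1, 2)
    crossed |= geom.segments_cross(a, b).reshape(-1, k).any(axis=1)
    return crossed


def _endpoint_invalid(cfg: FilterConfig, xy1, th1) -> np.ndarray:
    geom = cfg.map_arena.geometry
    bad = ~geom.contains_points(xy1)
    if not cfg.body.is_point:
        k = cfg.n_sweep
        pts = cfg.body.perimeter_points(xy1, th1, n=k).reshape(-1, 2)
        bad |= (~geom.contains_points(pts)).reshape(-1, k).any(axis=1)
    return bad


def _resample_to_n(ens_fields: dict, survivors: np.ndarray, weights: np.ndarray,
                   n: int, rng: np.random.Generator) -> dict:
    """Multinomial resampling of the whole population to n (used after
    continuous reweighting, e.g. a compass update)."""
    idx = np.flatnonzero(survivors)
    w = weights[idx]
    if np.ptp(w) <= 1e-15:  # uniform survivor weights: plain cloning
        pick = idx[rng.integers(0, len(idx), size=n)]
    else:
        pick = idx[rng.choice(len(idx), size=n, p=w / w.sum())]
    return {key: (None if val is None else val[pick]) for key, val in ens_fields.items()}


def _clone_replacements(ens_fields: dict, survivors: np.ndarray,
                        rng: np.random.Generator) -> dict:
    """Replacement cloning after a binary cull: acceptable hypotheses are
    kept in place and removed slots are refilled with clones of uniformly
    drawn survivors.  Lower resampling variance than resampling everyone."""
    surv_idx = np.flatnonzero(survivors)
    pick = np.arange(len(survivors))
    dead = np.flatnonzero(~survivors)
    pick[dead] = surv_idx[rng.integers(0, len(surv_idx), size=len(dead))]
    return {key: (None if val is None else val[pick]) for key, val in ens_fields.items()}


def _reinit_disoriented(cfg: FilterConfig, t: float, rng: np.random.Generator,
                        n_reinits: int) -> ParticleEnsemble:
    logger.info("total cull at t=%s s: reinitializing ensemble uniformly", t)
    ens = init_ensemble(cfg, "disoriented", rng=rng)
    ens.t = t
    ens.n_reinits = n_reinits + 1
    if cfg.track_lineage:
        # ancestry is severed: the time-0 estimate reverts to the
        # disoriented prior (the fresh uniform poses)
        ens.lineage_xy = ens.xy.copy()
        ens.lineage_theta = ens.theta.copy()
    return ens


def step(ens: ParticleEnsemble, d: DisplacementEstimate, cfg: FilterConfig,
         rng: Union[int, np.random.Generator, None] = None) -> ParticleEnsemble:
    """Advance the ensemble by one reported displacement.

    Each particle applies the reported heading change (iPI) or adopts the
    reported absolute heading (aPI), perturbed by the filter's assumed
    noise, then advances by the reported (noise-perturbed) step length
    along its own heading.  Particles failing the boundary test are culled
    and survivors multinomially cloned back to N.  A total cull triggers a
    uniform reinitialization over the remembered map.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    em = cfg.error_model
    n = ens.n
    dt = d.t - ens.t if d.t > ens.t else 1.0
    if d.dtheta_hat is not None:
        sd = em.assumed_sigma_theta * math.sqrt(dt)
        noise = rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
        theta1 = wrap_angle(ens.theta + d.dtheta_hat + noise)
    else:
        theta1 = np.full(n, wrap_angle(d.theta_hat))
    s_sd = em.assumed_sigma_step
    if s_sd > 0:
        lengths = d.step_hat * (1.0 + rng.normal(0.0, s_sd, size=n))
    else:
        lengths = np.full(n, d.step_hat)
    lengths = np.maximum(lengths, 0.0)
    xy1 = ens.xy + lengths[:, None] * np.stack([np.cos(theta1), np.sin(theta1)], axis=1)

    if cfg.boundary_mode == "crossing":
        if cfg.body.is_point:
            culled = cfg.map_arena.geometry.segments_cross(
                ens.xy, xy1, assume_inside=True)
        else:
            culled = _body_sweep_crossed(cfg, ens.xy, ens.theta, xy1, theta1)
    elif cfg.boundary_mode == "discrete_endpoint":
        culled = _endpoint_invalid(cfg, xy1, theta1)
    else:
        culled = np.zeros(n, dtype=bool)

    survivors = ~culled
    if not survivors.any():
        return _reinit_disoriented(cfg, d.t, rng, ens.n_reinits)
    if survivors.all():
        # nothing culled: cloning would only erode diversity
        return ParticleEnsemble(xy=xy1, theta=theta1,
                                weights=ens.weights.copy(), t=d.t,
                                lineage_xy=ens.lineage_xy,
                                lineage_theta=ens.lineage_theta,
                                n_reinits=ens.n_reinits)
    fields = {"xy": xy1, "theta": theta1,
              "lineage_xy": ens.lineage_xy, "lineage_theta": ens.lineage_theta}
    picked = _clone_replacements(fields, survivors, rng)
    return ParticleEnsemble(xy=picked["xy"], theta=picked["theta"],
                            weights=np.full(n, 1.0 / n), t=d.t,
                            lineage_xy=picked["lineage_xy"],
                            lineage_theta=picked["lineage_theta"],
                            n_reinits=ens.n_reinits)


def apply_compass(ens: ParticleEnsemble, obs: float, sd: float,
                  rng: Union[int, np.random.Generator, None] = None) -> ParticleEnsemble:
    """Bayes-update particle weights with a noisy absolute-heading reading.

    The likelihood is circular-normal (von Mises with kappa = 1/sd^2); the
    ensemble is then resampled back to uniform weights.  Positions are
    never reset — the compass only breaks rotational symmetry.
    """
    if sd <= 0:
        raise ValueError("compass sd must be positive")
    rng = as_rng(rng)
    kappa = 1.0 / (sd * sd)
    logw = kappa * (np.cos(ens.theta - obs) - 1.0)  # stable: max 0
    w = ens.weights * np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        logger.warning("degenerate compass weights at t=%s; keeping prior weights", ens.t)
        w = ens.weights.copy()
        total = w.sum()
    w /= total
    fields = {"xy": ens.xy, "theta": ens.theta,
              "lineage_xy": ens.lineage_xy, "lineage_theta": ens.lineage_theta}
    picked = _resample_to_n(fields, np.ones(ens.n, dtype=bool), w, ens.n, rng)
    return ParticleEnsemble(xy=picked["xy"], theta=picked["theta"],
                            weights=np.full(ens.n, 1.0 / ens.n), t=ens.t,
                            lineage_xy=picked["lineage_xy"],
                            lineage_theta=picked["lineage_theta"],
                            n_reinits=ens.n_reinits)


def apply_contact(ens: ParticleEnsemble, contact: bool, cfg: FilterConfig,
                  tol: float = 2.0,
                  rng: Union[int, np.random.Generator, None] = None) -> ParticleEnsemble:
    """Cull particles inconsistent with a boundary-contact observation.

    ``contact=True`` keeps only particles whose body perimeter is within
    ``tol`` cm of a remembered boundary; ``contact=False`` keeps only those
    farther away.  Survivors are cloned back to N.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = as_rng(rng)
    geom = cfg.map_arena.geometry
    if cfg.body.is_point:
        dist = geom.distance_to_boundary(ens.xy)
    else:
        k = cfg.n_sweep
        pts = cfg.body.perimeter_points(ens.xy, ens.theta, n=k).reshape(-1, 2)
        dist = geom.distance_to_boundary(pts).reshape(-1, k).min(axis=1)
    survivors = (dist <= tol) if contact else (dist > tol)
    if not survivors.any():
        return _reinit_disoriented(cfg, ens.t, rng, ens.n_reinits)
    if survivors.all():
        return ens.copy()
    fields = {"xy": ens.xy, "theta": ens.theta,
              "lineage_xy": ens.lineage_xy, "lineage_theta": ens.lineage_theta}
    picked = _clone_replacements(fields, survivors, rng)
    return ParticleEnsemble(xy=picked["xy"], theta=picked["theta"],
                            weights=np.full(ens.n, 1.0 / ens.n), t=ens.t,
                            lineage_xy=picked["lineage_xy"],
                            lineage_theta=picked["lineage_theta"],
                            n_reinits=ens.n_reinits)


def estimate_pose(ens: ParticleEnsemble) -> PoseEstimate:
    """Weighted mean position and circular mean heading of the ensemble."""
    if ens.n == 0:
        raise ValueError("empty ensemble")
    w = ens.weights
    x, y = (w[:, None] * ens.xy).sum(axis=0)
    c = (w * np.cos(ens.theta)).sum()
    s = (w * np.sin(ens.theta)).sum()
    r = math.hypot(c, s)
    # resultant below the Monte Carlo floor of a uniform sample (~N^-1/2)
    # means the heading is undefined rather than weakly concentrated
    return PoseEstimate(x=float(x), y=float(y),
                        theta=float(wrap_angle(math.atan2(s, c))),
                        heading_resultant=float(r),
                        heading_defined=bool(r > 0.05))


def propagate_pure_pi(stream: DisplacementStream, cfg: FilterConfig,
                      init_mode: str = "oriented", true_pose0=None,
                      rng: Union[int, np.random.Generator, None] = None,
                      eval_indices: Optional[np.ndarray] = None):
    """Closed-form propagation for ``boundary_mode='none'``.

    Without culling the filter is a pure path integrator, so all particle
    states follow from cumulative sums of the (noise-perturbed) reported
    displacements; this evaluates whole trials vectorized instead of
    stepping.  Statistically identical to the stepwise filter (noise draw
    order differs).  Returns ``(eval_indices, ensembles at those steps)``.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    em = cfg.error_model
    ens0 = init_ensemble(cfg, init_mode, true_pose=true_pose0, rng=rng)
    n = ens0.n
    T = len(stream)
    dt = float(stream.t[1] - stream.t[0]) if T > 1 else 1.0
    if eval_indices is None:
        eval_indices = np.arange(T)
    if stream.mode == "iPI":
        sd = em.assumed_sigma_theta * math.sqrt(dt)
        noise = rng.normal(0.0, sd, size=(T, n)) if sd > 0 else 0.0
        theta = ens0.theta[None, :] + np.cumsum(
            stream.heading[:, None] + noise, axis=0)
    else:
        theta = np.broadcast_to(stream.heading[:, None], (T, n)).copy()
    s_sd = em.assumed_sigma_step
    if s_sd > 0:
        lengths = stream.step_hat[:, None] * (1.0 + rng.normal(0.0, s_sd,
                                                               size=(T, n)))
    else:
        lengths = np.broadcast_to(stream.step_hat[:, None], (T, n)).copy()
    np.maximum(lengths, 0.0, out=lengths)
    xy = np.empty((T, n, 2))
    np.cumsum(lengths * np.cos(theta), axis=0, out=xy[:, :, 0])
    np.cumsum(lengths * np.sin(theta), axis=0, out=xy[:, :, 1])
    xy += ens0.xy[None, :, :]
    out = []
    w = np.full(n, 1.0 / n)
    for i in eval_indices:
        out.append(ParticleEnsemble(xy=xy[i].copy(),
                                    theta=wrap_angle(theta[i].copy()),
                                    weights=w.copy(), t=float(stream.t[i])))
    return np.asarray(eval_indices), out, ens0


def run_filter(stream: DisplacementStream, cfg: FilterConfig,
               init_mode: str = "disoriented", true_pose0=None,
               rng: Union[int, np.random.Generator, None] = None,
               callback: Optional[Callable[[int, ParticleEnsemble], None]] = None,
               contact_tol: float = 2.0) -> ParticleEnsemble:
    """Drive the filter over a whole displacement stream.

    Applies, in order per step: the motion/culling update, any compass
    observation, and any contact observation.  ``callback(i, ens)`` is
    invoked after each step (i indexes the stream).  Returns the final
    ensemble.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    ens = init_ensemble(cfg, init_mode, true_pose=true_pose0, rng=rng)
    if callback is not None:
        callback(-1, ens)
    sd = cfg.error_model.compass_sd
    for i in range(len(stream)):
        d = stream[i]
        ens = step(ens, d, cfg, rng)
        if d.compass_obs is not None:
            ens = apply_compass(ens, d.compass_obs, sd, rng)
        if d.contact_obs is not None:
            ens = apply_contact(ens, d.contact_obs, cfg, contact_tol, rng)
        if callback is not None:
            callback(i, ens)
    return ens


def reverse_replay(stream: DisplacementStream, final_ens: ParticleEnsemble,
                   cfg: FilterConfig,
                   rng: Union[int, np.random.Generator, None] = None,
                   callback: Optional[Callable[[int, ParticleEnsemble], None]] = None
                   ) -> ParticleEnsemble:
    """Offline retrospective inference: replay stored displacements backward.

    Starting from the final ensemble, each stored step is un-applied in
    reverse order (translate back along the current heading, then undo the
    heading change), with the same assumed noise and boundary culling as
    the forward pass.  The returned ensemble estimates the pose at time 0.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    em = cfg.error_model
    ens = final_ens.copy()
    n = ens.n
    dt = stream.t[1] - stream.t[0] if len(stream) > 1 else 1.0
    for i in range(len(stream) - 1, -1, -1):
        s_sd = em.assumed_sigma_step
        if s_sd > 0:
            lengths = stream.step_hat[i] * (1.0 + rng.normal(0.0, s_sd, size=n))
        else:
            lengths = np.full(n, stream.step_hat[i])
        lengths = np.maximum(lengths, 0.0)
        if stream.mode == "aPI":
            theta_now = np.full(n, wrap_angle(stream.heading[i]))
        else:
            theta_now = ens.theta
        xy1 = ens.xy - lengths[:, None] * np.stack(
            [np.cos(theta_now), np.sin(theta_now)], axis=1)
        if stream.mode == "aPI":
            theta1 = (np.full(n, wrap_angle(stream.heading[i - 1])) if i > 0
                      else theta_now)
        else:
            sd_th = em.assumed_sigma_theta * math.sqrt(dt)
            noise = rng.normal(0.0, sd_th, size=n) if sd_th > 0 else 0.0
            theta1 = wrap_angle(theta_now - stream.heading[i] + noise)
        if cfg.boundary_mode == "crossing":
            if cfg.body.is_point:
                culled = cfg.map_arena.geometry.segments_cross(ens.xy, xy1)
            else:
                culled = _body_sweep_crossed(cfg, ens.xy, theta_now, xy1, theta1)
        elif cfg.boundary_mode == "discrete_endpoint":
            culled = _endpoint_invalid(cfg, xy1, theta1)
        else:
            culled = np.zeros(n, dtype=bool)
        survivors = ~culled
        t_prev = stream.t[i] - dt
        if not survivors.any():
            ens = _reinit_disoriented(cfg, t_prev, rng, ens.n_reinits)
            continue
        if survivors.all():
            ens = ParticleEnsemble(xy=xy1, theta=theta1,
                                   weights=ens.weights.copy(), t=t_prev,
                                   n_reinits=ens.n_reinits)
        else:
            fields = {"xy": xy1, "theta": theta1}
            picked = _clone_replacements(fields, survivors, rng)
            ens = ParticleEnsemble(xy=picked["xy"], theta=picked["theta"],
                                   weights=np.full(n, 1.0 / n), t=t_prev,
                                   n_reinits=ens.n_reinits)
        if callback is not None:
            callback(i, ens)
    return ens


def backward_inference_online(stream: DisplacementStream, cfg: FilterConfig,
                              init_mode: str = "disoriented", true_pose0=None,
                              rng: Union[int, np.random.Generator, None] = None,
                              record_every: int = 1):
    """Online retrospective inference via ancestral lineage tracking.

    Runs the forward filter with lineage records enabled; at each recorded
    step the time-0 pose estimate is the distribution of surviving
    particles' ancestral initial poses (multiplicity acts as weight).  No
    displacement storage is needed.  Returns ``(times, ensembles)`` where
    each ensemble holds time-0 pose hypotheses.
    """
    cfg = replace(cfg, track_lineage=True)
    times: list[float] = []
    snaps: list[ParticleEnsemble] = []

    def cb(i: int, ens: ParticleEnsemble):
        if i == -1 or (i % record_every == 0) or i == len(stream) - 1:
            times.append(ens.t)
            snaps.append(ens.lineage_ensemble())

    run_filter(stream, cfg, init_mode=init_mode, true_pose0=true_pose0,
               rng=rng, callback=cb)
    return np.array(times), snaps
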