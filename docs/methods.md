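# Methods

## The model in brief

An agent moves through a bounded 2D arena it knows from memory. At each
discrete time step it receives a noisy report of its own motion — a heading
change and a step length (idiothetic path integration, iPI), or an exact
absolute heading and a noisy step length (compass-aided, aPI) — and nothing
else: no vision, no landmark, no boundary contact. Pose estimation is
sequential Monte Carlo: N pose hypotheses (particles) each track the
reported displacements perturbed by the filter's assumed motion noise;
hypotheses whose step would cross a remembered boundary are removed and
surviving hypotheses are cloned to keep N constant. Localization, when it
happens, emerges from the competition between diffusive uncertainty growth
(motion noise) and hypothesis culling (boundary-map constraint). In an
arena with n-fold rotational symmetry the posterior can concentrate on at
most n geometrically equivalent poses; only 1-fold rotationally symmetric
(1-RS) arenas admit a unique solution from a fully disoriented start.

## Arena geometry

All arenas are polygons in continuous centimetres, centred on the centroid
of their traversable region; curved outlines (circle, egg) are discretized
to 360-gons (chord error < 0.02 mm at 38 cm radius). The canonical shapes:

* **circle** — 76 cm diameter (152 cm at scale 2). All other canonical
  shapes are matched to its area (4536 cm²) so that cross-arena
  comparisons of the place stability index share a normalizer scale.
* **kite** — interior angles 60°/90°/120°/90°; with the area match the
  long diagonal comes out at 102.4 cm. (An 80 cm diagonal and the circle
  area match are mutually exclusive for this shape; the area match was
  kept.)
* **egg** — limaçon r = R(1 + 0.3 cos t): smooth, no straight edges, one
  mirror axis, 1-RS.
* **tmaze** — two 20 cm corridors (140 cm bar, 87 cm stem), concave, 1-RS.
* **void_landmark** — 76 cm circle with an off-centre teardrop void; the
  outer boundary is rotationally symmetric but the traversable region is
  1-RS.
* **circle_barrier** — 76 cm circle with a bent ~25 cm interior polyline;
  the traversable *area* stays rotationally symmetric (the barrier has
  zero width), which is exactly what makes this arena a probe of the
  boundary-*crossing* model.
* **square** / **regular_polygon(k)** — area-matched regular polygons for
  the symmetry-order sweeps.

Rotational asymmetry A(φ) is the area of the symmetric difference between
the traversable region and its rotation by φ, normalized by twice the
region area. The rotation pivot is the centroid of the traversable region
(the natural fixed point; nothing else is distinguished). The symmetry
order is the largest n ≤ 60 with A(2πk/n) below tolerance for all k;
regions also invariant under generic small rotations are reported as ∞
(a true regular 60-gon is indistinguishable from a circle at this
tolerance, which we accept).

Containment of the elliptic body (semi-axes 7.5 × 3.5 cm) uses the centre
plus 72 sampled perimeter points; swept collision during a step tests the
straight paths of sampled perimeter points (16 by default in the filter).
Exact per-heading Minkowski erosion would be disproportionate to the noise
scales involved.

Two geometry fast paths matter for throughput and are exact, not
approximate: for a convex outer boundary with no barriers or voids, a
segment between two interior points cannot cross the boundary, so the
crossing test reduces to endpoint containment; for non-convex arenas a
coarse distance field provides a conservative lower bound on the distance
to the nearest boundary, letting most interior steps skip the full
segment–edge intersection test. Both paths are validated against GEOS
(shapely) predicates in the test suite.

## Trajectories

The step interval is dt = 0.5 s, mean speed 15 cm/s (per-step lengths
N(7.5, 1.875²) cm, clipped at zero), rodent-plausible defaults. The random
policy is a correlated random walk with 30°/step turning SD; on a wall
encounter the step is truncated at the wall, a new heading is redrawn
uniformly from directions whose short probe step stays inside, and the
remaining step length is spent in the new direction. The thigmotactic
policy follows the boundary at a 5 cm offset (the exterior ring of the
eroded region) with ±15% speed noise; a finite body that pokes outside at
sharp offset-ring corners is nudged toward the centroid until it fits.

One kinematic convention is load-bearing: the recorded heading at each
pose is the direction of the net per-step displacement (the policy keeps a
separate internal heading to steer proposals). This makes the reported
(heading change, step length) stream exactly invertible by straight-line
propagation, so a zero-noise filter tracks the truth exactly — including
through wall encounters — and reverse replay is an exact inverse. The cost
is that at a wall step the true two-segment path is summarized by its
chord; in concave arenas the chord can occasionally clip a boundary the
true path avoided, which acts as a small extra model mismatch at wall
steps.

## Error model and calibration

Heading drift is a Wiener process: the per-step heading-change error is
N(0, σ_θ² dt) with σ_θ in rad·s^(−1/2), so cumulative heading-error
variance grows as σ_θ²·t (verified by a linear-fit property test). Step
lengths are multiplied by (1 + N(0, σ_s²)). aPI reports the absolute
heading exactly each step — a compass resets orientation error — leaving
only step-length noise. Optional channels: compass readings as a Poisson
process (default mean rate 1/30 s⁻¹ when enabled, von Mises-like Gaussian
error of 15°) and boundary-contact flags (body perimeter within 2 cm).

The default noise magnitudes are fixed by their behavioural consequence,
not copied from any source: a grid search
(`idioloc calibrate`, `experiments.calibrate_noise`) selects the smallest
σ_s whose PI-only median I_p in the kite arena (initially oriented at the
centre, boundary test disabled) falls below chance within 6 minutes under
aPI, then the smallest σ_θ that reaches chance within 3 minutes under iPI
at that σ_s. At 60 trials, N = 1000, the search selects **σ_θ = 0.05
rad·s^(−1/2), σ_s = 0.16**, with crossings at 2:30 (iPI) and 4:50 (aPI);
the values are packaged in `data/error_defaults.json`. Two consequences of
this calibration are worth stating: first, the iPI-before-aPI failure
ordering is structural (iPI carries strictly more noise); second, the
calibrated σ_θ implies a heading-error SD of about 0.27 rad after 30
simulated minutes, so the across-trial circular variance of pure-iPI
heading error grows clearly but does not approach 1 within an hour — a
smaller drift than rodent darkness recordings suggest, inherited from the
calibration targets rather than measured physiology.

The filter's assumed noise (`filter_sigma_*`) defaults to the generative
values and can be set independently to study matched vs mismatched
uncertainty.

## Particle filter

N = 10⁴ particles by default (experiments use 2000 unless stated). The
motion update applies the reported heading change plus per-particle noise
from the *assumed* σ_θ (aPI adopts the exact reported heading), then
advances by the reported step length scaled by per-particle noise from the
assumed σ_s. Boundary models: `crossing` culls a particle whose step
segment (plus swept body-perimeter paths for a finite body) crosses the
outer boundary, a barrier or a void edge; `discrete_endpoint` only
requires the endpoint to lie in traversable space (and is blind to
zero-width barriers — the degraded model); `none` disables the test
(pure path integration).

Resampling is replacement cloning: surviving particles are kept in place
and only the culled slots are refilled with uniform draws from the
survivors; steps with no culls do not resample at all. Full multinomial
resampling at every step (an early implementation) collapses ensemble
diversity within minutes, locks the posterior onto transient wrong modes
and degrades localization; replacement cloning is also the literal reading
of removing invalid hypotheses and cloning acceptable ones to keep the
population constant. Multinomial resampling is retained where weights are
genuinely continuous, i.e. after a compass likelihood update (von Mises
with κ = 1/σ², computed as exp(κ(cos Δ − 1)) for stability). No roughening
noise is added beyond the process noise itself.

A total cull (no survivor) reinitializes the ensemble uniformly over the
remembered map — the disoriented prior — and logs the event; when lineage
records are tracked, their time-0 estimate likewise reverts to the prior,
since the ancestry information is genuinely lost. Total culls are rare in
the kite (a few per hundred 16-minute trials) and signal that the cloud
had collapsed onto a pose falsified *en bloc*.

With `boundary_mode="none"` the filter is a pure path integrator and all
particle states are cumulative sums of the perturbed displacement reports;
`propagate_pure_pi` evaluates whole trials vectorized (statistically
identical to stepping, with a different noise-draw order) and is used by
the experiment runner for the PI-only baselines.

Retrospective inference comes in two forms. Offline reverse replay steps
the stored displacement sequence backward from the final ensemble
(translate back along the current heading, then undo the heading change,
same culling), yielding an ensemble over the *initial* pose. Online
backward inference tracks, per particle, the ancestral pose at time 0
through all cloning; the lineage distribution at any time is the current
estimate of the starting pose and needs no displacement storage.

## Localization metrics

The place stability index of an ensemble against the true position is

    I_p = 1 − D̄_post / (2 D̄_unif),

with D̄_post the weighted mean particle–truth distance and D̄_unif the mean
distance from a uniformly random point of the traversable space to the
truth. D̄_unif is evaluated by Monte Carlo quadrature on 10⁵ cached points
per arena (fixed internal seed; quadrature error on I_p ≈ 0.001). The
definition pins the two anchors — uniform ensemble 0.5, point mass at the
truth 1 — and is not clamped below zero. One consequence worth noting: for
a point mass *inside* any of the standard convex arenas the index floor
stays positive (max distance < 2× mean uniform distance everywhere), so
"worse than chance" (I_p < 0.5), not "below zero", is the practical
failure reading.

The adjusted index I_p* for an n-RS arena replaces the distance with the
minimum over the n rotations of the true position about the centroid
(normalizer recomputed identically); n = 1 recovers I_p. Heading
performance across trials is the circular variance V = 1 − R of per-trial
heading errors (ensemble circular-mean heading minus true heading), 0 for
no error, → 1 for uniformly random. The convention "0 = no error" follows
the results-level usage; the inverted phrasing that appears once in the
source material's methods summary is treated as a typographical inversion.
Convergence kinetics: the plateau is the median of the last 10% of the
median-I_p series and t90 is the first time the series covers 90% of the
start-to-plateau change.

## Grid-cell readout

A simulated grid cell fires as an inhomogeneous Poisson process with rate
λ = λ_max·exp(−d²/2σ_f²), where d is the distance from the *estimated*
position to the nearest node of a hexagonal lattice (spacing 30 cm,
random orientation and phase per cell; λ_max = 20 Hz, σ_f = 6 cm = 0.2×
spacing, rodent-like). Spikes are georeferenced to the *true* position, so
spatial structure appears only if the estimate tracks the truth. Rate maps
use 2 cm pixels, occupancy normalization and 1-pixel Gaussian smoothing of
counts and occupancy separately (masked to visited pixels). The
autocorrelogram is the masked-Pearson spatial correlation at every lag
(FFT-based; lags with < 20 overlapping pixels are undefined). Gridness is
min(correlation at 60°, 120°) − max(30°, 90°, 150°) over an annulus from
the central-peak extent (first radius where the azimuthal mean drops below
0.1) to 1.25× the modal side-peak distance; fewer than 3 detectable side
peaks yields NaN. This standard estimator is slightly negatively biased on
structureless fields (a min of two is compared with a max of three
identically distributed correlations), which the null test acknowledges:
noise fields score around −0.2 ± 0.3, far from hexagonal fields (> 1).
Skaggs information is Σ pᵢ(λᵢ/λ̄)log₂(λᵢ/λ̄) in bits/spike. Grid rescaling
between two rate maps is a grid search over per-axis factors 0.8–1.3
(step 0.01) maximizing the normalized correlation after rescaling the
test map about its centre; the reported factor is the test map's stretch
relative to the reference.

## Experiment runner and problem sizes

Each figure-style preset expands to one or more fully specified
conditions; every condition runs trajectory → corruption → filter →
metrics per trial, with per-trial seeds spawned deterministically from the
master seed (identical configs reproduce outputs bit-exactly, and a
written manifest re-runs them). Scale knobs uniformly downscale the full
protocols (10³ trials, 48–192 min in the original study). The sizes used
by the packaged checks were chosen to keep the full suite comfortably
within a coffee break on one CPU while leaving the tested effects clearly
resolved: metric anchors at N = 10⁴; PI-only failure kinetics at 200
trials × 8–12 min × N = 2000; disoriented kite localization at 100 trials
× 48 min × N = 2000; the comparative predictions (asymmetry ranking,
barrier dichotomy, thigmotaxis ordering, replay, square-arena modes) at
6–12 trials × 2–16 min × N = 500–1000.

## Known limitations

* The synthetic trajectories idealize rodent movement: constant mean
  speed, no rest periods, no speed–turn coupling, schematic thigmotaxis on
  a fixed offset ring. Passing tests show the *inference* machinery works
  under the stated error model, not that real rodents carry these exact
  noise magnitudes.
* The calibrated noise is identified only up to the behavioural targets;
  configurations trading σ_θ against σ_s can satisfy them similarly, and
  derived quantities (e.g. how close V(θ) gets to 1 under pure iPI within
  48 minutes) inherit that freedom.
* At the reduced particle counts used for speed, the posterior
  occasionally collapses onto a wrong mode in weakly asymmetric or
  symmetric arenas before being falsified (then recovers via reinit).
* The thigmotactic-vs-random convergence-speed ordering for the
  elliptic-bodied agent in the egg arena does **not** reproduce under the
  calibrated noise: along the egg's smooth, weakly asymmetric offset ring
  the boundary constraint provides almost no tangential (phase)
  information, so wall-following runs show long wrong-phase transients
  and the ordering flips from seed to seed at every scale we can afford;
  the corresponding end-to-end test is expected to fail and is kept as an
  honest record of this model-condition mismatch rather than weakened.
* Expansion about the centroid is not containment-monotone for regions
  that are not star-shaped about it (the T-maze); the corresponding
  property holds for the star-shaped arenas only.
* The zero-width barrier model means `discrete_endpoint` is blind to
  barriers by construction; a finite-thickness barrier would blur the
  crossing-vs-endpoint dichotomy.
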