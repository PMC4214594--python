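# idioloc

**Idiothetic localization in bounded arenas: can an agent know where it is
using only self-motion cues and a remembered map?**

A navigating animal deprived of vision and every other external cue still
receives self-motion ("idiothetic") signals — vestibular, proprioceptive,
motor — from which it can integrate its path. Path integration alone
accumulates error without bound, so on its own it cannot sustain a
location estimate. This package simulates and analyzes the surprising
alternative: if the agent carries a *remembered map of the arena boundary*
and the arena has 1-fold rotational symmetry (no rotation short of 360°
maps it onto itself), then fusing noisy self-motion estimates with the
map suffices to localize — starting fully disoriented, without ever
sensing the boundary or any landmark. The package is aimed at
computational neuroscientists and roboticists studying spatial memory,
grid/place-cell physiology, and minimal-cue localization.

## The model

The agent's pose is (x, y, θ). Each time step (dt = 0.5 s) it reports a
heading change Δθ̂ and step length ŝ corrupted by a rodent-style error
model: heading drift is a Wiener process (per-step error N(0, σ_θ² dt),
σ_θ in rad·s^(−1/2)) and step lengths carry multiplicative noise
(1 + N(0, σ_s²)). Pose inference is Monte Carlo localization: N particles
each track the reported displacements under the filter's assumed noise,
particles whose step crosses a remembered boundary are culled, and
survivors are cloned to keep N constant. The posterior sharpens because
wrong hypotheses eventually walk through a wall in memory.

Performance is quantified by the **place stability index**

    I_p = 1 − D̄_post / (2 D̄_unif)

(0.5 = chance, i.e. uniform uncertainty over the arena; 1 = perfect), the
across-trial **circular variance V(θ)** of heading error (0 = exact,
→ 1 = uniformly random), and **t90**, the time for the median I_p series
to complete 90% of its change from start to plateau. Estimated positions
can additionally drive a stochastic grid-cell model — spike probability
decays with the distance from the *estimated* position to the nearest
node of a hexagonal lattice, spikes are plotted at the *true* position —
so localization quality becomes visible as grid-like firing fields
(gridness score, Skaggs information). Retrospective ("replay") inference
recovers the *initial* pose of a trial either by replaying stored
self-motion estimates backward or online via particle ancestry records.

## Worked example

Ten disoriented 8-minute trials in the kite-shaped arena (the canonical
1-RS shape: interior angles 60°/90°/120°/90°, area matched to a 76 cm
circle), 2000 particles, calibrated noise defaults:

```bash
idioloc run --preset custom --arena kite --trials 10 --duration 8m \
            --particles 2000 --seed 7
```

prints

```
custom: final median I_p = 0.800, t90 = 1:00 (start 0.500, plateau 0.858)
```

Read: the trials start at chance (I_p = 0.5, the agent knows nothing
about its pose), and within a minute of movement the across-trial
median I_p has completed 90% of its climb to a plateau of about 0.86 —
the particle cloud has contracted onto the true pose and stays there,
using nothing but noisy self-motion and the remembered outline. The same
protocol with `--boundary-mode none` (path integration without the map)
instead decays below chance within ~2–3 minutes.

Other presets reproduce the remaining protocols at configurable scale:
`fig1` (PI-only baselines), `fig2` (four 1-RS arenas), `fig3_asym`
(adjusted index vs rotational asymmetry across equal-area arenas),
`fig3_barrier` (boundary-crossing vs endpoint-only models in a circular
arena with an interior barrier), `fig4_body` (elliptic body,
thigmotactic vs random movement), `fig4_expand` (grid rescaling under
arena expansion), `fig5_replay` (reverse replay), and the supplementary
manipulations (`s1_mismatch`, `s2_contact`, `s3_scale`, `s4_compass`).
`idioloc calibrate` re-derives the packaged noise defaults from their
behavioural targets; `idioloc arena show NAME` inspects the canonical
arenas. Every run writes a manifest that reproduces it bit-exactly
(`idioloc run --manifest DIR/manifest.json`).

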