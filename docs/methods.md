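# Methods

## The model

A distance runner is modelled as a point mass on the standard 400 m
track. Three states evolve with distance from the start `s`: speed
`v(s)`, propulsive force per unit mass `f(s)` (N/kg), and remaining
anaerobic energy per unit mass `e(s)` (J/kg, the mechanical equivalent
of the maximal accumulated oxygen deficit). In time,

    dv/dt = f − v/τ
    df/dt = u,           u ∈ [−u−, u+]
    de/dt = σ(e) − f·v

with `τ` a global friction coefficient lumping every speed-proportional
loss (so `f_M·τ` is the maximal sprint speed and `v/τ` the per-distance
steady cost of speed `v`), `u` the force rate (motor control: effort
cannot change instantaneously), and `σ(e)` the aerobic power available,
modelled as a function of the remaining anaerobic store because the
store tracks race phase. On the bends, part of the force budget is
consumed by the centripetal acceleration `v²/R`:

    f² + v⁴/R² ≤ f_M²,

which is the only place track geometry enters. The race strategy is the
solution of the minimum-time optimal control problem under these
dynamics, energy non-negativity, a speed floor and, optionally, a
tactical speed corridor (lower/upper speed bounds vs distance that
encode a championship race's surges and cruising).

### The aerobic power curve

`σ(e)` is continuous, piecewise linear in `e`: it rises from
`sigma_rest` at `e = e0` to `sigma_max` at `e = phi_ramp·e0`
(oxygen-uptake kinetics at the gun — the runner incurs an oxygen deficit
before aerobic power is fully available), holds the plateau down to
`phi_final·e0`, and declines to `sigma_final` at exhaustion. Defaults:
`sigma_rest = 0.3·sigma_max`, `sigma_final = 0.8·sigma_max`,
`phi_ramp = 0.9`, `phi_final = 0.2`.

Anaerobic re-synthesis (`de/dt > 0` when running below aerobic balance)
is permitted, capped at `e ≤ e0`; a flag (`allow_resynthesis`) clips it.

### Units and the default athlete

`σ` and `e` are *mechanical* quantities. Oxygen uptake converts to
metabolic power at 20.9 J per mL O₂ (`vo2_to_power`); only a fraction of
metabolic power (gross efficiency of running, with elastic return, on
the order of a third) appears as mechanical work against `v/τ`. The
winner-like default (`default_winner()`, `data/default_winner.json`) is
a tuning anchor, not a measurement:

| parameter | value | consequence |
|---|---|---|
| e0 | 600 J/kg | anaerobic budget; exhausted at the line |
| f_M | 1.76 N/kg | sprint/bend force ceiling |
| τ | 4.5 s | max speed f_M·τ = 7.92 m/s |
| sigma_max | 8.54 W/kg | aerobic balance speed √(σ·τ) = 6.20 m/s |
| u± | 0.2 N/kg/s | full force range traversed in ~9 s |

These put the unconstrained optimal 10,000 m at ≈ 26:28 (≈ 6.3 m/s
mean), a 7.3–7.9 m/s finale, and — deliberately — a bend force cap that
starts to bind at cruising speed: the sustained bend speed (where
`(v/τ)² + v⁴/R² = f_M²`) is ≈ 6.27 m/s, so on cruise laps the bends are
run ~0.04–0.07 m/s slower than the straights, and during the finale the
gap widens (sprint the straights, ride the cap through the bends). A
regime with the cap fully slack would run every lap metronomically and
show no bend effect at all; the binding regime is the scientifically
interesting one and is a knife edge: the sustained bend speed must sit
*between* the cruise speed and the finale speed.

## Numerical solution

### Transcription

The problem is transcribed in the distance domain on `[0, D]` (fixed
horizon; `dt/ds = 1/v` etc.), on a grid that is uniform (default
`n_nodes = 500`, 20 m) except for a geometric launch zone over the first
60 m (the standing-start transient covers 1 → 6 m/s in a few tens of
metres; first spacing 0.8 m) and a uniformly refined finish zone (last
450 m at 5 m) where the bend-cap switching is sharpest.

The decision vector is the speed profile at the nodes only. All other
quantities are reconstructed from it by a *staggered midpoint scheme*:
the force is piecewise constant per interval,

    f_i = v̄_i (v_{i+1} − v_i)/h_i + v̄_i/τ,   v̄_i = (v_i + v_{i+1})/2,

the energy follows by a Heun step of `de/ds = σ(e)/v̄ − f`, and the
force rate by differencing interval forces across node boundaries.
First differences are essential: a central-difference force admits a
node-level sawtooth in `v` that the rate constraint cannot see.
Curvature is evaluated at interval midpoints, so bend/straight
boundaries never sit ambiguously on a constraint point.

Remaining constraints (bend cap per interval, `f ≥ 0`, `e ≥ 0` — scaled
to O(1) — and the rate bounds) plus per-node speed bounds (floor,
corridor, `f_M·τ`) form a nonlinear program in ~500 variables, solved
with SLSQP using batched finite-difference Jacobians. The objective is
the finish time (trapezoid of `1/v`) plus a small smoothing term
`reg_eps·∫u²/v ds` (`reg_eps = 1e-4`, contributing ≪ 0.01 s) against
rate chattering.

### Warm start

A quasi-steady profile seeds the solver: at a scalar energy price λ, the
pointwise optimal speed minimises `1/v + λ(v/τ − σ/v)` clipped to the
node bounds and to the sustained bend speed; λ is bisected so the total
drain matches the anaerobic budget (a conservative 80% of it when a
corridor is present, since start kinetics and the end-of-race σ decline
eat into the plateau-power assumption). A densely integrated
maximal-force launch curve replaces the first metres. Corridor solves
that still fail retry once from a 55% drain profile. Everything is
deterministic; no random numbers enter the solver.

### Exact control recovery and verification

After convergence the per-interval constant force that *exactly*
reproduces the optimal node speeds is recovered by per-interval shooting
(the momentum equation does not involve `e`, so intervals decouple; a
vectorized secant iteration on the landing speed converges in a few
steps and stays within O(h²) of the collocation force). The energy path
is then re-integrated under that schedule. The reported trajectory is
therefore a genuine solution of the model ODEs driven by its own stored
force schedule.

`verify_trajectory` is the independent oracle: a fixed-step classical
Runge–Kutta integration (4 substeps per interval) of speed and energy
driven by the stored zero-order-hold force, compared at every 100 m
mark, plus a global energy-balance quadrature. On solver output the
speed deviation is at integrator precision (~1e-15 m/s) and the energy
residual ~0.02% of `e0`; a corrupted schedule (force scaled ×1.1) is
flagged immediately.

### Discretization accuracy and problem sizes

Finish times are grid-converged to ~0.5% between 40 m and 10 m spacing;
100-m splits use exact piecewise-linear-speed quadrature
(`∫ds/v = h·ln(v₂/v₁)/(v₂−v₁)` per interval), so splits sum to the
finish time to machine precision. Production solves use `n_nodes = 500`;
the many-solve experiments (calibration, scenario sweeps) use
`n_nodes = 250` with a 12 m finish zone, where a warm-started solve
takes ~1–3 s. Synthetic races used for recovery are generated and
fitted on the same grid so the zero-noise floor of the fit error is
exactly zero.

## Synthetic championship races

`generate_race` emulates the observable of a championship 10,000 m: a
fast first 200 m, a slightly slower variable cruise, a tactical surge at
4,000–6,000 m, a lull, a build from 7,000 m and a free-sprint finale.
A tactic template supplies piecewise multipliers of the runner's own
sustainable mean speed (quasi-steady estimate, less a 0.4% margin —
tactically varied races are slower than the even-paced optimum); the
corridor is ±0.15 m/s generally and ±0.1 m/s in the strategic windows
(0–200 m and 4,000–6,000 m), with the upper bound released after
9,200 m so the finale is chosen by the optimizer, not the template.

Because the bend cap binds at cruise speed, a corridor cannot *pin*
speeds above the sustained bend speed for a whole window; the surge is
therefore imposed mostly by capping the cruise slightly below the surge
band. Timing noise is zero-mean Gaussian on each split time (default
sd 0.05 s, the plausible resolution of video-derived splits), redrawn in
the (never observed at realistic scales) event of a non-positive split.

What the generator does *not* emulate: reaction time and the staggered
start, drafting and runner–runner interaction, wind, lap-to-lap
variability beyond the template, and split-time correlation. Passing
recovery tests therefore show the *pipeline* is consistent, not that
real athletes' parameters are identifiable to the same precision.

## Calibration

`fit_error` re-solves the race for candidate parameters inside the
tactical corridor and returns the RMSE of simulated vs observed 100-m
mean speeds (a time-domain metric is a flag away). Infeasible candidates
— runners who physically cannot follow the corridor — return +inf with
the reason logged; a cheap necessary-condition screen (corridor lower
bound vs sustained bend speed; energy along the slowest admissible path)
rejects most of these without an NLP solve.

`calibrate` minimises this with a bounded Nelder–Mead simplex on
initial-value-scaled parameters, run in two stages with a fresh
full-size simplex at the incumbent (the restart re-expands the collapsed
simplex and walks down the narrow (e0, τ) compensation valley: a small
decrease of τ burns extra energy over the whole race and can mask a
sizable e0 change). By default only `(e0, f_M, τ)` are free: from one
race's 100-m splits the σ-curve levels and the rate limits act almost
solely through the total work available in the unconstrained phases —
the channel `e0` already parametrizes — and freeing them degrades
recovery by an order of magnitude. They can be freed explicitly via
`free_fields`. Within `calibrate`, solves warm-start from the incumbent
solution (the evaluation order is deterministic, so results are
reproducible); standalone `fit_error` always cold-starts so repeated
calls are bitwise identical.

On zero-noise synthetic data (budget 200 solves, init 10% high), the
recovered `e0` and `τ` are within ~0.5% of truth and the refitted finish
time within ~0.01 s. With 0.05 s timing noise the fit floor rises to
roughly the implied speed noise (~0.02 m/s) and recovery degrades
gracefully.

Known limitation: a corridor rebuilt from observed splits by the default
moving-average construction can be infeasible in the strong-bend regime
(edge truncation lifts the tail centreline above the sustained bend
speed). Recovery workflows should pass the known tactic corridor, widen
`delta_wide`, or shorten the smoothing window.

## Scenario experiments

`perturb_params` scales one field and re-validates. "Worse running
economy" maps to a *smaller* τ (per-distance steady cost `v/τ` rises);
users preferring to tax the aerobic side can scale `sigma_max` instead.
`compare_scenarios` solves both runners under the same corridor; if the
variant cannot follow it, the wide sections are relaxed by 0.15 m/s
(strategic windows kept) and the fallback is flagged. Headline outputs:
Δt, per-split speed differences, an endspurt summary (last-400 m mean
minus race mean), and the per-lap straight-minus-bend amplitude
(mean, std). At the defaults: −5% `e0` costs ~1.5 s, concentrated in
the final 400 m; τ×0.9 damps the bend/straight amplitude.

## Degenerate inputs and tie-breaks

Zero-length track segments are skipped; a corridor whose lower bound
exceeds the upper (or the sprint ceiling) raises before any solve;
solver non-convergence is always surfaced through `solve_status`
(`converged` / `max_iterations` / `infeasible` / `failed`) — a
feasible-but-stalled SLSQP line search is accepted as converged, a
feasibility violation never is. Segments are half-open `[start, end)`,
so at a boundary the next segment's curvature applies; splits are cut at
fixed 100-m marks from the start line, mixing bend and straight running
exactly as track-side data do.
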