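# trackpace

Optimal-control modelling of pacing strategy in world-class 10,000 m
track racing.

Championship 10,000 m finals are not run at even pace: athletes start
fast, cruise, surge mid-race, and settle the medals in the endspurt —
all while covering 5,800 m of their race on bends. `trackpace` models a
runner as a point mass whose speed `v(s)`, propulsive force per unit
mass `f(s)` and anaerobic reserve `e(s)` obey

    dv/dt = f − v/τ                 (motion, with friction coefficient τ)
    df/dt = u ∈ [−u₋, u₊]           (bounded force rate: motor control)
    de/dt = σ(e) − f·v              (aerobic supply vs mechanical power)

with the bend constraint `f² + v⁴/R² ≤ f_M²` on the 36.5 m-radius
curves, and computes minimum-time races by direct collocation — either
free, or inside a tactical *speed corridor* that encodes championship
behaviour (fast start, a 4,000–6,000 m surge, an endspurt). On top of
the solver it provides:

- **100-m splits** (`T_k = ∫ ds/v`, `v_k = 100/T_k`), the observable the
  model is fitted to, with exact quadrature and CSV I/O;
- **synthetic championship races** with known ground truth (tactic
  templates + per-split timing noise) for recovery experiments;
- **calibration** of the physiological parameters `(e⁰, f_M, τ, …)` to
  observed splits by repeated re-optimization;
- **scenario experiments**: reduce the anaerobic capacity `e⁰` by 5%, or
  worsen the running economy (smaller τ), re-solve, and quantify the
  strategic consequences;
- an independent **trajectory verifier** that re-integrates the solved
  force schedule with a Runge–Kutta oracle.

## Worked example

```python
import trackpace as tp

winner = tp.default_winner()          # winner-like parameter set
traj = tp.solve_race(winner)          # unconstrained optimal 10,000 m
print(f"final time {tp.format_race_time(traj.final_time)}")
print(f"terminal anaerobic reserve {traj.e[-1]:.1f} J/kg")

splits = tp.compute_splits(traj)
lap5 = (traj.s >= 1600) & (traj.s < 2000)
bend = traj.v[lap5 & (traj.curvature > 0)].mean()
straight = traj.v[lap5 & (traj.curvature == 0)].mean()
print(f"lap 5: bends {bend:.3f} m/s, straights {straight:.3f} m/s")

report = tp.verify_trajectory(traj, winner)
print(report)
```

prints (to the displayed precision):

```
final time 26:26.19
terminal anaerobic reserve -0.5 J/kg
lap 5: bends 6.282 m/s, straights 6.326 m/s
speed dev 1.78e-15 m/s, energy dev 1.51e-01 J/kg, time dev 6.02e-02 s,
energy residual 1.40e-01 J/kg (0.023% of e0) -> OK
```

— a 26½-minute race that exhausts the anaerobic store at the line, runs
the bends slower than the straights on cruise laps (the centripetal term
`v⁴/R²` eats into the force budget), and whose force schedule
re-integrates to the reported speeds at machine precision.

The same pipeline from the shell:

```bash
trackpace synth --tactic championship_surge --noise 0.05 --seed 42 \
    --out obs.csv --truth truth.json
trackpace calibrate --splits obs.csv --out fit.json
trackpace scenario --base fit.json --perturb e0=0.95 --out report.json
```

See `docs/methods.md` for the model assumptions, the transcription, the
parameter defaults and their rationale, and known limitations.

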