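# pincontrol

Simulation and analysis of upright postural control under a
**unilaterally-constrained pin-controller model**: one limb contributes a
fixed centre of pressure (a "pin" — e.g. a prosthetic limb or a mechanical
constraint device), while the other limb acts as the controller.  The
package generates synthetic dual-force-plate quiet-standing trials from a
delayed-PD-controlled inverted pendulum and runs the complete analysis
chain: per-limb and combined CoP extraction from plate wrenches, segmental
CoM estimation from markers, and per-limb kinetic/kinematic
inverted-pendulum correlation statistics aggregated into a summary table.

## Layout

| module | contents |
| --- | --- |
| `pincontrol.simulator` | inverted-pendulum trial generator: delayed-PD CoP control, pin constraint, load-share (load/unload) ML mechanism, per-plate wrench emission, marker synthesis, cohort generation |
| `pincontrol.kinetics` | CoP from plate wrenches (zero-horizontal-moment point), projection onto elevated "force structure" planes, load-weighted CoP combination, weight-bearing share, pin-location construction |
| `pincontrol.kinematics` | segmental (anthropometric) whole-body CoM, zero-phase filtering, double differentiation, per-marker height/excursion statistics |
| `pincontrol.ipstats` | Pearson correlations for the kinetic and kinematic inverted-pendulum tests, Fisher-z aggregation with t-based 95% CIs, tidy long-format export and summary table |
| `pincontrol.trialio` / `pincontrol.cli` | canonical CSV + JSON-sidecar trial format, optional C3D ingestion, `pincontrol` command-line interface |
| `pincontrol.body` | bundled 13-pseudo-segment anthropometric table and default marker layout |

## Command-line use

```sh
# simulate a cohort (one CSV + JSON sidecar per trial, plus manifest.json)
pincontrol simulate --config examples/cohort.toml --seed 7 --out trials/

# per-trial correlations, tidy long format (one row per
# trial x definition x direction x limb) for external ANOVA tools
pincontrol analyze --in trials/ --out results.csv

# back-transformed group means with 95% CIs per
# direction x group x limb x condition
pincontrol report --in results.csv --out summary.csv
```

Exit codes: 0 ok, 1 user error, 2 internal error.

## Model sketch

Each horizontal direction follows the single-segment inverted pendulum

    x''(t) = (g / h) * (x(t) - u(t))

where `u` is the realized combined CoP.  A delayed PD law with band-passed
exploratory noise and a slow set-point wander commands `u`.  In AP the
command is realized by the controller limb's within-foot CoP while the pin
limb's CoP stays fixed at the pin location (66% of the ankle-to-5th-
metatarsal distance by default).  In ML the command is realized by
modulating the vertical load share between two per-limb CoPs held near the
foot centres, so per-limb ML CoPs barely move while the combined CoP
tracks the command.  This reproduces the characteristic correlation
signature between `CoP - CoM` and the CoM acceleration: strongly negative
for the controller limb and the combined CoP in AP, near zero for the pin
limb and for each individual limb in ML, strongly negative for the
combined CoP in ML.

Ground truth (CoM position/velocity/acceleration, total CoP, load share)
is stored alongside every synthetic recording; the stored acceleration
equals `(g/h)(x - u)` at machine precision, so the pendulum relation is
exactly recoverable from the outputs.

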