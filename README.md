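# myosyn

Model-based, posture-dependent muscle synergies for 1-DoF musculoskeletal
systems, and a synergy-driven feedback controller that needs no online
optimization.

A redundant 1-DoF plant (many muscles, one operational-space coordinate)
admits a closed-form solution of the minimum-effort force-sharing problem:
only muscles acting in the demanded torque direction are active, with
activations proportional to their torque transform `h` (torque per unit
activation at a posture). Because the ratio between any two same-direction
muscles is independent of the demand, the whole optimum can be stored as
**two posture-dependent synergies** — one per torque direction — each
scaled by a single *representative* muscle. A scalar signed-activation
controller (PID) then drives the full muscle set optimally. The package
also ships a static-synergy NNMF baseline which, unlike the posture tables,
cannot follow muscles that change function with posture.

## Layout

| module | contents |
| --- | --- |
| `myosyn.muscle_mechanics` | Hill-type muscle (Gaussian force–length, Thelen-form force–velocity, rigid tendon), moment arms from length polynomials, analytic torque transform `h` |
| `myosyn.plant` | 1-DoF forward dynamics (RK4), `net_torque`, seeded crank-model generator with function-switching muscles |
| `myosyn.force_sharing` | closed-form minimum-effort sharing + independent NNLS-based QP oracle |
| `myosyn.synergy` | plant-probed `h`, representative validation, synergy-ratio tables, reconstruction |
| `myosyn.nnmf` | optimal-activation training data, multiplicative-update NNMF, representative scaling, VAF |
| `myosyn.control` | signed-activation PID, forward static optimization (FSO) baseline, tracking simulations, effort metric, controller comparison |
| `myosyn.fixtures` / `myosyn.config` | shipped 7-muscle forearm model (YAML), model (de)serialization |

## CLI

```sh
# minimum-effort sharing for transforms listed in h.txt, demand 5 N*m
myosyn share --input h.txt -T 5

# build and export a synergy table
myosyn synergies build --model forearm --out table.json --csv table.csv

# track a seeded sum-of-sines reference with one controller
myosyn simulate --model forearm --controller pid-table --seed 1 --out out/

# FSO vs synergy-PID (vs NNMF-PID) on the identical task
myosyn compare --model crank --seed 1 --with-nnmf --out out/

# fit the static-synergy baseline
myosyn nnmf fit --model crank --seed 1 --out-prefix out/nn

# persist a generated crank model for reuse
myosyn export-model --model crank --seed 1 --out crank.yaml
```

`--model` accepts `forearm` (shipped fixture), `crank` (seeded generator),
or a path to a YAML/JSON model config.

## Conventions

Angles in radians, torques in N·m, forces in N, lengths in m. Moment arms
are the negative derivative of musculotendon length with respect to the
operational angle: positive arms increase the angle when the muscle
shortens. All randomness flows through explicit integer seeds; identical
seeds give bitwise-identical results.
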