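# stablegait

Inference of feedforward–feedback foot placement control from planar
locomotion kinematics.

Legged animals stay upright while walking by adjusting where they place
each swinging foot. `stablegait` takes time series of body and foot
positions in the horizontal plane — from a biped, a trotting quadruped, or
a tripod-gait hexapod — and asks how much of the step-to-step variability
in foot placement is explained by (a) a velocity-dependent *feedforward*
pattern and (b) linear *feedback* from deviations of the body state. It is
aimed at motor-control and neuromechanics researchers working with
pose-tracked open-field or overground locomotion data.

## The model

Per leg, with cycle-averaged speed v̂ and gait fraction φ ∈ [0, 1]:

- feedforward: step length/width f^{x,y}(v̂) = β₀ + β₁ v̂, cycle duration
  f^t(v̂) = β₀ e^{−β₁(v̂−β₂)} + β₃, and a velocity-conditioned nominal
  pattern Q*_v̂(φ) for every body-state channel;
- feedback: placement deviations regress on body-state errors,
  ΔP ≈ γ₀ + Σᵢ γᵢ ΔQᵢ(φ), with ΔQ = Q − Q*_v̂, compared against a baseline
  regression on the swinging foot's own deviations ΔQ̃(φ);
- stability: the Poincaré return map K of cycle-sampled deviations
  (spectral radius ρ < 1 ⇒ stable gait), the association between placement
  magnitude and subsequent error reduction, and the decay constant τ of
  lagged placement correlations r(N) ≈ r₀ e^{−N/τ}.

A built-in stochastic walker generates trajectories from exactly this
control structure — lateral error e_{n+1} = a·e_n − d_n + η with
corrective placements d_n = G·e_n + ε, closed-loop coefficient
λ = a − G — so every estimator can be validated against known ground
truth. See `docs/methods.md` for the full account.

## Worked example

Simulate five biped individuals (two minutes each) with feedback gain
G = 0.4 and persistence a = 0.9, then run the full inference pipeline:

```python
import numpy as np
import stablegait as sg

cfg = sg.RunConfig(profile="biped", n_individuals=5, duration=120.0,
                   seed=7, n_boot=200)
report = sg.run_pipeline(cfg)

ff = report["feedforward"]["per_leg"]["left"]
print("cycles:", report["n_cycles"])
print("length slope (median animal):",
      round(np.median([a["length"]["beta1"] for a in ff["animals"].values()]), 3))
print("significant length slopes:",
      ff["n_significant_length"], "/", ff["n_animals"])
print("control magnitude median:",
      round(report["feedback"]["control_magnitude"]["median"], 3))
print("spectral radius:", round(report["stability"]["spectral_radius"], 3))
print("error reduction slope:",
      round(report["stability"]["error_reduction"]["slope"], 3))
print("max tau:", round(report["timescale"]["max_tau"]["tau"], 2),
      "ci:", [round(x, 2) for x in report["timescale"]["max_tau"]["tau_ci"]])
```

prints

```
cycles: 1024
length slope (median animal): 0.395
significant length slopes: 5 / 5
control magnitude median: 0.541
spectral radius: 0.514
error reduction slope: 0.665
max tau: 1.47 ci: [1.11, 3.06]
```

Reading these numbers: the fitted step-length slope recovers the
generative β₁ = 0.4 and is significant in every individual; the body-state
model explains ~0.54 more placement variance than the foot-kinematics
baseline at its best phase (feedback is present); the return map's
spectral radius ≈ 0.51 matches the closed-loop prediction a − G = 0.5
(stable gait); larger placement deviations are followed by larger error
reductions (positive slope); and placement correlations decay over
τ ≈ 1.4 cycles ≈ −1/ln 0.5.

The same stages are available as a CLI for file-based workflows:

```sh
stablegait simulate --profile hexapod --duration 120 --seed 7 --out bouts.h5
stablegait process  --in bouts.h5 --profile hexapod --out cycles.json
stablegait run      --config run.yaml --out report.json
```

Input data use a simple canonical schema (HDF5 groups of `t` and
`pos/<marker>`, or long-format CSV with columns
`bout_id, animal_id, t, marker, x, y`) plus a YAML species profile naming
the legs, their two alternating support groups, and the body markers.

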