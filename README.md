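# myospring

Isometric skeletal-muscle force as a **controllable nonlinear spring**,
hybrid dynamical models of the **muscle-spindle Ia/II afferents**, and an
**antagonist-muscle oculomotor plant** — for researchers in neuromechanics
and motor control who want muscle and proprioceptor models simple enough
for control analysis but faithful to the classic force-length data.

## The models

Muscle force at fixed length depends on the length L (normalized to the
optimal length Lo) and the alpha-motoneuron firing rate alpha (0–120
pulses per second).  The package provides three descriptions of that
surface, plus the sensors and a plant built on top of them:

* **Evaluation Model** — F_ISO = max(0, A(α)·exp(−((L−μ(α))/σ(α))²) + Fp(L)),
  an activation-dependent Gaussian active force plus a sigmoid-plus-
  exponential passive force whose negative branch below L = 1 places an
  activation-dependent rest length on the ascending limb.
* **Control Model** — F_ISO = K(α, L)·(L − L0(α)): a spring with
  controllable stiffness (cubic in α, sextic in L) and rest length
  (quadratic in α).  A fitting pipeline regenerates its 31 coefficients
  from the Evaluation Model: bisection extraction of rest-length zeros,
  equivalent-stiffness quotients, and a constrained polynomial refit.
* **Spindle Ia / II** — first-order hybrid filters whose eigenvalue and
  gain path are reset by the sign regime of the length rate (flow/jump
  dynamics), with zero-saturated outputs: the Ia captures dynamic
  stretch sensitivity and release silencing, the II a tonic
  length-proportional discharge.
* **Oculomotor plant** — two antagonist muscle springs torquing a damped
  eyeball (Jω̇ = −βω + R·F1 − R·F2), with spindle feedback per muscle,
  equilibrium analysis, and a constructive demonstration that the
  activation-to-torque map is redundant: co-contraction sets joint
  stiffness independently of torque.

Classic Hill-type reference models (activation shape factor Nf,
force-length bell, force-velocity branches, Gaussian-with-shifting-mean
active force) are included in `myospring.literature` for comparison.

## Worked example

```python
from myospring import ControlModel, fit_control_model

cm = ControlModel()                 # shipped coefficient tables
cm.rest_length(0.0)                 # 1.0     — rest length at 0 pps (Lo units)
cm.rest_length(60.0)                # 0.481984
cm.iso_force(60.0, cm.rest_length(60.0))   # 0.0 — the spring's structural zero
cm.iso_force(0.0, 1.3)              # 0.18132781109999405 — passive stretch force

# regenerate the spring from the Evaluation Model and check its fidelity
model, points, report = fit_control_model()
report.force_max_abs_error          # 0.0765  (Fo units, over the validity box)
report.force_rms_error              # 0.0274
```

The first two numbers say that with no excitation the muscle is slack at
exactly its natural length, and that 60 pps of motoneuron drive shortens
the zero-force length to ~0.48 Lo — activation contracts the spring.  The
passive value 0.181 Fo is the force of the unstimulated muscle stretched
30 % past its natural length.  The fit report shows the regenerated
spring tracks the Evaluation Model within 0.08 Fo everywhere on
[0.4, 1.5] Lo × [0, 120] pps.

The same is available from the shell:

```console
$ myospring force-control --alpha 0 --length 1.3
{"alpha_pps": 0.0, "L_norm": 1.3, "rest_length": 1.0, "stiffness": 0.6044260369999801, "F_iso": 0.18132781109999405}
```

Other subcommands: `force-eval`, `fit-control`, `extract-points`,
`spindle-sim`, `oculo-sim`, `gen-data` (see `myospring --help`).

## Documentation

`docs/methods.md` describes the model equations, parameter meanings and
defaults, the numerical choices (deadband, exact afferent integration,
capped stiffness fit, conditioning of the printed stiffness table), what
the synthetic data generators emulate, and known limitations.
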