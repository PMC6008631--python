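# shoulderkin

Closed-chain kinematics and motion-rhythm modelling of the human shoulder
girdle, for researchers in musculoskeletal biomechanics and upper-limb
rehabilitation robotics.

The human shoulder is not a ball joint: the humerus rides on a shoulder
girdle (clavicle + scapula) that glides over the rib cage, and during
natural arm raising the girdle follows the humerus in a highly repeatable
pattern — the *shoulder rhythm*. Exoskeletons designed around a 3-DoF
ball-and-socket shoulder misalign with this mechanism; planning their
trajectories needs a model of the girdle's constrained motion.

## The model

The shoulder is a hybrid spatial mechanism:

* **SC, AC, GH joints** — spherical (3 DoF each): sternum–clavicle,
  clavicle–scapula, scapula–humerus;
* **ST joint** — the scapula touches an ellipsoid approximating the thorax
  at two points *c*, *d* of its medial border (a 4-DoF cylinder–plane
  pair).

By the Kutzbach–Grübler count `M = 6(n − g − 1) + Σ fᵢ` the closed girdle
loop (3 links, joints {3, 3, 4}) has **4 DoF**; with the glenohumeral joint
the shoulder has 7. One girdle freedom is the clavicle's internal axial
spin (θ₃ ≡ 0), so three inputs determine the girdle: the SC-joint angles
θ₁, θ₂ and the azimuth ψ_d of contact point *d* on the ellipsoid.

Writing the chain as homogeneous transforms
`T₁₀ = Rz(θ₁) Rx(θ₂) Rz(θ₃)` (clavicle) and
`T₂₁ = Trans_z(l₁) Ry(θ₄) Rx(θ₅) Ry(θ₆)` (scapula), and parameterizing the
ellipsoid surface as `(m sinφ cosψ, n sinφ sinψ, p cosφ)`, the loop closes
when both scapular points reach the surface:

```
T₁₀ T₂₁ p_c² − (O + e(φ_c, ψ_c)) = 0
T₁₀ T₂₁ p_d² − (O + e(φ_d, ψ_d)) = 0
```

— six scalar constraints solved for (θ₄, θ₅, θ₆, φ_c, ψ_c, φ_d) by a
damped Newton iteration with a geometric assembly seed that selects the
anatomical branch.

The inputs come from measurable quantities: θ₁, θ₂ from the ISB clavicle
Euler angles (YXZ) and ψ_d from the central projection of the scapula's
inferior-angle landmark AI onto the thorax ellipsoid. The *rhythm model*
closes the loop with the humerus: per task (ABD / SCAP / FLEX) each of
(θ₁, θ₂, ψ_d, HumY₂) is a cubic in the humeral elevation HumX, assembled
piecewise over the plane of elevation HumY₁ (ABD for [−10°, 20°), SCAP for
[20°, 50°), FLEX for [50°, 90°]).

A synthetic-trial generator drives the forward model with these rhythm
functions (100 Hz, raised-cosine lift/drop cycles, optional Gaussian angle
noise) so the whole pipeline is testable without a motion-capture database.

## Worked example

```sh
$ python examples/solve_rest_posture.py
inputs:  theta1 = 74.07 deg, theta2 = 81.40 deg, psi_d = -50.89 deg
solved:  theta4  =    85.45 deg
solved:  theta5  =   168.02 deg
solved:  theta6  =     3.93 deg
solved:  phi_c   =    59.57 deg
solved:  psi_c   =   -48.15 deg
solved:  phi_d   =    88.86 deg
loop-closure residual = 1.09e-11 mm (both contact points on the thorax ellipsoid)
```

The inputs are the rhythm-table intercepts at zero elevation (arm hanging);
the solver returns the six dependent joint variables that place both
scapular contact points on the subject's thorax ellipsoid — the residual is
the remaining loop-closure gap. `examples/full_pipeline.py` runs the whole
loop (simulate → extract → solve → fit) and reports recovery errors at
machine precision on noiseless data; `examples/rhythm_curves.py` and
`examples/mobility_count.py` show the rhythm model and the mobility count.

The same operations are available from the shell:

```sh
shoulderkin mobility --links 3 --joints 3,3,4      # prints 4
shoulderkin rhythm-eval --task ABD --humx 0        # theta1 = 74.07 deg, ...
shoulderkin simulate --config sim.yaml -o traj.csv
shoulderkin extract -i traj.csv -o inputs.csv
shoulderkin solve -i inputs.csv -o solved.csv
```

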