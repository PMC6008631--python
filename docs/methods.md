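# Methods

## Frames and conventions

All computation is done in frames tied to the mechanism: S0 (global, at the
SC joint, x lateral / y anterior / z superior), S1 (clavicle), S2 (scapula,
at the AC joint), S3 (ellipsoid, axes parallel to S0), S4 (humerus).
Constant rotations R0t, R1c, R2s, R4h align these with the ISB-recommended
bone frames (thorax, clavicle, scapula, humerus); R0t and R4h are axis
permutations, R1c the identity. Angles are radians internally and degrees
at every file and CLI boundary (all published coefficient tables are in
degrees); lengths are mm.

Euler sequences are intrinsic (body-fixed), the matrix being the
left-to-right product of elementary rotations as written. The clavicle
chain is Z–X–Z (`T₁₀ = Rz(θ₁) Rx(θ₂) Rz(θ₃)`): this is the product whose
third column `(s₁s₂, −c₁s₂, c₂)` the input-extraction relations are built
on. The scapula chain is Y–X–Y, the humerus computation sequence Y–X–Z,
and ISB reporting uses YXZ (clavicle, scapula) and YXY (humerus).
Decompositions take the principal branch (middle angle in [0, π] for
symmetric sequences, [−π/2, π/2] otherwise); a `prev` argument shifts
angles by 2π multiples toward the previous sample so trajectory
decompositions stay continuous, and configurations within 1e-8 rad of a
singular middle angle are flagged as gimbal-locked rather than erroring.

## Geometry

Link lengths (l₁ = 154.17, l₂ = 120.71, l₃ = 187.21, l₄ = 301.56 mm,
γ = 33.8°) come from the cadaver-derived generic skeleton; the bundled
geometry sets pair them with either the generic thorax ellipsoid
(m, n, p = 76.85, 97.17, 217.44 mm, centre in S0) or the test subject's
ellipsoid and landmark table (centre in thorax coordinates). The subject's
semi-axis triple is published in thorax-frame axis order and is mapped to
the ellipsoid frame through R0t, giving (m, n, p) = (164.8, 114.4, 222.7)
mm — the only reading that keeps the longest axis vertical, consistent
with the generic set. Two consistency facts support these conventions: the
auxiliary length l₂₂ = 109.83 mm equals the c–d chord
√(l₂² + l₃² − 2 l₂ l₃ cos γ) = 109.83 mm, and the subject's AI landmark
lies on the subject ellipsoid to 0.2% with azimuth −44.8°, matching the
rhythm-table rest intercepts for ψ_d (−44.4° SCAP, −50.9° ABD).

The published scapula alignment R2s is visibly non-orthogonal (det ≈ 0.94;
two rows are ~20° from orthogonal — most plausibly a sign misprint). It is
kept verbatim with a warning, with an opt-in SVD re-orthonormalization;
ST-posture reporting projects the composed matrix onto SO(3) before
decomposition. The GH-centre offset printed for frame S2 has unstated
units and is stored untouched, unused by any computation.

## Inverse position solve

Unknowns are x = (θ₄, θ₅, θ₆, φ_c, ψ_c, φ_d) with inputs (θ₁, θ₂, ψ_d) and
θ₃ = 0; the residual is the six-component loop-closure gap in mm. The
iteration is damped Newton with a forward-difference Jacobian (step 1e-7
rad), backtracking line search, and a Levenberg fallback
((JᵀJ + λI)δ = −JᵀF with λ escalation) when the Newton step stalls or the
Jacobian condition exceeds 1e12. Defaults: residual-norm tolerance 1e-8 mm
(giving joint angles far beyond the 1e-6 rad verified in tests), 100
iterations. Non-convergence raises with the final residual and condition
estimate; trajectory solves flag failed frames instead of aborting and use
previous-frame warm starts.

Closed chains admit multiple assembly modes. The neutral initial guess
selects the anatomical branch constructively: d is the inferior
intersection of the ψ_d meridian with the sphere |b − d| = l₃ about the AC
joint b; c sits on the circle |c − b| = l₂, ∠(c−b, d−b) = γ, at its
superior on-surface root (c is above d on the scapula's medial border);
θ₄–θ₆ follow from the scapula frame built on (b, c, d). With a warm start
or user guess, Newton converges to the branch nearest the guess. The
parameterization degenerates at the ellipsoid poles (sin φ = 0, azimuth
undefined); anatomical postures keep both contact points far from the
poles, and solutions with φ_d < 0 (the mirrored branch, equivalent to an
azimuth flip of π) are what the geometric seed avoids.

## Input extraction

θ₁ = atan2(w_z, −w_x) and θ₂ = atan2(√(w_z² + w_x²), w_y) ∈ [0, π] from
the third column of R₁₀ = R0tᵀ Rct R1c — the quadrant-aware resolution of
the single-argument arctangent forms, chosen so all three scalar relations
(s₁s₂ = w_z, −c₁s₂ = w_x, c₂ = w_y) hold simultaneously. When
sin θ₂ ≈ 0 the clavicle lies along the global z-axis and θ₁ is
undetermined: the row is flagged (θ₁ = 0) and excluded from fitting
downstream, never dropped. ψ_d = atan2(m·y_AI, n·x_AI) from the AI
landmark in ellipsoid coordinates — the azimuth of its central (ray
through the centre) projection onto the surface, invariant to radial
scaling; both surface parameters of the projected point are reported.

## Rhythm model

Per task and dependent variable, v(HumX) = p₁HumX³ + p₂HumX² + p₃HumX + p₄
(degrees). The built-in tables carry all 48 published coefficients with
their fit diagnostics. Piecewise dispatch over HumY₁ uses half-open
intervals ([−10, 20), [20, 50), [50, 90]) — a hard switch, no blending —
and the elevation domain [0°, 165°] applies to all branches
(warn-and-evaluate outside). Fitting is ordinary least squares in a
centred/scaled basis (condition number ~10 instead of ~10⁹ for raw powers
of HumX), with coefficients mapped back exactly; reported diagnostics are
R² = 1 − SSres/SStot, RMSE in both the population (√(SSres/n)) and
dof-corrected (√(SSres/(n−4))) conventions — the published tables do not
say which — and analytic coefficient standard errors from
(XᵀX)⁻¹·SSres/(n−4).

## Synthetic trials

The generator emulates range-of-motion trials: HumX follows raised-cosine
lift/drop cycles (defaults: 5 cycles ABD, 4 SCAP/FLEX; 4 s per cycle;
100 Hz; subject geometry), HumY₁ wanders inside the task's
plane-of-elevation band as two incommensurate random-phase sinusoids at
80% of the band half-width (subjects drift about the nominal plane, and
this exercises the piecewise dispatch), and the girdle state per frame
comes from the rhythm functions plus the inverse solve, so every generated
frame satisfies the closure constraints before noise. The AI landmark is
placed radially outside contact point d by a factor 1.1 (AI sits off the
rib cage; the central projection must do real work yet stay exactly
invertible). Peak elevation defaults to 90°: the cubics are regressions,
and extrapolated far beyond the fitted regime they drive ψ_d through an
azimuth sweep of hundreds of degrees — assemblable by continuation but not
physiological. Ground truth is drawn from a seed-derived stream separate
from the noise stream, so gt columns are bit-identical across noise
settings at a fixed seed.

Noise is independent zero-mean Gaussian (default 0, in degrees) on every
observed output angle: the six Euler-angle columns directly, and the AI
landmark through its two angular placement parameters. Monte-Carlo
recovery checks regress on the true elevation: the 3-standard-error
guarantee is that of OLS with exact regressors, and regressing on the
noisy elevation instead adds errors-in-variables attenuation (measured
|z| up to ~9 at σ = 2°) — a property of the estimator, not of the
implementation. What the synthetic data does not emulate: marker-cluster
geometry and soft-tissue artifact, left shoulders, clavicle axial rotation
(θ₃ is exactly 0 here; real data would have a small nonzero spin), and
inter-subject rhythm variability. Passing tests therefore establish the
internal consistency of the model, solver, extraction and fitting — not
agreement with any particular subject's measured curves, which would
require the original motion-capture database.

## Numerical choices and limitations

* Loop-closure tolerance 1e-8 mm; forward-difference step 1e-7 rad;
  ellipsoid-membership checks at 1e-9; round-trip tolerances 1e-6 rad
  (solver) and 1e-9 (Euler decompositions away from flagged
  singularities).
* Degenerate inputs: θ₂ = 0 (clavicle vertical) flags extraction; AI at
  the ellipsoid centre has no projection and raises; an unreachable
  ellipsoid raises with the final residual.
* The solver accepts any warm start and thereby any 3-in/6-out branch the
  guess selects, but the three inputs are fixed as (θ₁, θ₂, ψ_d); other
  input partitions of the nine free variables would need their own
  residual wiring.
* Velocity/acceleration kinematics, muscle forces, workspace mapping, and
  subject scaling from landmark data (the "zoom factor" row is stored as
  metadata only) are out of scope.
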