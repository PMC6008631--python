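"""Inverse position solve of the girdle at the arm-hanging rest posture.

The three independent inputs (theta1, theta2, psi_d) are taken from the
rhythm-table intercepts at zero humeral elevation (ABD task); the solver
returns the six dependent joint variables that close the loop, i.e. place
both scapular contact points on the thorax ellipsoid.
"""

import numpy as np

from shoulderkin import GirdleInputs, constraint_residual, default_geometry, solve_girdle
from shoulderkin.rhythm import builtin_rhythm, rhythm_eval

g, e, landmarks = default_geometry("subject_s1")
rest = rhythm_eval(builtin_rhythm().tables["ABD"], 0.0)
inputs = GirdleInputs(
    theta1=np.radians(rest["theta1"]),
    theta2=np.radians(rest["theta2"]),
    psi_d=np.radians(rest["psi_d"]),
)
state = solve_girdle(inputs, g, e, p_sc=landmarks["SC"])
residual = np.linalg.norm(constraint_residual(state, g, e, p_sc=landmarks["SC"]))

print(f"inputs:  theta1 = {rest['theta1']:.2f} deg, theta2 = {rest['theta2']:.2f} deg, "
      f"psi_d = {rest['psi_d']:.2f} deg")
for name in ("theta4", "theta5", "theta6", "phi_c", "psi_c", "phi_d"):
    print(f"solved:  {name:7s} = {np.degrees(getattr(state, name)):8.2f} deg")
print(f"loop-closure residual = {residual:.2e} mm "
      "(both contact points on the thorax ellipsoid)")
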