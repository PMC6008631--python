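"""Evaluate the piecewise shoulder-rhythm model across humeral postures.

For a grid of (plane of elevation HumY1, elevation HumX) the model selects
the task band (ABD / SCAP / FLEX) by HumY1 and evaluates that task's cubic
regressions, predicting the girdle inputs (theta1, theta2, psi_d) and the
humeral axial rotation HumY2, all in degrees.
"""

from shoulderkin.rhythm import builtin_rhythm, dispatch_task, rhythm_piecewise

model = builtin_rhythm()
print(f"{'HumY1':>6} {'HumX':>6}  task  {'theta1':>8} {'theta2':>8} {'psi_d':>8} {'HumY2':>8}")
for hum_y1 in (0.0, 35.0, 70.0):
    for hum_x in (0.0, 30.0, 60.0, 90.0):
        v = rhythm_piecewise(model, hum_y1, hum_x)
        task = dispatch_task(model, hum_y1)
        print(
            f"{hum_y1:6.0f} {hum_x:6.0f}  {task:<5}"
            f" {v['theta1']:8.2f} {v['theta2']:8.2f} {v['psi_d']:8.2f} {v['HumY2']:8.2f}"
        )
print("\nEach row: predicted girdle posture (deg) for one humeral posture; "
      "at HumX = 0 the values are the task's fitted intercepts.")
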