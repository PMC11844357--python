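"""Stability margins of the feedback loop and the gain-swap counterfactual.

The feedback pathway PB is the open-loop transfer function of the
disturbance-rejection loop, so classical gain and phase margins quantify
how close each group operates to instability.  The counterfactual asks:
if the ataxia group (feedback gain 1.0, delay 144 ms) adopted the control
group's higher gain (1.3) without shortening its delay, would tracking
improve?  Margins shrink and tracking error does not improve — consistent
with the lower ataxia gain being an adaptation to the longer delay.
"""
import numpy as np

import trackloop as tl

for group in ("control", "ataxia"):
    fb = tl.PathwayModel(**tl.GROUP_PARAMS[group]["feedback"])
    m = tl.stability_margins(fb)
    print(f"{group:8s} gain margin {m.gain_margin:6.2f}  "
          f"phase margin {m.phase_margin_deg:6.1f} deg  "
          f"(crossovers {m.gain_crossover_hz:.3f} / "
          f"{m.phase_crossover_hz:.3f} Hz)")

grid = tl.build_frequency_grid()
rng = np.random.default_rng(3)
ref = tl.make_signal_groups(grid, "reference", rng)
dist = tl.make_signal_groups(grid, "disturbance", rng)
plan = tl.build_session_plan(grid, rng_seed=3)

p = tl.GROUP_PARAMS["ataxia"]
subject = tl.SyntheticSubject("ax_demo",
                              tl.PathwayModel(**p["feedforward"]),
                              tl.PathwayModel(**p["feedback"]))
res = tl.gain_swap_experiment(subject, 1.3, plan, ref, dist, 75.0, 80.0)
print(f"\ngain swap {res.original_gain} -> {res.swapped_gain}:")
print(f"  tracking MSE   {res.mse_original:.3f} -> {res.mse_swapped:.3f} cm^2")
print(f"  gain margin    {res.margins_original.gain_margin:.2f} -> "
      f"{res.margins_swapped.gain_margin:.2f}")
print(f"  phase margin   {res.margins_original.phase_margin_deg:.1f} -> "
      f"{res.margins_swapped.phase_margin_deg:.1f} deg")
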