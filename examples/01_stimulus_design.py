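"""Design the sum-of-sines stimulus and the 16-trial session plan.

The frequency grid is the first 20 prime multiples of a 0.04 Hz base
(0.08 to 2.84 Hz): prime multipliers guarantee that no stimulated frequency
is a harmonic or an intermodulation sum/difference of any two others, so
each frequency carries independent information about the loop.  Component
amplitudes follow a velocity-limited profile min(c_v / f, cap), with caps
of 2.3 cm for the reference and 1.5 cm for the disturbance.
"""
import numpy as np

import trackloop as tl

grid = tl.build_frequency_grid()
print(f"grid: {len(grid)} frequencies, "
      f"{grid.frequencies[0]:.2f}-{grid.frequencies[-1]:.2f} Hz")
print("multipliers:", grid.multipliers)

for role, (coeff, cap) in (("reference", (1.3, 2.3)),
                           ("disturbance", (0.7, 1.5))):
    mags = tl.amplitude_profile(grid.frequencies, coeff, cap)
    peak_vel = 2 * np.pi * np.max(grid.frequencies * mags)
    print(f"{role:12s} max amplitude {mags.max():.2f} cm, "
          f"peak component velocity {peak_vel:.2f} cm/s")

# Each axis of each trial gets a disjoint quarter of the grid for the
# reference and for the disturbance; a 4-row rotation crossed with the two
# preview conditions and two repetitions gives 16 trials per session.
rng = np.random.default_rng(0)
ref = tl.make_signal_groups(grid, "reference", rng)
dist = tl.make_signal_groups(grid, "disturbance", rng)
print("\nreference group r1 frequencies (Hz):",
      np.round(ref["r1"].frequencies, 2))

plan = tl.build_session_plan(grid, rng_seed=0)
print(f"\nsession: {len(plan.trials)} trials")
for slot in plan.trials[:4]:
    print(f"  trial {slot.trial:2d}  preview {slot.preview_ms:3d} ms  "
          f"composition {slot.composition}")
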