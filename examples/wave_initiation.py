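"""Ca2+ waves initiated by a sensitive central region.

Runs the deterministic 25 x 25 network with a 3 x 3 central region of higher
sensitivity (20% higher stimulus plateaus). Once every cell is stimulated,
each oscillation cycle starts in the sensitive center and sweeps outward as
a phase wave; the script reports the initiating cell and the radial speed.
"""

from cawave import build_dense_grid, wave_speed
from cawave.phase import first_spiker
from cawave.presets import run_experiment

traj = run_experiment("fig3", seed=0)  # d = 0.003
grid = build_dense_grid(25, 25)

node, t = first_spiker(traj, t_from=traj.config["t1_max"])
print(f"first spike once all cells are stimulated: cell {node} at t = {t:.1f} s")
print("(the sensitive 3x3 region spans cells (12..14, 12..14))")

speed, ci95, n_waves = wave_speed(traj, grid)
print(f"radial wave speed: {speed:.2f} +/- {ci95:.2f} cells/s "
      f"(95% CI over {n_waves} waves)")
# the most sensitive cells oscillate fastest and therefore pace the network:
# each of their spikes seeds an outward-travelling ring.
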