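"""Validate the full reconstruction pipeline on simulated trajectories.

Simulates an asynchronously cycling population (single-wave E2F3A/E2F8,
two-wave E2F4, EdU/pH3 pattern runs), samples per-nucleus measurement tables
from it, runs quantization -> graph initialization -> pH3/EdU registration ->
Hungarian refinement, and scores recovery by per-marker mean squared error
against the generated truth (levels^2 for E2Fs, ordinal state codes^2 for
EdU/pH3, after the best circular alignment per marker and sample).
"""

from snapcycle.pipeline import run_simulation_study
from snapcycle.simulate import SimulationSpec

spec = SimulationSpec(nb_i=4, nb_t=100, nb_s=3, nb_s2=2, noise_fraction=0.0, seed=1)
study = run_simulation_study(
    spec, cells_per_image=400, images_per_mouse=3, n_iters=25
)

print("per-marker MSE after registration:")
for marker, mse in study.mse_registered.per_marker.items():
    print(f"  {marker:6s} {mse:6.3f}")
print("per-marker MSE after global refinement:")
for marker, mse in study.mse_refined.per_marker.items():
    print(f"  {marker:6s} {mse:6.3f}")
# An MSE of 0.1 on a 0..4 level scale means the reconstructed wave deviates by
# ~0.3 of a level per bin on average; EdU/pH3 near zero means the S-phase and
# mitosis pattern runs were placed almost exactly.  E2F4 is hardest: its two
# waves share histogram cells, which the minimum-cost traversal compresses.

from snapcycle.optimize import fit_profile

profile = fit_profile(study.result.refined, "E2F3A")
peak = int(profile.values.argmax()) + 1
print(f"\nfitted E2F3A profile peaks at bin {peak} of {spec.nb_t} "
      f"(level {profile.values.max():.2f})")
# The periodic spline pools all mice and couples containing E2F3A; with the
# cycle anchored so mitosis ends at bin 100, the peak bin locates the E2F3A
# maximum relative to mitosis.
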