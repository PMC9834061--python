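"""Full iterative helical reconstruction on synthetic filaments.

Generates a small filament dataset at SNR 0.1, runs the three-iteration
2D-projected reconstruction pipeline (segment -> orient -> project -> align
-> back-project -> refine rise/twist -> symmetrize), and prints the refined
helical parameters next to the generative truth.
"""

from pathlib import Path

from helicta import (
    AcquisitionGeometry,
    RunConfig,
    lokiactin_filament_dataset,
    run_filament_pipeline,
    write_volume,
)

out = Path("scratch/example02")
out.mkdir(parents=True, exist_ok=True)

n_filaments = 8  # 20 for the full-scale experiment; 8 keeps this quick
data = lokiactin_filament_dataset(n_filaments, snr=0.1, seed=7)
config = RunConfig(pixel_size_unbinned=5.36, binning=1, n_iterations=3,
                   rng_seed=7, box_size=64)

result = run_filament_pipeline(
    config,
    [d[0] for d in data],
    [d[1] for d in data],
    geometry=AcquisitionGeometry(),
)

write_volume(result.map, out / "symmetrized_map.mrc")
print(f"segments used in the final reconstruction: {result.n_particles_used}")
print(f"refined rise : {result.refined.rise:6.2f} A/subunit   (truth 27.90)")
print(f"refined twist: {result.refined.twist:6.2f} deg/subunit (truth -167.70)")
print(f"half-set FSC resolution (0.143): {result.resolution:.1f} A")
# The refined values come from maximizing the map's self-correlation under
# helical symmetry; at this noise level they land within a few tenths of an
# Angstrom / degree of the generative parameters.
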