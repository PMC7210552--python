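#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces the rest-state and counterpulsation-state CCA velocity
waveforms (the during-state adds a diastolic augmentation peak near
0.56 T), the lumen diameter waveform, the bifurcation wall geometry with
a 15% diameter stenosis on the ICA, and the noisy MR-like slice stack of
the trunk with its ground-truth contours.
"""

from pathlib import Path

import numpy as np

from eecp_hemoflow.io import write_contours_csv, write_image_stack
from eecp_hemoflow.synthdata import (
    GeometrySpec,
    ImageStackSpec,
    WaveformSpec,
    generate_bifurcation_geometry,
    generate_diameter_waveform,
    generate_mr_stack,
    generate_velocity_waveform,
    measure_stenosis,
    velocity_waveform_mean,
)

OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

wspec = WaveformSpec()
for state in ("pre", "during"):
    w = generate_velocity_waveform(wspec, state)
    w.to_csv(OUT / f"velocity_{state}.csv")
    print(
        f"{state:6s}: cycle-mean velocity {w.cycle_mean():.4f} m/s "
        f"(closed form {velocity_waveform_mean(wspec, state):.4f})"
    )

gspec = GeometrySpec()
dia = generate_diameter_waveform(wspec, 2 * gspec.cca_radius, 0.05)
dia.to_csv(OUT / "diameter.csv")
print(f"diameter: mean {dia.cycle_mean()*1e3:.2f} mm, pulsation 5%")

mesh = generate_bifurcation_geometry(gspec)
mesh.save_stl(OUT / "bifurcation.stl")
mesh.save_vtk(OUT / "bifurcation.vtk")
sten = measure_stenosis(mesh, gspec)
print(
    f"geometry: {len(mesh.faces)} faces, Euler characteristic "
    f"{mesh.euler_characteristic()}, measured diameter stenosis {sten*100:.1f}% "
    f"(spec {gspec.plaque_depth_frac*100:.0f}%)"
)

ispec = ImageStackSpec(noise_sigma=16.0, clutter_blob_count=3, seed=7)
stack, truth = generate_mr_stack(gspec, ispec)
write_image_stack(OUT / "stack", stack)
write_contours_csv(OUT / "truth_contours.csv", truth)
print(f"stack: {stack.shape[0]} slices of {stack.shape[1]}x{stack.shape[2]} px")
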