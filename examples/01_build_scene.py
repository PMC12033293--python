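"""Build a synthetic ptychography scene and inspect its ingredients.

Creates the reduced-size scene (64 px frames, same 29.6 nm pixel pitch as
the full-scale study), then prints the derived geometry, the probe footprint
and the nominal overlap of the spiral scan.
"""

import ptystream as ps

scene = ps.build_scene(ps.scaled_scene_config(step_px=4.0, n_points=60))

g = scene.geometry
print(f"wavelength:        {g.wavelength * 1e9:.4f} nm")
print(f"real-space pixel:  {g.real_space_pixel * 1e9:.2f} nm")
print(f"object grid:       {scene.grid_side} x {scene.grid_side} px")

diameter = ps.probe_power_diameter(scene.probe_truth.field)
print(f"probe 90%-power footprint: {diameter:.1f} px")
print(f"scan: {scene.scan.n_points} points, step {scene.scan.step} px, "
      f"nominal overlap {scene.scan.overlap:.1%}")

# The overlap is the shared illuminated area of neighbouring scan positions:
# above ~60% the joint object/probe retrieval is well conditioned.
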