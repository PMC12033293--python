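"""Simulate a noisy diffraction dataset and its streaming delivery schedule.

Each far-field frame carries Poisson photon noise; the chunk stream emulates
frames produced at a fixed cadence and handed over in chunks, on a logical
clock (no wall time involved).
"""

import numpy as np

import ptystream as ps

scene = ps.build_scene(ps.scaled_scene_config(step_px=4.0, n_points=60))
dataset = ps.simulate_scene_dataset(scene, seed=7)

totals = [f.counts.sum() for f in dataset.frames]
print(f"{dataset.n_frames} frames; photons per frame: "
      f"min {min(totals):.3g}, median {np.median(totals):.3g}, max {max(totals):.3g}")
# each frame should carry roughly the probe's photon budget (1e10), minus
# what the gold absorbs at that scan position

stream = ps.make_chunk_stream(dataset, chunk_size=10, delay=0.6)
for c, (chunk, t) in enumerate(zip(stream.chunks, stream.arrival_times)):
    print(f"chunk {c}: frames {chunk.start:3d}-{chunk.stop - 1:3d} "
          f"available at t = {t:5.1f} s")
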