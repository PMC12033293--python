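"""Run the reduced-size version of the full study matrix and render outputs.

Two step sizes, streaming and offline reconstructions with matched totals,
three compared pairs each. Writes the table, the per-iteration NMSE trace of
the sparsest scan and difference-map images under scratch/scaled_study/.
"""

import ptystream as ps

config = ps.scaled_study_config(
    engine=ps.EngineConfig(iterations_per_interval=80, post_load_iterations=400),
    compute_traces=True,
)
results = ps.run_study(config)

for cell in results.cells:
    print(f"step {cell.step_px:4.1f} px  (overlap ~{cell.overlap_label:.0%}, "
          f"seed {cell.seed}): total {cell.total_iterations} iterations")
    block = results.nmse_block(cell.step_px)
    for pair, value in block.items():
        print(f"    NMSE {pair:20s} {value:.3e}")

written = ps.render_outputs(results, "scratch/scaled_study")
print("\nwrote:", ", ".join(str(p) for p in written.values()))
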