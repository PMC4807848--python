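"""Phase-field morphology learning: a lobed cell from circular initial data.

The cell surface is the 0.5-level set of the exterior phase fraction; its
Helfrich bending energy carries a spontaneous-curvature field C1 that the
model learns so that the relaxed surface matches a prescribed target — here
a circle with 25 superimposed lobes (the full-resolution benchmark runs at
256^2; this demo uses a 128^2 grid and larger lobes and finishes in
seconds).
"""

import numpy as np

from blipsim import phase_field as pf

res, g, phit, params = pf.run_lobed_benchmark(
    n_lobes=25, amplitude=0.25, grid_n=128, n_outer=30, n_inner=200)

print(f"grid 128^2, interface thickness eps = {params.eps:.4f} box units")
print(f"target surface length (coarea): {params.target_area:.3f}")
print(f"outer iterations used: {res.n_outer}")
print(f"mean contour distance to target: {res.mismatch:.5f} "
      f"(= {res.mismatch / g.h:.2f} grid spacings; tolerance 2)")
print(f"lobes on the converged contour: {pf.count_lobes(res.state)}")
print(f"learned C1 range on the grid: [{res.C1.min():.0f}, {res.C1.max():.0f}] "
      "(1/box units)")
print("\nThe converged surface reproduces the target morphology; C1 is the "
      "model's inferred\nmap of membrane-cortex attachment heterogeneity.")
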