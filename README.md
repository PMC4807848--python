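# blipsim

Models of excess cell-surface storage in bleb-like protrusions (BLiPs).

When an adherent cell detaches and rounds up — in mitosis, or during
mesenchymal-to-amoeboid transitions — its volume is conserved but its
plasma membrane suddenly exceeds the area of the smooth sphere enclosing
that volume by several fold (up to ~14x). The excess is stored in a dense,
size-skewed population of approximately spherical protrusions on the cell
surface. `blipsim` is for biophysicists who want to simulate and reason
about that storage quantitatively. It implements three complementary
models:

1. **Closed-form geometry** (`blipsim.surface_math`) — excess-ratio
   arithmetic and the analytic bound: a sphere coated with *equal*
   spherical BLiPs of radius `r` (footprint coverage `f`) has excess
   `1 + 4f`, with supremum **5** as `r -> 0`; observed 14-fold excess
   therefore requires heterogeneous BLiP sizes.

2. **A 2D two-layer Hamiltonian** (`blipsim.discrete_fold_model`) — cell
   surface and contractile cortex as closed bead-spring chains coupled at
   `M` contact points:

       H = c1 Σ κ_i² + c2 Σ (l_i − L/N)²  +  c3 Σ p_j² + c4 (A − Ā)²
         + c5 Σ ‖t_i − τ_i‖²  +  H_cross + H_self

   Minimization from a contracting cortex yields exactly `M` flask-shaped
   folds; bending energy grows with `M` and falls with the excess ratio
   `ER = L / (2√(πĀ))`.

3. **3D BLiP packing** (`blipsim.blip_packing`) — spherical-Voronoi
   (bell-shaped radii) versus seed-and-growth packing (tangent spheres
   grow at a uniform rate, freeze at first contact; radii inherit the
   skewed seed-spacing statistics seen in scanning electron micrographs),
   with surface/volume fractions, thin sections, and level-set export.

4. **A multi-phase-field model** (`blipsim.phase_field`) — three phases
   (exterior medium, nematic actomyosin cortex, cytosol), diffuse-interface
   surface tension, Helfrich bending `(γ_b/2)∮(H − C1)² dA` with a
   *learnable* spontaneous-curvature field `C1`, nematic Frank–Oseen /
   Landau–de Gennes cortex energy with anchoring, and a surface-area
   penalty `(λ_S/2)(S − s0·S*)²` prescribing the excess ratio `s0`.
   Conserved Cahn–Hilliard relaxation evolves the phases; the model learns
   `C1` until its 0.5-level surface matches a target morphology (a
   digitized 2D cell periphery or a packed-cell 3D reconstruction).

`blipsim.blip_morphometrics` adds the SEM measurement model (projected
patch read as a great circle, `r = √(A/π)`) and a lognormal radius fixture
matched to measured summary statistics. `blipsim.io` handles contour CSV,
NPZ grids, legacy VTK, OBJ and run metadata.

See `docs/methods.md` for the full model descriptions, parameter defaults
and numerical choices.

## Worked example

`examples/phase_field_lobes.py` learns a lobed morphology from circular
initial data on a 128² grid (the full benchmark uses 256²):

```
$ python examples/phase_field_lobes.py
grid 128^2, interface thickness eps = 0.0156 box units
target surface length (coarea): 5.199
outer iterations used: 3
mean contour distance to target: 0.00711 (= 0.91 grid spacings; tolerance 2)
lobes on the converged contour: 25
learned C1 range on the grid: [-160, 160] (1/box units)
```

The converged cell surface reproduces all 25 target lobes to sub-grid mean
accuracy; the learned `C1` map is the model's inferred spatial pattern of
membrane–cortex attachment. The other examples cover the excess-area
arithmetic (`excess_surface_arithmetic.py`), fold-model steady states and
their energy trends (`fold_model_steady_states.py`), the two packing
models and their radius statistics (`blip_packing_models.py`), and the
SEM-style size measurement (`projected_blip_sizes.py`); each prints the
numbers it computes with a line on what they mean.

## Acceptance script

`scripts/acceptance.py` recomputes the package's two headline numbers from
scratch — the analytic equal-BLiP excess limit (supremum over footprint
coverage), and the lobe count of the converged 2D phase-field run against
the 25-lobe Fourier target on a 256² grid — and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
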