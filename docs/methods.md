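# Methods

`blipsim` models how a rounding cell stores severalfold excess plasma
membrane in bleb-like protrusions (BLiPs). Three complementary models are
implemented; this note records their assumptions, parameters, numerical
choices and limitations.

## 1. Closed-form excess-area geometry (`surface_math`)

The excess surface ratio of a rounded cell is the actual membrane area
divided by the area `4*pi*R^2` of the smooth sphere enclosing the cell
volume. For a sphere uniformly coated with equal spherical BLiPs of radius
`r`, each BLiP contributes its full area `4*pi*r^2` over a flat footprint
disk `pi*r^2` (the base sphere is counted intact; tangency hides zero
area), so a footprint coverage fraction `f` yields an excess of `1 + 4f`.
The supremum over all packings — `r -> 0`, `f -> 1` — is exactly **5**.
Observed excesses of up to ~14 therefore require size-heterogeneous BLiPs
or non-spherical storage. The flat-footprint approximation deliberately
omits finite-`r` spherical-cap corrections; only the limit is asserted.

Discrete contours use one curvature estimator package-wide: the turning
angle at a vertex divided by the mean adjacent segment length. It converges
to the continuum curvature under refinement, and the normalized total
bending energy `E = (L/N) * sum_i kappa_i^2` tends to the contour integral
of squared curvature (`2*pi/R` for a circle). `E` is invariant under rigid
motions and scales as `1/s` under dilation by `s`.

## 2. Two-layer bead-spring fold model (`discrete_fold_model`)

State: an outer closed chain of `N` beads (the cell surface: plasma
membrane plus spectrin-actin mesh) and an inner closed chain of `M` beads
(the contractile actomyosin cortex), tied pairwise at `M` contact points.
The Hamiltonian is

    H = c1*sum kappa_i^2 + c2*sum (l_i - L/N)^2        (surface bending + inextensibility)
      + c3*sum p_j^2 + c4*(A - A_target)^2             (cortex contraction + target area)
      + c5*sum ||t_i - tau_i||^2                       (contact springs)
      + c6*sum_{beads in cortex} d^2                   (no surface inside the cortex)
      + H_self (hard, c7 -> infinity)                  (no surface self-crossing)

The cortex springs have zero rest length (pure contraction); the excess
surface ratio `ER` is the prescribed outer perimeter over the perimeter of
the circle of area `A_target`. Working units fix `A_target = pi` (unit
contracted-cortex radius).

**Weights.** Only `c2 >> c1` is physically prescribed. Defaults are
`c1 = 1, c2 = 1e8, c3 = 1, c4 = 1e7, c5 = 1e8, c6 = 1e8`: at `N = 400` the
bending forces at fold necks reach ~`kappa^3 ~ 1e3-1e4`, and holding the
spring/area/contact residuals below 1% of their scales requires constraint
stiffness of that order squared. The values were fixed once from this force
balance and verified across the whole `(M, ER)` grid.

**Finding the M-fold steady state.** The uniform M-fold configuration is an
equilibrium of `H` but only marginally stable against fold pairing — fewer,
larger folds are cheaper (the model's own coarsening prediction), so any
unconstrained full-space descent at `M >= 40` drifts out of the M-fold
basin; likewise, plain damped descent from the coincident-circle initial
condition buckles at its own spontaneous wavelength (~12 lobes at
`N = 400`) instead of the contact template. `steady_state` therefore
(i) constructs the intermediate configuration directly — cortex contracted
to a regular M-gon of the target area, surface excess hanging in M
identical flask-shaped folds of the correct arc length — and (ii) relaxes
it with L-BFGS in the C_M-symmetric subspace via gradient projection: every
energy term is that of the full chain, the pairing mode is excluded by
symmetry, and the result is an exact equilibrium of the full Hamiltonian
with uniform folds. Self-avoidance under the quasi-Newton steps is realized
as a stiff short-range bead repulsion (excluded volume standing in for
`c7 = infinity`); every returned state is verified exactly crossing-free by
an all-pairs proper-intersection test.

The literal constrained descent is kept as `minimize`: FIRE-type damped
dynamics with per-step energy rejection (energy non-increasing along
accepted steps) and the rule that any bead whose proposed move would create
a proper self-crossing is kept fixed for that iteration.

**Reported trends** (shapes rescaled to a common enclosed area first):
bending energy increases with `M` at fixed `ER`, decreases with `ER` at
fixed `M`, and the area stored inside folds decreases with `M`.

## 3. BLiP packing on the sphere (`blip_packing`)

*Voronoi model*: `n` seeds uniform on the sphere; each spherical-Voronoi
cell of geodesic area `v` becomes a BLiP of radius `sqrt(v/(4*pi))`
(`scipy.spatial.SphericalVoronoi`; `n = 1, 2` in closed form). Cell areas
sum to the sphere area; the radius distribution is bell-shaped.

*Seed-and-growth model*: tangent spheres grow at a uniform rate, riding
radially outward so `|center| = R + r`, and freeze at first contact. The
growth is integrated exactly event-by-event: a growing-growing pair meets
at `t = R*d/(2-d)` (`d` the seed chord distance) and a growing-frozen pair
at the root of a linear equation; freezing only postpones contacts, so a
lazy priority queue processes events in order. At a mutual growing-growing
contact both spheres freeze (`freeze="both"`, default); the alternative
`"first"` freezes one and re-examines the survivor, which in practice
freezes immediately because its outward ride cannot open the gap. A cap
`r_max` (default `R`) bounds isolated seeds. The independent cross-check
integrator advances all radii in small steps and bisects any step that
would create a new contact; it shares no closed-form contact times with the
event-driven path and agrees to ~1e-6 R at n = 300.

Radii are proportional to local seed spacing, so the distribution is
right-skewed (mode < median < mean), unlike the Voronoi model — the
packing's key qualitative prediction.

**Excess-ratio bookkeeping.** `surface_fraction` normalizes by the *base
sphere* (`total/(4*pi*R^2)`), the convention whose equal-BLiP limit is 5.
The physiological excess compares area against the smooth sphere enclosing
the same *total volume* (cytoplasm fills the BLiPs);
`excess_ratio_volume_equivalent` implements it. Against BLiP number the two
trend oppositely: small-`n` packings grow few, very large BLiPs whose area
inflates the base-normalized ratio but whose volume inflates the equivalent
sphere even faster. The volume-equivalent excess increases with `n` while
the BLiP volume fraction decreases — many small BLiPs add area much faster
than volume.

## 4. Morphometrics (`blip_morphometrics`)

The SEM measurement model: each visible protrusion is a sphere whose
projected patch is its great circle, so `r = sqrt(A/pi)`; the hidden
tangent cap is ignored, making synthetic and measured tables commensurable.
The synthetic projector records near-hemisphere BLiPs (optionally dropping
those whose projected centers fall inside a nearer BLiP's disk) and is
lossless without occlusion. The skewed radius fixture is lognormal with
`mu = ln(median)` and `sigma = sqrt(2 ln(mean/median))` — matched in
expectation to the measured mean 0.25 um and median 0.22 um; the implied
mode `median*exp(-sigma^2) ~ 0.17 um` sits near the measured 0.19 um. The
lognormal family is a choice; only mean/median are matched.

## 5. Multi-phase-field model (`phase_field`)

Three volume fractions on a periodic grid — `phi1` exterior medium, `phi2`
nematic cortex, `phi3` cytosol, `phi1+phi2+phi3 = 1` enforced exactly by
evolving two and deriving the third. The cell surface is the level set
`phi1 = 0.5`; the cortex-cytosol interface is `phi2 = phi3 = 0.5`. The free
energy is the sum of

* interfacial tension `K_SURF * sum_i gamma_is * int f(phi_i)` with
  `f = eps/2 |grad phi|^2 + W/eps`, `W = phi^2(1-phi)^2`, plus a
  three-phase penalty `(gamma123/eps) int (phi1 phi2 phi3)^2`;
* Helfrich bending
  `K_BEND*(gamma1b/eps) * int (eps lap phi1 - W'/eps - sqrt(2) C1 phi1(1-phi1))^2`,
  which reduces on a resolved interface to `(gamma1b/2) int (H - C1)^2 dA`
  (`H`: sum of principal curvatures, `C1`: spontaneous curvature);
* Frank-Oseen + Landau-deGennes nematic energy gated by `phi2^2`, with
  equilibrium scalar order `|p| = sqrt(h1/h2)` for `h1 > 0` (the Flory
  order parameter is `h1/h2`) and the isotropic state for `h1 <= 0`;
* anchoring `(alpha1/2) int (p . grad phi1)^2` (`alpha1 > 0` tangential);
* a surface-area penalty `(lam_S/2)(S - s0 S*)^2` prescribing the excess
  ratio `s0`.

**Calibration.** The equilibrium profile of `f` is
`phi(d) = (1 + tanh(d/(sqrt(2) eps)))/2`; with `K_SURF = 3*sqrt(2)` the
`f`-integral equals geometric area exactly (slab test ~1e-10, sphere to
`O((eps/R)^2)` < 2% at the default resolution), and with
`K_BEND = 3/sqrt(2)` a sphere's bending energy is `8*pi*gamma1b`
independent of radius (the diffuse Willmore identity, numerically exact to
4 digits at 96^3). Targets are built with the same profile, so constructed
targets are exact equilibria.

**Dynamics.** Stationary morphologies are reached by gradient flows:
conserved Cahn-Hilliard transport for `phi1, phi2` — phase volumes are
conserved to machine precision because the k = 0 mode is untouched — and
non-conserved relaxation for the director, evolved only where
`phi2 > 0.01` with automatic substepping under the explicit stability
bound. Phase stepping is semi-implicit Fourier-spectral with linear
stabilization `Lambda(k) = 4*(S0 + a2 k^2 + a4 k^4)`; the factor 4 matters
because for stiff modes the update degenerates to a fixed-point iteration
with step `1/Lambda`, so `Lambda` must dominate the true Jacobian
regardless of `dt`. Hydrodynamics (pressure and Ericksen-stress maps) are
out of scope; the stationary predictions are energy-variational.

**Area measure.** The energy-form estimate (`K_SURF * int f`) is exact on
equilibrium profiles but can be satisfied by off-equilibrium profile
*widening*; used as the drive of the area penalty it inflates the interface
instead of lengthening it. `FieldParams.area_measure = "coarea"` switches
the penalty to `S = int 6 phi1(1-phi1) |grad phi1|`, which by the coarea
formula is the geometric area for any monotone profile. Benchmarks use the
coarea measure; the energy-form estimator remains the default reporting
quantity. Two force-level regularizations accompany it: the penalty drive
`lam_S*(S - s0 S*)` is clamped to `sa_drive_max` (a bounded inflation
pressure — unbounded drive acts as a runaway negative surface tension), and
the drive force is gated to the interfacial band by `clip(4 phi1(1-phi1))`
(an ungated force pumps bulk noise into satellite droplets). With the clamp
active the dynamics is not strictly a gradient flow, so the energy-descent
contract applies to unclamped settings.

**Spontaneous-curvature learning.** `C1` is initialized with the target
surface's curvature extended constantly along normals (nearest-surface
value; computed from the polyline in 2D, from `lap(d)` on the band in 3D)
and clamped to `|C1| <= 2.5/eps` — sharper curvature is unresolvable and
destabilizes the bending force. The loop alternates `n_inner` relaxation
steps with the proportional correction
`C1 <- C1 + eta*(phi1 - phi1_target)` on the interfacial band. The sign is
the *local-feature* rule: where the target cell extends beyond the current
surface, raising the preferred curvature nucleates an outward bulge there
(the opposite, global-resizing intuition — lower `C1` to grow — locks the
lobe pattern exactly anti-phase to the target; this was diagnosed by
cross-correlating contour radial profiles). `eta` defaults to `0.25/eps`;
on three consecutive non-improving iterations the loop backs off to the
best iterate and halves `eta`. Convergence is measured as the symmetric
mean nearest-neighbour distance between 0.5-contours in 2D (band-L1
mismatch in 3D).

**Benchmark working point** (256^2, `eps = 2h`, box 1): tensions
`gamma_is = gamma123 = 1`, `gamma1b = 1e-4` (places the roughening cutoff
of the area drive just above the lobe wavenumber), `lam_S = 100`,
`sa_drive_max = 4`, `dt = 1e-5`, `n_inner = 200`. The 25-lobe target
(base radius 0.25 box, amplitude 0.15) converges from circular initial data
in ~5 outer iterations to ~0.7 grid spacings mean contour distance.

**3D runs** are scaled-down qualitative reproductions (48^3 in tests):
target from a seed-and-growth packed cell via its signed-distance export,
volume-matched sphere initial data, `s0` measured from the target; the
asserted outcomes are mismatch decrease and volume conservation, since no
quantitative 3D reference values exist.

## What a green test does and does not establish

The synthetic generators emulate the *statistical shape* of the
measurements: skewed radius distributions with matched mean/median,
projected-area tables under the great-circle reading, prescribed excess
ratios. They do not emulate imaging noise, segmentation bias, occlusion
statistics of real SEM, or BLiP dynamics (the seed-growth-and-shrinking
remodeling is explicitly out of scope). Measured population statistics
(mean BLiP radius 0.25 um, rounded-cell radius 8.36 um, mean excess 3.8)
parameterize fixtures; they are not reproduction targets.

## Known limitations

* The M-fold steady states are symmetric equilibria; their marginal
  stability to pairwise fold coalescence is physical (coarsening) and means
  unconstrained dynamics would slowly merge folds.
* The learning controller is proportional with a saturating `C1`; targets
  with sub-grid curvature features (sharp lobe tips) converge in contour
  distance but cannot match curvature pointwise.
* 2D phase-field contours live on a periodic box; boundaries must stay far
  from the cell (default: cell diameter = half the box).
* The Voronoi model's `n = 3` (all seeds on a great circle) is degenerate
  and rejected rather than special-cased.
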