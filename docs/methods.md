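# Methods

`trabtopo` reconstructs trabecular-scale bone microstructure from a
continuum-resolution 2D density image by topology optimization, and
quantifies how closely a *localized* reconstruction (ROI model + estimated
local loads) reproduces the *conventional* reconstruction (full refined
global model). This note records the models, the numerical choices, and
what the synthetic phantom does and does not establish.

## Physical model

Bone is represented as a masked grid of relative densities
ρ ∈ [0.01, 1] (0.01 ≈ marrow, 1 = fully mineralized tissue) on square
pixels. Every active pixel is one 4-node bilinear quadrilateral element in
plane stress with unit thickness and 2×2 Gauss quadrature; Poisson ratio
0.3 everywhere. Two density→modulus laws share the reference modulus
E₀ = 15 GPa:

* **micro level (design elements):** SIMP, `E = ρ^γ E₀` with γ = 3 —
  penalizes intermediate densities so the optimizer is driven to a
  near-binary strut layout;
* **continuum level (non-design elements):** the two-branch apparent-density
  regression `E = 0.3044 (2ρ)^1.49 E₀` for ρ ≤ 0.84 and
  `E = 0.1908 (2ρ)^2.39 E₀` above. The factor 2 maps relative density to
  the apparent-density scale of the regression; the two branches agree at
  ρ = 0.84 and return E₀ at ρ = 1 to within 0.1%, which is the consistency
  check the tests enforce.

The global model is fully fixed along the distal cut (the bottom edge of
the shaft); loads are three daily-activity cases — one-legged stance,
abduction, adduction — each a hip-contact force on the femoral head
(2317 / 1158 / 1548 N at 24 / −15 / 56° from vertical) plus an abductor
force on the greater trochanter (703 / 351 / 468 N at 28 / −8 / 35°), with
normalized weights 0.6 / 0.2 / 0.2 (relative daily cycle counts). A
positive angle tilts the force toward the lateral side, so the stance
force enters the superomedial head surface and presses down-laterally,
roughly along the neck axis — the standard frontal-plane hip-loading
geometry. Each force is spread cosine-weighted over a 60° surface arc
centred on its entry point, every nodal force pointing toward the landmark
centre, then mapped by one rotation+scale so the resultant equals the
stated magnitude and angle exactly.

## Reconstruction formulation

Each low-resolution (LR) pixel of the region of interest is subdivided
into n×n sub-elements inheriting the parent density (n = 12 for
600 → 50 μm). The design problem over the ROI sub-element densities is

    minimize   f(ρ) = Σⱼ cⱼ ( ½ uⱼᵀ K uⱼ )          (weighted compliance)
    subject to g(ρ) = mean( [S(ρ − ρ⁰)]² ) ≤ ε = 0.01,
               mean(ρ) = mean(ρ⁰),
               0.01 ≤ ρᵢ ≤ 1,

with ρ⁰ the refined parent densities. Three choices here were genuinely
open and are the package's own:

* **Deviation measured at the continuum scale.** S is a Gaussian smoother
  with σ of a quarter LR pixel. Measured per sub-element instead, the
  bound would forbid any binarization (a strut layout deviates ~0.4 RMS
  from a smooth parent, far above √ε = 0.1), while a hard per-LR-pixel
  block average permits it but imprints the LR lattice on the
  microstructure. σ sets the mass-transport scale the bound tolerates:
  rearrangement within ~2σ of a pixel is nearly free (what binarization
  needs), while moving bone across parent pixels is charged (what keeps
  the reconstruction on the patient's pattern). A larger σ (half a pixel)
  was tried first and allowed the global-mode optimizer to consolidate
  mass into thick load corridors far from the parent pattern.
* **Bone-mass conservation.** Compliance is strictly decreasing in every
  density, so with the deviation bound alone the optimizer spends the
  whole budget on uniform densification (+√ε mean drift — measured, not
  hypothetical), yielding blobs rather than trabeculae. The mean-density
  equality is handled as a proper dual: a uniform shift μ added to the
  objective gradient is bisected so that the MMA update itself lands on
  the conserved physical mass. (Two simpler schemes were tried and
  rejected: post-step re-projection fights the MMA step and stalls it, and
  subtracting the gradient mean lets concentrated boundary sensitivities
  skew the interior competition.)
* **Density filtering + Heaviside projection** (three-field scheme): cone
  filter of radius 1.5 sub-element widths sets the minimum feature size
  and suppresses checkerboards; a smoothed Heaviside projection at
  threshold 0.5 with sharpness β doubled from 1 to 16 every 40 iterations
  drives the physical field near-binary, without which threshold-based
  morphometry on the half-gray filtered fields is noise. A classic
  sensitivity filter is available (`OptimizerParams.filter_type`) but
  measured worse on the phantom: coarser features, poorer
  conventional-vs-localized agreement.

The update is the method of moving asymptotes specialized to the single
deviation constraint: separable rational approximations between moving
asymptotes (initial offset 0.5× range, adaptation 1.2 / 0.7, move limit
0.2, feasibility margin 0.1), the subproblem solved exactly through its
1-D dual by bisection, nested inside the μ-bisection of the mass
constraint. The quadratic g may transiently exceed its rational
approximation mid-run (excursions up to ~2ε were observed); feasibility is
enforced at convergence (g ≤ ε + 10⁻³). Iterations stop when the largest
density change drops below 0.01 with β at its maximum, or at the
iteration cap (700 full-scale, 300 desk-scale). The objective gradient is
normalized by the design-region strain energy at the start, so the two
modes share one gradient scale.

## Conventional vs localized drivers

**Conventional (global) mode** refines the whole image, routes ROI
sub-elements to SIMP and everything else to the continuum law, and
re-analyzes the refined global model each iteration. Because the
non-design region never changes, its stiffness is reduced once onto the
ROI cut boundary by an exact Schur complement (with the load terms
`F̃_b = F_b − K_be K_ee⁻¹ F_e` and the constant energy
`½ F_eᵀ K_ee⁻¹ F_e` retained so the reported compliance is the full-model
value); per-iteration factorizations then involve only ROI DOFs plus the
condensed boundary block. Tests verify this equals the direct full-model
solve to 10⁻⁸ relative — an algebraic acceleration, not an approximation.

**Localized mode** first estimates the physiological local loads by static
condensation at LR: solve the LR global model per load case, prescribe the
cut-boundary displacements Dc on the extracted LR ROI model, and take the
perimeter reactions (operationally identical to
`K′cc Dc − K′cl K′ll⁻¹ K′lc Dc`, verified against the explicit matrix on a
small instance). Each estimated load set is self-equilibrated (zero
resultant force and moment), and re-applying it to the same localized
model reproduces the global interior field up to a rigid-body motion to
10⁻⁶ relative — the module's principal oracle. The loads are estimated
once and held fixed; the LR nodal reactions represent a piecewise-linear
traction along the cut boundary (the LR shape functions), so each LR ring
force is spread with hat weights over the HR nodes of its tributary
segment, total force preserved exactly (single-node injection is
available as ``spread="point"`` but adds artificial stress
singularities). The load resolution still stops at the LR element size;
this mismatch with the conventional method's HR-coupled boundary is
intentional — it is the mechanism that makes the localized reconstruction
differ near the cut boundary, and it is what the comparison quantifies. Rigid-body modes are
removed by pinning both DOFs of the lower-left corner and the vertical DOF
of the lower-right corner; with self-equilibrated loads the pin reactions
stay at round-off level.

## Synthetic phantom

No real input image ships with the package; a proximal-femur phantom
stands in. Geometry is a smooth union of signed-distance primitives (head
disc, neck capsule, greater-trochanter lobe, shaft box) on a
94.2 × 104.4 mm frontal-plane domain at 600 μm/pixel (157 × 174 px); the
interior density field is a base level plus Gaussian ridges along the
principal compressive (head–calcar) and tensile (trochanteric arch)
trajectories, a Ward's-triangle low, a metaphyseal bump, a medullary
canal, seeded smooth noise (amplitude 0.04), and a graded cortical shell
(≈4 mm diaphyseal thinning to ≈1.5 mm over the head). Site means were
chosen a priori to the ranges reported for those sites — head ≈ 0.55,
neck ≈ 0.2–0.3, intertrochanter ≈ 0.35–0.4 — and the same seed reproduces
the image bit-for-bit.

What the phantom does **not** emulate: real CT noise and partial-volume
blur, anisotropic continuum fabric, cortical porosity, any
non-mechanical (metabolic) contribution to architecture, and
out-of-plane (3D) load paths. Agreement between the two reconstruction
modes on this phantom therefore validates the *localization machinery* —
load estimation, boundary handling, shared optimization — not the
biological fidelity of either reconstruction.

## Study sizes

The default paired study (`desk_config`, also what
`scripts/acceptance.py` runs) uses a half-linear-scale phantom
(47.1 × 52.2 mm at 600 μm/pixel, 79 × 87 px) with n = 6, i.e. 100 μm
design elements: head and intertrochanter ROIs of 16 × 16 LR px (9216
design elements), neck 8 × 8 (2304), iteration cap 300. This keeps a full
paired study within minutes on one CPU while preserving every structural
feature of the full-scale problem. `full_config` ships the full-scale
setting (n = 12, 50 μm elements, ROI sizes 8/16/24 px, cap 700, global
refined models of ~2.1 M elements) and runs for hours; it is not exercised
by the test-suite.

## Morphometry

Reconstructed fields are binarized at 0.5 (near-binary fields make the
threshold uncritical; tested insensitive over [0.3, 0.7] on converged toy
runs). BV/TV is the bone area fraction. Tb.Th and Tb.Sp are 2D local
thickness — the diameter of the largest inscribed disc covering each
pixel, computed by painting distance-transform discs in decreasing radius
order with the 2D−1 pixel-centre correction so a w-pixel strut measures
w pixels; values carry ±1 px discretization error. Tb.N is the plate-model
(BV/TV)/Tb.Th; separation is measured directly, not derived. Trabecular
alignment is the minor-eigenvector orientation of the
derivative-of-Gaussian structure tensor (σ_d = 1 px, window σ = 2 px,
interior-averaged), reported in degrees from vertical in [−90, 90);
central-difference gradients were rejected for their degree-level bias
toward the grid axes. Fields whose tensor eigenvalue ratio is below 1.05
are flagged isotropic (angle undefined).

Method agreement is tabulated as: BV/TV deviation in percentage points,
Tb.Th/Tb.Sp/Tb.N relative errors in percent of the conventional value,
and the absolute alignment-angle difference (mod 180°).

## Known limitations

* 2D plane stress only; no 3D extension.
* The localized mode's cut-boundary loads stay at LR resolution by design;
  expect structural differences within ~1 LR pixel of the ROI perimeter,
  and degraded agreement for small, sparse ROIs where that band is a large
  area fraction.
* The connectivity check treats elements sharing only a corner node as
  connected; a corner-hinge mechanism would pass the check and fail in the
  solve.
* Local thickness is edge-biased for phases touching the image border
  (distances are measured to the phase boundary inside the window only).
* MMA iterates can transiently violate the deviation bound (≲2ε) before
  settling; per-iterate feasibility is not guaranteed.
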