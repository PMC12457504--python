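# Methods

`ringhomog` turns a gray-scale voxel image of ring-porous wood tissue into
effective macroscopic hygro-elastic properties and meso-scale strain/stress
fields. This note records the model, the numerical choices, and what the
synthetic test data do and do not establish.

## Model overview

The meso-structure is a periodic unit cell `Q` occupied by two phases:
cell-wall solid `Q+` and void (lumina and vessels) `Q-`. The cell wall is a
homogenized orthotropic hygro-elastic solid,

    sigma = C : (eps - beta dm),

with stiffness `C` and diagonal hygro-expansion `beta` defined in a local
frame whose 3-axis follows the cell axis (longitudinal `z` for axial cells,
radial `x` for rays). Asymptotic (two-scale) homogenization yields seven
periodic cell problems on `Q`: six mechanical influence functions (one per
unit macroscopic strain, Voigt order) and one hygric influence function.
Their solutions give the effective stiffness and expansion as unit-cell
averages, and reconstruct local fields under a uniform moisture step `dm`
in two loading modes: *constrained* expansion (zero average strain) and
*free* expansion (zero average stress).

Axes follow the wood convention: `x` = radial (R), `y` = tangential (T),
`z` = longitudinal (L). Internal units are mm and MPa, so stresses come out
in N/mm^2; lengths in the image layer are micrometres; moisture content and
hygro-expansion are in percent.

## Segmentation

The solid/void split is carried by a level set `phi` (positive = solid),
initialized as the *exact* signed Euclidean distance from each voxel center
to the inter-voxel interface. The interface is taken to lie on voxel faces,
so a voxel adjacent to a planar boundary carries `|phi| = h/2`; the exact
transform is computed with a KD-tree over boundary-face centers plus an
exact point-to-face minimization over a provably complete candidate set.

The evolution minimizes a hybrid intensity energy: a global two-region mean
term plus a local Gaussian-window mean term (window `sigma = 3` voxels by
default) that tolerates smooth multiplicative intensity inhomogeneity, with
a curvature (boundary-length) penalty `mu = 0.1`. One *sweep* performs ten
gradient-descent steps (step `dt = 2`, smoothed Heaviside width `eps = 1.5`
voxels, force normalized to unit amplitude) followed by a signed-distance
reinitialization; the iteration stops when the reinitialized field changes
by less than `1e-3` voxels anywhere, which makes a converged segmentation an
exact fixed point of the procedure. All of these constants are exposed in
`EnergyParams`; the defaults are package choices — the hybrid energy family
is standard, but no reference parameterization exists for this tissue type.

Cleanup flips 26-connected islands of either phase strictly smaller than 27
voxels (one 3x3x3 block — the smallest feature a two-voxel wall can
produce). Periodization mirrors the volume across the R-T plane (exact
mirror periodicity in z) and pads two-voxel solid layers on the x and y
faces so that opposite faces can be tied periodically; those artificial tie
layers are assigned axial material at orientation `alpha = 0`.

## Orientation and materials

The in-plane wall orientation is read from the level-set gradient by
central differences at each element center:
`alpha = arctan(-phi_,x / phi_,y)` in the x-y slice for axial cells, and the
same construction in the y-z slice for ray cells (whose 3-axis is radial).
The two-argument arctangent is reduced to the director range `(-pi/2,
pi/2]`. Where the in-plane gradient magnitude falls below `1e-6 h` (medial
axes, plateaus) the element takes the most common angle among its valid
26-neighbors, falling back to `alpha = 0` with a warning. The y-z slice
choice for rays follows from the ray 3-axis being radial; no other
orientation is consistent with a prismatic radial cell.

Reference cell-wall constants at 12% moisture content (axial and ray
parameter sets: moduli 3.5–18.3 GPa, expansion 0.00–0.43 %/%) are built
into the package; arbitrary moisture contents are handled by per-parameter
tabulated multipliers normalized to 1 at the reference moisture (identity
by default — the package ships no moisture curve of its own and expects a
user table). The orthotropic compliance is assembled in engineering-shear
Voigt order (11, 22, 33, 23, 13, 12) and inverted to stiffness; rotations
to the global frame use 6x6 Bond matrices (verified in the tests against
full fourth-order tensor rotation). Rotated expansion vectors keep the
engineering factor 2 on shear entries so that `C : beta` load terms are
consistent.

## Discretization and quadrature

Each voxel maps to one eight-node hexahedral element. Voxel-center `phi` is
averaged to the nodes (periodic wrap); elements with all nodal `phi >= 0`
are solid, all negative void, mixed cut. The zero level belongs to the
solid phase (`H(0) = 1`). The displacement interpolation is multiplied by
the Heaviside of `phi`, so void regions carry no stiffness without any
extra enrichment DOFs; nodes surrounded exclusively by void elements are
removed from the system.

Solid elements use the standard 2x2x2 Gauss rule. Cut elements keep the
27 Gauss-Legendre points of order `p_q = 2` and receive *moment-fitted*
weights: the element is split into `n_c = 10^3` equal sub-cells, each
sub-cell's Heaviside value is taken from trilinear `phi` at its center, and

    w_i = sum_c H^c int_{Q_c} l_i dQ,

where the per-sub-cell integrals of the Lagrange basis `l_i` (nodes at the
Gauss points, so the moment system is explicit) are precomputed once — the
factored and the naive per-sub-cell evaluation agree to 1e-12 in the tests.
The weight sum equals 8x the sub-cell solid volume fraction exactly, and
the rule integrates `H x (any polynomial of per-axis degree <= 2)` exactly
up to the sub-cell quantization of `H`. Weights can be slightly negative;
cut elements whose sub-cell Heaviside field is identically zero are demoted
to void. Both `p_q` and `n_c` are configurable.

## Periodic cell problems and the solver

Opposite-face nodes share reduced DOFs (index wrap), which resolves edges
and corners automatically. The six mechanical load columns are the
unit-strain loads `int B^T C e_j`; the hygric load is `int B^T C beta`.
Rigid translations are the only nullspace and are projected out of the
residual and iterates inside the conjugate-gradient loop; solved fields are
post-shifted to a zero tributary-volume-weighted mean. Default relative
residual tolerance is 1e-8.

The preconditioner starts from the element-sum of spectral pseudo-inverses:
each `K^e` is eigendecomposed and eigenvalues at or below
`lambda_th = eps max_i lambda_i` (default `eps = 1e-13`) are dropped before
inversion, which stabilizes cut elements whose small solid slivers produce
round-off-negative eigenvalues. Two augmentations proved necessary and are
on by default in the pipeline:

1. **Stiffness-share weighting.** A plain sum of element inverses is
   dominated at shared nodes by the softest adjacent element; under strong
   stiffness contrast this makes the preconditioned spectrum *worse* than
   the unpreconditioned one (measured on a 288-DOF contrast fixture:
   condition 1.9e6 versus 4.3e4 raw). Each element inverse is therefore
   weighted by the element's share of the assembled diagonal stiffness at
   every DOF (a partition of unity over elements), a standard
   element-by-element stabilization.
2. **Coarse-grid correction.** Element pseudo-inverses annihilate each
   element's rigid modes, so the assembled sum transfers nothing along
   smooth, nearly rigid deformation patterns and PCG stagnates on meshes
   beyond a few thousand elements. An additive coarse correction over 4^3
   node aggregates (per-aggregate translations, direct factorization of
   the Galerkin coarse operator) restores them.

With both, the seven cell problems on the 64x32x16 reference mesh converge
in ~470 iterations each (~75 s total on one CPU); the bare element-sum
operator remains available for small, strongly cut fixtures where it is
demonstrably the cure (the test suite includes a thin-cut, 10-decade
contrast fixture on which unpreconditioned CG stalls).

## Homogenization and fields

Effective tensors are the quadrature-consistent unit-cell averages, with
`|Q|` the *total* cell volume including voids (consistent with the
porosity-density arithmetic `rho = (1 - phi) rho_cw`). Engineering
constants are read from the inverse of the effective stiffness under the
orthotropic parameterization; the norm of the compliance entries that exact
orthotropy would set to zero is reported as a residual rather than forced
away. Local strain/stress fields are evaluated at element centers (one
material orientation per element); volume averages use the element
quadrature, so `<sigma> = 0` under free expansion holds to solver tolerance
by construction.

## Synthetic data

No public micro-CT volume of this kind exists, so the test bed is a
geometric phantom of a single growth ring: square-prism axial cells on a
jittered lattice (pitch 340 um, walls 85 um, thickened 1.5x in latewood),
large earlywood and small latewood vessel cylinders along z placed by dart
throwing to target area fractions, and a bottom band of ray prisms along x.
The default 60x28x8-voxel spec at 40 um spacing was calibrated once so the
rendered morphometrics match a reference oak growth-ring unit cell
(porosity 0.454, ray
solid fraction ~0.21, earlywood vessel fraction ~0.14); periodization then
yields exactly 64x32x16 elements. Intensities are two modes (0.3 void, 0.7
solid) plus Gaussian noise (default study condition sd 0.05) and a smooth
low-order polynomial multiplicative inhomogeneity (amplitude 0.6, chosen
above the 0.5 threshold at which dark-region solid overlaps bright-region
void, so that a global threshold genuinely fails and the local energy term
is exercised).

The phantom gives exact ground truth (phase, orientation, labels,
porosity), which is what the accuracy tests quantify. It does *not* emulate
scanner physics (beam hardening, rings, partial-volume blur), real cell
lumen shape variability, pits, or cell-wall layering — passing tests
establish correctness of the numerics and qualitative anatomy-driven
anisotropy (E_L > E_R > E_T, beta_T > beta_R > beta_L, with E_R/E_T ~ 1.9
and beta_T/beta_R ~ 2.3 on the reference phantom), not quantitative
agreement with any particular oak sample.

## Known limitations

- The segmentation energy is gradient descent with reinitialization, not a
  globally convergent scheme; heavily textured images may need parameter
  changes.
- Ray/axial labelling is taken as an input annotation (a y-band by
  default); no automatic ray classifier is provided.
- Moment fitting quantizes the interface to `n_c` sub-cells; solid slivers
  thinner than one sub-cell are dropped (which also self-regularizes the
  worst XFEM conditioning).
- One material orientation per element; sub-element orientation gradients
  are not resolved.
- Moisture content is uniform across the cell; moisture transport and
  mechano-sorptive effects are out of scope.
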