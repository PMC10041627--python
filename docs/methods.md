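# Methods

## Scope and model

`elastimap` analyses the linear-elastic response of crystals described by a
symmetric 6×6 Voigt stiffness matrix **C** (GPa). The crystal is treated as
a homogeneous anisotropic elastic continuum; all directional properties
derive from the compliance **S** = **C**⁻¹ expanded to the rank-4 tensor
S_ijkl. Voigt index pairs are (11, 22, 33, 23, 13, 12) → (1…6). The
stiffness matrix maps to the full tensor with unit factors; compliance
entries are divided by 2 for each shear row/column index (the 1/2/4
convention), which is the unique choice under which σ = C : ε, the
contracted Hooke's law, and the contraction formulas for E(u) and G(u, v)
are mutually consistent. The round trip matrix → tensor → matrix is exact.

Directional moduli:

* `1/E(u) = u_i u_j u_k u_l S_ijkl` (uniaxial stiffness along **u**),
* `1/G(u, v) = 4 u_i v_j u_k v_l S_ijkl` with **v** ⊥ **u** (shear along
  **u** in the plane normal to **v**); symmetric under u ↔ v.

Both are validated in the tests against an independent brute-force route:
rotate the full compliance tensor into a frame aligned with (u, v) and read
the 1111 / 1212 component.

Stability is the Born criterion for unstressed crystals: positive
definiteness of the 6×6 Voigt matrix, evaluated by its eigenvalue spectrum.
This form is necessary and sufficient and uniform across crystal systems,
so no per-class closed-form inequalities are used. Inversion rejects
matrices with condition number above 1e12; such tensors are numerically
indistinguishable from unstable ones and their directional moduli would be
dominated by rounding error.

Voigt (uniform-strain) orientation averages K_V, G_V, E_V use the standard
contractions of **C**; for an isotropic tensor they reproduce the
generating (E, ν) exactly, which the tests assert. Reuss and Hill averages
are out of scope.

## Extrema, anisotropy and surfaces

For fixed **u**, 1/G(χ) along v(χ) = cos χ w₁ + sin χ w₂ is the quadratic
form of a 2×2 restriction of the shear tensor, hence exactly
α + β cos 2χ + γ sin 2χ. The implementation scans χ ∈ [0, π) on a 72-point
grid and refines the best bracket by golden section to 1e-6 rad; where the
form is degenerate (flat in χ, e.g. **u** along a cube axis) the grid value
is already exact and refinement is skipped. The closed-form eigenvalues of
the 2×2 restriction serve as an independent oracle in the tests, and the
trapezoid mean over a closed [0, π] grid gives G_avg.

Global extrema over the sphere seed a deterministic icosphere grid
(default 2562 vertices, the smallest subdivision with at least the
requested count) and refine the best few seeds — deduplicated by 10°
angular separation after antipodal folding — with Nelder–Mead over
(θ, φ) to 1e-8 rad. Icosphere seeding was chosen over random sampling so
results carry no seed dependence. The shear anisotropy index is computed
over all admissible (u, v) pairs: A_G = max_{u,χ} G / min_{u,χ} G, and
A_E = E_max / E_min over the full sphere; both are ≥ 1 by construction and
equal 1 for isotropic tensors to 1e-9. Modulus surfaces are sampled on a
regular (θ, φ) grid (`resolution` azimuths per ring, `resolution/2 + 1`
polar rings) and respect antipodal symmetry exactly.

## Stress–strain fitting

`StressStrainModel` estimates **C** from deformation series. Each strain
pattern excites one Voigt component (engineering-shear convention:
amplitude a on component 4 means γ₂₃ = a); amplitudes are 12 evenly spaced
points spanning ±max_amplitude, which for an even count excludes zero —
the zero-strain stress carries no slope information, and the symmetric
grid cancels even-order contributions to the slope. The default
max_amplitude is 0.003: small enough that the quadratic anharmonicity of
the synthetic engine biases slopes negligibly, large enough that realistic
stress noise (1e-3 GPa, the convergence level of a well-converged
plane-wave calculation) does not drown the signal. Note the model's
anharmonic term γ‖ε‖ε is odd in the amplitude, so it biases the fitted
slope by γ Σ|a|³/Σa² (the tests assert this closed form) and the bias
vanishes linearly as max_amplitude → 0.

For each series and stress component, an ordinary least-squares slope
(no intercept by default, since the engine contract fixes σ(0) = 0; an
intercept can be fitted to detect residual stress) gives one column entry
C[i, k] with its regression standard error. Pattern sets are minimal per
Laue class: all six single-component patterns for triclinic, monoclinic
and orthorhombic; components {1, 3, 4, 6} for tetragonal; {1, 3, 4} for
hexagonal (C66 is derived as (C11 − C12)/2); {1, 4} for cubic; {1} for
isotropic. With a Laue class, every independent coefficient is the mean of
all measured positions tied to it by symmetry (its standard error combined
accordingly), and the class pattern rebuilds the full matrix; without one,
the six measured columns are symmetrized by (C + Cᵀ)/2. The
pre-symmetrization spread is reported as a diagnostic, and underdetermined
coverage is rejected naming the missing components. Noise-free fits are
exact to rounding (OLS on linear data), which the tests require at 1e-8
GPa for every class.

Internal (atomic) relaxation under strain is deliberately absorbed into
the stress-engine contract: a real engine relaxes ions at fixed cell and
returns the relaxed stress; the synthetic engine simply has no internal
degrees of freedom.

## Synthetic data

The generators define the test conditions:

* `isotropic_stiffness(E, ν)` — exact Lamé closed form.
* `random_stable_stiffness(class, scale=20 GPa, seed)` — independent
  coefficients drawn uniformly (diagonal entries on [scale, 2·scale]; the
  diagonal bias makes Born rejection rare but shapes the sampled
  distribution toward diagonally dominant, moderately anisotropic
  tensors), rejected until positive definite; exactly in-class, bit-identical
  per seed. The 20 GPa scale puts the moduli in the range typical of
  molecular crystals.
* `SyntheticStressCalculator` — Hooke's law plus optional γ‖ε‖ε
  anharmonicity and seeded Gaussian noise applied to the six independent
  components of the symmetric stress (so each Voigt component carries
  exactly the declared sd).
* `urea_like_structure()` — a tetragonal toy cell (a = 5.6 Å, c = 4.7 Å)
  with two planar 4-atom molecules, each donating one N–H···O bond to its
  own +c translational image (d_HA = 1.9 Å, angle 165°, direction within
  10° of c); the two tapes are rotated 90° about c. The ground-truth
  contact list is constructed analytically from the placement geometry,
  independent of the detector. It is a geometric fixture, not real urea.
* `fibrous_stiffness()` — a tetragonal tensor with C33 ≫ C11, the
  mechanical caricature of a tape/chain motif along c.

What passing tests on these fixtures do **not** show: real molecular
crystals have soft librational degrees of freedom, temperature-dependent
elastic constants, and contact networks far denser and messier than two
tapes. The synthetic suite validates the *analysis machinery* — tensor
algebra, optimization, detection, alignment — not any claim about a
particular compound.

## Crystallographic frames and contacts

The Cartesian convention is **a** ∥ x, **b** in the xy-plane with positive
y, **c** completing a right-handed set; right angles produce exact zeros so
orthorhombic frames equal the normalized lattice vectors exactly. Plane
slices use e₁ = first named axis normalized and e₂ = second axis
Gram–Schmidt-orthogonalized against e₁, with θ measured from e₁ — the
angle origin is a convention, so only slice shapes and extremum positions
are meaningful for comparison across programs.

Contact detection assigns each hydrogen to its nearest donor-element atom
within 1.25 Å (over periodic images), then tests acceptor atoms in all
lattice images that can fall within the cutoff (image range computed from
the cell's perpendicular widths). Default criteria follow common
crystallographic practice: donors {N, O, C}, acceptors {N, O},
d(H···A) ≤ 2.7 Å, ∠(D–H···A) ≥ 120°; all are configurable and echoed into
every report. Contacts are reported once per (donor, acceptor, image)
triple. The criteria are geometric heuristics — they carry no energetic
information.

π-stacking is detected separately and heuristically: six-membered carbon
rings are found as minimal cycles of the minimum-image C–C bond graph
(bond cutoff 1.8 Å), and ring pairs whose centroids lie within 4.5 Å
(periodic images included) are reported with the centroid–centroid
direction, labelled parallel-displaced or T-shaped by the ring-plane
dihedral at a 30° threshold. The labels are geometric conventions, not
energetic classifications.

The alignment report folds all directions into a hemisphere (angles in
[0°, 90°]) and gives, per contact class, the mean and minimum angle to the
E_max direction plus the angle of the class's principal direction (leading
eigenvector of the second-moment matrix of folded directions); per plane
slice, the angle between the slice maximum and the in-plane projection of
the nearest contact. Large angles are a legitimate outcome — stiffness in
some crystals cannot be traced to any single contact class — so nothing in
the report is an error condition.

## Numerical choices and degenerate inputs

* Matrix validation symmetrizes (M + Mᵀ)/2 with a default asymmetry
  tolerance of 1e-3 GPa (file round-tripping can break exact symmetry);
  larger asymmetry is rejected naming the worst entry.
* Rotations must be proper orthogonal to 1e-10; improper rotations are
  rejected rather than silently absorbed (elastic tensors are inversion-
  even, but a failed orthogonality check usually signals a bug upstream).
* Golden-section refinement tolerance 1e-6 rad in χ; Nelder–Mead
  tolerance 1e-8 rad on the sphere; icosphere default 2562 seeds. These
  resolve the narrow minima of strongly anisotropic tensors (anisotropy
  indices of order 50 and beyond) while keeping a full single-tensor
  analysis under a second.
* Reports round moduli and indices to 1 decimal in their `table` section
  (alongside full-precision fields), matching how such quantities are
  conventionally tabulated.

## Problem sizes

Defaults used throughout the test suite and the acceptance script: 2562
sphere seeds, 72-point χ scans, 360-point plane slices, 12-point
deformation series, 100 tensors × 20 directions for the dual-route modulus
check, and 500 replicates for the noisy-recovery coverage measurement.
These sizes make every quantity reproducible on a single CPU in seconds
while leaving the measured tolerances far from their asserted bounds.

## Known limitations

* Only Voigt averages are implemented (no Reuss/Hill, no linear
  compressibility or Poisson-ratio surfaces).
* Second-order (linear) elasticity only; no third-order constants, no
  stress-dependent stability criteria.
* The fit assumes single-component strain patterns; arbitrary mixed
  patterns are represented in the data model but not in the estimator.
* CIF reading targets ordered small-molecule structures; disorder is not
  handled (duplicate generated positions are merged).
* The π-stack detector only recognizes six-membered all-carbon rings;
  heteroaromatic rings and C–H···π contacts (hydrogen-to-ring-centroid)
  are not classified.
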