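# Methods

## Model and procedure

`hessbond` derives harmonic bonded parameters from the mass-unweighted
Cartesian Hessian **H** = ∂²E/∂**x**∂**x** of a molecule at an optimised
geometry.  For an atom pair (A, B) the interatomic force-constant matrix is
taken as the negated off-diagonal subblock

    K_AB = −H[3A:3A+3, 3B:3B+3],

following the force–displacement relation δ**F** = −**H** δ**x**: the
negation makes the eigenvalues of a bonded pair's coupling block positive
along the bond. The subblock of a symmetric Hessian is itself not symmetric
in general, so K_AB is symmetrised as (K + Kᵀ)/2 before diagonalisation —
this preserves its quadratic form and guarantees real eigenvalues with
orthonormal eigenvectors.  Bond constants are the projection-weighted
eigenvalue sum along the unit bond vector; angle constants combine two
arm stiffnesses harmonically, each arm projected on the in-plane unit
vector perpendicular to it (û_PA = û_N × û_AB, û_PC = û_CB × û_N, with
û_N the unit normal of the A–B–C plane).  The printed products in the
angle formula are read as cross products: only those yield the unit
perpendiculars the projections require.  Equilibrium values are Euclidean
distances and arccos angles of the input geometry.

Assumptions: the structure is at a true minimum of the QM energy (the
upstream frequency job should confirm no imaginary modes); bonded terms
are harmonic near that minimum; non-bonded contributions to the Hessian
are *not* decoupled, so derived constants inherit whatever non-bonded
curvature the QM model places on an atom pair.

## Parameters

| parameter | unit | default | notes |
|---|---|---|---|
| frequency scale factor *s* | — | 1.0 | applied as *s²* to every force constant (ω ∝ √k); accepted range (0, 1.5] |
| coincidence threshold | Bohr | 1e-6 | pairs closer than this are geometry errors |
| collinearity threshold | — | 1e-6 | minimum \|û_CB × û_AB\| for a valid angle frame |
| finite-difference step | Bohr | 1e-3 | oracle Hessians; valid range [1e-6, 1e-2] |

Unit constants: 1 Hartree = 2625.4996 kJ/mol, 1 Bohr = 0.052917721 nm;
hence 1 Hartree/Bohr² = 937 582.93 kJ mol⁻¹ nm⁻².  Emitted constants match
GROMACS's V = ½k(b−b₀)² and V = ½k_θ(θ−θ₀)² conventions with no extra
factor of two; function type 1 is written for both bondtypes and
angletypes.

## What the synthetic oracle emulates — and what it does not

The oracle builds molecules whose energy is an explicit sum of independent
harmonic bond and angle terms, anchored exactly at their minimum, and
produces Hessians by central differences of the analytic gradient
(O(step²); at step 1e-3 Bohr the discretisation error is ~1e-7 relative).
These Hessians travel through the same fchk writer/parser as real
Gaussian output, so parsing, expansion, eigen-analysis, unit conversion
and output formatting are all exercised against exact ground truth.

What the toys do not emulate: non-bonded (electrostatic/van der Waals)
curvature, anharmonicity, cross-terms between internal coordinates, and
the dense inter-term coupling of real electronic structure.  Passing the
recovery tests therefore demonstrates that the implementation computes the
method's defined quantities correctly — not that the method reproduces QM
vibrational spectra, which it is known not to do in general.

Measured recovery on the standard toys (also recomputed by
`scripts/acceptance.py`):

* isolated bonds (diatomic, linear triatomic, 6-ring): exact to within
  finite-difference noise (≪0.1%);
* bonds whose coupling block also carries angle curvature (water-like
  bent triatomic): ~0.95% high;
* the bent triatomic's angle constant: **~11% low** (355.6 recovered vs
  400 true).  This underestimate is intrinsic to the series-combination
  formula, not a numerical artefact: for a pure harmonic bend the negated
  A–B block equals k_θ·g_A(g_A+g_C)ᵀ (g's being the angle gradients), and
  its projected eigenvalue sum falls short of the 2k_θ/d² each arm would
  need for exact recovery.  The bias shrinks as the bend opens toward
  180° and varies only weakly with bond stiffness (−13% in the rigid-bond
  limit, −5% with soft bonds).  Later "modified Seminario" schemes exist
  precisely to correct this; this package implements the original
  formula and documents the bias instead of silently compensating for it.

## Numerical choices

* Eigen-decomposition: `numpy.linalg.eigh` on the symmetrised block;
  ascending eigenvalue order (the projection sum is order-independent).
* Degenerate inputs are errors, not NaNs: coincident atoms, zero-length
  arms and collinear angle triplets raise geometry errors; an angle arm
  with non-positive projected stiffness raises a dedicated error naming
  the arm.
* Non-positive *bond* sums are returned as-is with a warning (and refused
  only at topology-writing time) so that unrealistic atom pairs remain
  visible rather than masked — a pair with an exactly zero coupling block
  returns k = 0 with a "no interaction" warning.
* Exchange symmetry (A,B)↔(B,A) and (A,B,C)↔(C,B,A) holds to the last
  bit by construction: swapped blocks symmetrise to the identical matrix
  and the frame vectors flip sign exactly, which the absolute-value
  projections ignore.
* The fchk writer emits reals as `%24.15E` (5 per line) rather than
  Gaussian's 8-digit fields so write→parse round trips are lossless to
  <1e-15 relative; the whitespace-tolerant parser reads either width.
* Hypothesis-based and rotation-based property tests run derandomised /
  with fixed seeds; problem sizes (2–6 atoms) keep the whole suite and the
  acceptance script in the seconds range.

## Known limitations

* Dihedral terms are not derived (poor harmonic approximation; fit them
  from potential-energy scans instead).
* Bonded and non-bonded Hessian contributions are not decoupled, so
  normal-mode frequencies of the resulting MM model will not match the QM
  spectrum in general.
* The systematic angle-constant underestimate described above.
* Only the three fchk sections needed here are read; binary `.chk` files
  must be converted with `formchk` first, and Gaussian `.log` files are
  not required.
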