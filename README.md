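# hessbond

Harmonic bond-stretch and angle-bend parameters for GROMACS force fields,
derived from the Cartesian Hessian of a quantum-chemistry frequency
calculation.

## The problem

Standard biomolecular force fields cover the common amino acids, a few
solvents and little else.  Small organic molecules, post-translationally
modified residues and metal binding centres routinely lack bonded
parameters, and fitting them by trial-and-error optimisation is slow.  If a
QM geometry optimisation and frequency analysis of the molecule is
available, however, the curvature information needed for harmonic bonded
terms is already sitting in its Hessian.

`hessbond` reads a Gaussian *formatted checkpoint* (fchk) file — geometry
in Bohr plus the lower-triangular Cartesian force-constant matrix in
Hartree/Bohr² — and turns selected atom pairs and triplets into ready-made
`[ bondtypes ]` / `[ angletypes ]` entries for `ffbonded.itp`.

## The method

For atoms A and B, the negated 3×3 off-diagonal subblock of the Hessian,
−∂²E/∂**x**_A∂**x**_B, is symmetrised and diagonalised into eigenvalues
λᵢ^AB and eigenvectors vᵢ^AB.  The bond-stretch constant is the
projection-weighted eigenvalue sum (Seminario's method)

```
k_AB = Σᵢ λᵢ^AB |û_AB · vᵢ^AB|
```

and an angle A–B–C combines the two arms like springs in series, each arm
projected on the in-plane unit vector perpendicular to it:

```
1/k_θ = 1/(d²_AB Σᵢ λᵢ^AB |û_PA·vᵢ^AB|) + 1/(d²_CB Σᵢ λᵢ^CB |û_PC·vᵢ^CB|)
```

Equilibrium values b₀ and θ₀ are plain 3-D geometry from the optimised
structure.  Results are converted to GROMACS units (kJ mol⁻¹ nm⁻²,
kJ mol⁻¹ rad⁻², nm, degrees) for the harmonic forms V = ½k(b−b₀)² and
V = ½k_θ(θ−θ₀)², and an optional vibrational frequency scale factor *s*
is applied as *s²* to every force constant.

No internal coordinates are ever defined, which makes the approach robust
for awkward connectivity (rings, crosslinks, metal centres).  Dihedrals are
out of scope: their harmonic approximation from a Hessian is poor and they
are better fit by scanning the potential-energy surface.

Because QM Hessians are expensive, the package ships a synthetic oracle
(`hessbond.oracle`): toy molecules with *analytically known* harmonic force
fields whose finite-difference Hessians are written through the same fchk
writer, so every stage of the pipeline is testable against exact ground
truth.  See `docs/methods.md` for accuracy characteristics — in particular
the known systematic underestimate of angle constants on clean harmonic
test systems.

## Worked example

Generate a synthetic water-like checkpoint (two O–H bonds with
k = 4.0×10⁵ kJ mol⁻¹ nm⁻² at b₀ = 0.0957 nm, one H–O–H angle with
k_θ = 400 kJ mol⁻¹ rad⁻² at θ₀ = 104.5°) and a term list:

```python
from hessbond.oracle import standard_fixtures
fx = standard_fixtures()["bent_triatomic"]
open("water.fchk", "w").write(fx.fchk_text)
open("water.terms", "w").write(fx.terms_text)
```

The term list names 1-based atom IDs and force-field atom types:

```
1 2 HW OW
3 2 HW OW
1 2 3 HW OW HW
```

Run the derivation:

```
$ hessbond --fchk water.fchk --terms water.terms --out bonded.itp
INFO loaded water.fchk: 3 atoms, 9x9 Hessian
INFO term list: 2 bond(s), 1 angle(s); frequency scale factor 1
INFO bond 1-2 (HW-OW): b0 = 0.095700 nm, kb = 403790.917 kJ/mol/nm^2
INFO bond 3-2 (HW-OW): b0 = 0.095700 nm, kb = 403790.917 kJ/mol/nm^2
INFO angle 1-2-3 (HW-OW-HW): theta0 = 104.500 deg, ktheta = 355.577 kJ/mol/rad^2
INFO wrote 2 bondtypes and 1 angletypes to bonded.itp
```

`bonded.itp` now holds blocks ready to paste into `ffbonded.itp`:

```
[ bondtypes ]
; i    j  func        b0            kb
  HW   OW      1    0.095700      403790.917
  HW   OW      1    0.095700      403790.917

[ angletypes ]
; i    j    k  func      theta0        ktheta
  HW   OW   HW      1     104.500       355.577
```

Reading the numbers: both equilibrium values are recovered exactly
(0.0957 nm, 104.5°), the bond constants land within 1% of the true
4.0×10⁵ (the small excess comes from angle curvature leaking into the
O–H coupling blocks), and the angle constant shows the method's
characteristic ~11% underestimate of a pure harmonic bend (355.6 vs 400).
On real QM Hessians the same projections are applied to the full coupled
curvature, and unrealistic atom pairs make themselves obvious: a pair with
no Hessian coupling yields k ≈ 0 and a "no interaction" warning
(`--strict` turns any warning into a non-zero exit).

Useful flags: `--scale 0.9` applies a frequency scale factor (force
constants ×0.81), `--log-level debug|info|warning|error` controls the
stderr log.  Exit codes: 0 success, 1 usage, 2 input parse error,
3 derivation/output error.

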