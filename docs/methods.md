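# Methods

## Scope and models

`xccprop` computes one-electron properties (dipole, traceless quadrupole)
of closed-shell molecules from pair-coupled-cluster-doubles (pCCD) based
wave functions, using the *expectation-value* route to the one-particle
reduced density matrix (1-RDM) instead of the Lambda/response route.

The wave-function models are

| model    | cluster operator        | reference              |
|----------|-------------------------|------------------------|
| pCCD     | T2(pair)                | RHF / optimized-orbital determinant |
| CCD/CCSD | T2 / T1+T2              | RHF determinant        |
| fpCCD    | T2' (nonpair)           | pCCD state, pairs frozen |
| fpCCSD   | T1 + T2'                | pCCD state, pairs frozen |
| fpLCCD/fpLCCSD | linearized T2' (+T1) | pCCD state, single-commutator BCH |

All amplitude equations are *projective*: `<mu| e^-T H e^T |0> = 0` over
the model's manifold.  The spin-orbital residual routine keeps the full
(non-canonical) Fock matrix, so the same code serves canonical-RHF and
pCCD-optimized orbital references.  The frozen-pair channel is exactly the
spin-orbital image of the pair amplitudes `t2[i,i,a,a] = t_i^a`; residual
components on that channel are projected out, never solved.

The linearized (fpLCC) equations are the part of the fpCC residual linear
in the external amplitudes around T'=0.  They are evaluated *exactly* by
complex-step linearization of the full residual (the residual is a real
polynomial in the amplitudes, so `Im R(Tp + ih T')/h` is its directional
derivative to machine precision).  A non-convergent linear iteration is
reported as a (near-)singular fpLCC system — a known failure mode of the
model at some geometries — and never masked.

## pCCD equations

Only seniority-zero integral slices enter: `J_pq=(pp|qq)`, `K_pq=(pq|qp)`
and the Fock diagonal.  The residual (quadratic in t) and the analytic
Jacobian were derived in the hard-core-boson representation of the
seniority-zero sector; the derivation is *verified*, not assumed, by the
brute-force determinant oracle (`oracle.DetSpace`), which evaluates
`<pair_ia| e^-T H e^T |0>` by explicit sparse operator algebra.  The
Lambda multipliers solve the exact linear system `J^T lam = -dE/dt`, and
the response 1-/2-RDM pieces (diagonal occupations, pair-transfer and
pair-number correlators) have closed forms that the test suite checks to
machine precision against oracle transition expectations.

## Orbital optimization

The pCCD Lagrangian is stationary in t and lambda, so its orbital gradient
is the contraction of the response densities with derivative integrals,
`g = 2(F^T - F)` with a generalized Fock `F` assembled from the
seniority-zero density pieces (finite-difference validated to 1e-5).  The
energy is minimized over `U = U0 exp(kappa)` with L-BFGS in preconditioned
exponential coordinates; the `dexp` chain-rule factor is applied exactly so
the optimizer sees consistent gradients everywhere, and convergence is
declared at `|g|_inf < 1e-6` with double-precision orthogonality of U.

Two practical points a user should know:

* The canonical-orbital point is typically a *symmetric saddle* of the
  pCCD energy: the variational optimum breaks spatial symmetry toward
  localized orbitals (for HF/cc-pVDZ by ~5 mHa, for H2O/STO-3G by ~14
  mHa).  Cold starts therefore apply small seeded random rotations and
  keep the best of a few restarts; with an exactly symmetric start the
  optimizer would never leave the saddle.  Reference implementations reach
  the same branch by seeding with Pipek-Mezey localization, which this
  package deliberately omits (it accelerates convergence but does not move
  the optimum).
* Geometry scans warm-start each point from the previous rotation, which
  both cuts iterations and keeps the scan on one solution branch — the
  protocol used for every "(OO)" curve here.

## Expectation-value (XCC) densities

The S-operator expansion of `<e^T 0|E_pq e^T 0>/<e^T 0|e^T 0>` truncated
at the terms complete through third order ("XCCSD(3)" level) gives, in
spin-free amplitudes with `tbar_ij^ab = 2 t_ij^ab - t_ij^ba`:

```
gamma_ia = 2 (t_i^a + sum_jb t_j^b tbar_ij^ab)          (occ-virt)
gamma_ik = 2 delta_ik - 2 sum_jab t_ij^ab tbar_kj^ab    (occ-occ)
gamma_ca = + 2 sum_ijb t_ij^ab tbar_ij^cb               (virt-virt)
```

Three conventions here are *pinned by the determinant oracle* rather than
taken on faith: (i) the index pattern of the `S1^[2] = P1([T1+,T2])`
contraction in the occ-virt block, (ii) the overall factor 2 (fixed by the
single-pair model, whose occupations must be `2-2t^2 / +2t^2`, the exact
`2/(1+t^2)` through third order), and (iii) the *sign* of the virt-virt
block, which must be opposite to the occ-occ depletion so that the trace
is conserved identically.  The central property test scales the
two-electron fluctuation by lambda (holding the mean field fixed) and
verifies that `||gamma_XCC - gamma_exact||/||gamma_exact - gamma_HF||`
decays at least one power of lambda faster — third-order completeness.
The quadratic-singles term `<[S1[1]+,[X,T1]]>` is excluded from this
truncation by construction; reintroducing it would change the occ-occ and
virt-virt blocks at order t1^2.

Doubles-only models (XpCCD, XCCD, XfpCCD, XfpLCCD) have an identically
zero occ-virt block.  Approximate densities need not be N-representable;
natural occupations are only soft-checked to [-0.05, 2.05].

## Properties

`mu = sum Z_i R_i - Tr[gamma d]` and the traceless quadrupole
`Theta_ab = Theta_ab(nuc) - Tr[gamma q_ab]`, `q_ab = (3 r_a r_b -
delta_ab r^2)/2`, about the Cartesian origin of the supplied geometry
(ions are therefore origin-dependent).  The debye conversion constant is
2.5417464519 D per a.u.  `orient_qzz` relabels axes so the largest
|diagonal| quadrupole component sits on z.

## Dipole-moment surfaces

Diatomic scans place the molecule on z (H at the origin, F on +z for HF).
In this frame mu_z is negative near equilibrium; stretching first lowers
mu_z to a minimum — the *turning point*, near 1.27 A for FCI/cc-pVDZ —
after which it rises toward 0 D at dissociation.  Scans chain three warm
starts point-to-point: canonical MOs aligned by the cross-geometry AO
overlap (order and sign), the Davidson FCI from the previous CI vector and
subspace, and the orbital optimization from the previous rotation.  An
energy-continuity guard compares each point's pCCD energy with its
predecessor (threshold scaled with the stride) and retries from a cold
start when a hop between orbital-optimization branches is detected --
without it a warm chain can silently follow a spurious high-energy branch
near dissociation.  Failed points are recorded, never interpolated.  Curves are interpolated with
cubic splines; the turning point is the interior minimum of the spline,
and the nonparallelity error (NPE) versus a reference curve is
`max_R d(R) - min_R d(R)` of the pointwise deviation on the overlap
window.

Default desk-scale grids: the Table-style NPE window 0.75-3.5 A is
sampled at 0.25 A (with extra FCI points in the turning region), and the XpCCD turning-point scan runs at
0.0125 A.  Cubic-spline interpolation error on these smooth curves is
well below 0.01 D / 0.005 A, so finer strides change the headline numbers
negligibly; all strides are configuration knobs.

## Inputs: integrals, SCF, FCI references

No external quantum-chemistry engine is used anywhere.

* **AO integrals**: McMurchie-Davidson Hermite expansions up to d
  functions, with a series/asymptotic Boys function.  Validated against
  textbook H2/STO-3G tables and by exact derivative identities (a raw p
  Gaussian is the center-derivative of s over 2a, etc.) and quadrature.
* **Basis sets**: STO-3G (H, He, O) from the standard published tables;
  cc-pVDZ (H, F) with published primitive exponents and contraction
  vectors *generated at run time* from atomic mean-field calculations in
  the primitive space — the construction correlation-consistent sets use,
  which avoids transcribing long coefficient tables.  The molecular SCF is
  variational in the contracted space, so residual contraction differences
  enter only at the sub-mEh level and cancel between the method curves and
  the in-repo FCI reference computed in the same basis.
* **RHF**: DIIS-accelerated, solved per C2v symmetry block for z-axis
  molecules so that degenerate pi orbitals stay symmetry-pure.
* **FCI**: two independent engines.  `oracle.DetSpace` (n_orb <= 14) is a
  deliberately simple sparse-operator brute-force engine — the ground
  truth for every sign and prefactor.  `bigfci.DirectCI` is a
  string-driven Davidson direct CI with spin-summed gather/GEMM/scatter
  sigma, C2v blocking of both the determinant basis and the pair GEMM,
  singlet spin symmetry (all work done on the alpha side), Olsen-corrected
  updates and warm starts.  The two agree to 1e-8 on every overlapping
  case in the test suite; HF/cc-pVDZ (F 1s frozen, 18 orbitals, 2.3M
  symmetry-reduced determinants) runs at ~4 s per sigma on one core.

## Numerical choices

* pCCD solver: quasi-Newton with the diagonal pair-excitation-energy
  preconditioner + DIIS(6); guess `t = K_ov / (2f_ii - 2f_aa)`; residual
  inf-norm < 1e-8 and energy change < 1e-10; Tikhonov floor 1e-3 on the
  preconditioner only for quasi-degenerate pairs; |t| > 1e3 aborts as
  divergence.
* CC solvers: DIIS(6), MP2-like doubles guess, denominator floor 1e-2,
  residual inf-norm < 1e-8.
* Davidson: residual 2-norm < 1e-5 for production dipole scans (dipole
  error well below 1e-4 D), < 1e-9 in correctness tests; subspace 14 with
  restart; double Gram-Schmidt re-orthogonalization.
* Degenerate turning points/tie-breaks: the spline minimum takes the
  lowest interior critical value; exact ties resolve to the smaller R.

## What the synthetic systems do and do not show

All test molecules (H2, HeH+, H2O in minimal bases; HF/cc-pVDZ) are small
closed-shell systems generated in-repo; they exercise every code path
(degenerate pi shells, frozen cores, ions, symmetry breaking, bond
dissociation) but not large basis sets, Cholesky-decomposed integrals,
open shells, or the heavier molecules where pCCD's localization behavior
is more intricate.  Passing tests certify the equations and their
implementation exactly at small scale; accuracy statements for larger
systems inherit only the model's own limitations (truncated XCC density,
frozen pairs, linearization).

## Known limitations

* Dense `(pq|rs)` storage: practical to ~40 active orbitals.
* The response (Lambda) density is implemented for pCCD only — the point
  of the expectation-value route is to avoid Lambda equations for the
  other models.
* oo-pCCD landscapes have multiple minima at stretched geometries; the
  warm-started scan protocol selects a continuous branch but cannot prove
  global optimality.
* fpLCC can be near-singular at some geometries; this surfaces as a
  solver error by design.
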