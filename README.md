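# xccprop

Expectation-value coupled-cluster density matrices and multipole
properties for pCCD-based wave functions.

## The problem

Pair coupled cluster doubles (pCCD, also known as AP1roG) captures strong
static correlation in closed-shell molecules with mean-field-like cost,
and frozen-pair CC corrections (fpCCD/fpCCSD and their linearized fpLCC
variants) restore dynamic correlation on top of it.  Computing one-electron
*properties* from any of these wave functions normally requires the
Lambda (response) equations — as expensive as the amplitude equations
themselves and simply unavailable for the frozen-pair models.  This
package instead evaluates the one-particle density matrix directly as an
expectation value,

    gamma_pq = <e^T Phi0| E_p^q |e^T Phi0> / <e^T Phi0|e^T Phi0>,

through the connected S-operator expansion truncated at the terms complete
through third order.  With spin-free amplitudes and
t̄ᵢⱼᵃᵇ = 2tᵢⱼᵃᵇ − tᵢⱼᵇᵃ the density blocks are

    gamma_ia = 2 (t_i^a + Σ_jb t_j^b t̄_ij^ab)          occ–virt
    gamma_ik = 2 δ_ik − 2 Σ_jab t_ij^ab t̄_kj^ab         occ–occ
    gamma_ca = +2 Σ_ijb t_ij^ab t̄_ij^cb                 virt–virt

(the occ–virt block vanishes for doubles-only models).  Dipole and
traceless quadrupole moments follow by contraction with the operator
matrices, μ_α = Σ_i Z_i R_iα − Σ_pq γ_pq ⟨p|r_α|q⟩.

Everything needed to run and to *verify* this sits in the repo: a
McMurchie–Davidson Gaussian integral engine (STO-3G and cc-pVDZ), RHF,
pCCD with variational orbital optimization, spin-orbital CC solvers for
CCD/CCSD/fpCC/fpLCC, a brute-force determinant oracle that pins every
sign and prefactor, and a symmetry-blocked direct-CI FCI for the
dipole-moment-surface reference of the HF molecule.

Audience: method developers and students of geminal/coupled-cluster
property theory who want a compact, fully self-contained, oracle-verified
reference implementation.

## Worked example

```bash
python examples/01_pccd_and_fci.py
```

prints (H2O/STO-3G):

```
RHF energy        : -74.96292824 Eh
pCCD energy       : -74.98794882 Eh  (correlation -0.025021)
FCI energy        : -75.01240364 Eh
max |<pair|Hbar|0>| in the full determinant space: 4.04e-10
```

pCCD recovers the paired (seniority-zero) half of the correlation energy;
the last line evaluates the converged amplitudes inside the explicit
441-determinant space and certifies the analytic residual equations.
`examples/02_orbital_optimized_dipole.py` compares the XCC and response
dipoles at the variational-orbital optimum, and
`examples/03_hf_dipole_surface.py` scans the HF/cc-pVDZ bond through the
dipole turning region against the in-repo FCI (a few minutes: each point
is an 18-orbital FCI).

A thin CLI wraps the same library calls:

```bash
xccprop run --molecule h2o_sto3g --method fpccsd --orbitals optimized
xccprop scan --molecule hf_ccpvdz --methods fci,xpccd --rmin 1.1 --rmax 1.45 --stride 0.05
xccprop fixtures --molecule heh+_sto3g --prefix hehp
xccprop oracle-check --molecule h2o_sto3g
```

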