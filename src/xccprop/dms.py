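"""Dipole-moment-surface scans for diatomics, turning points and NPE.

The driver walks a bond-length grid in increasing order and chains three
warm starts: canonical MOs are sign/order aligned with the previous
geometry, the FCI Davidson starts from the previous CI vector, and the
pCCD orbital optimization starts from the previous rotation.  Per point it
can evaluate the FCI reference dipole plus any of the pCCD/CC
expectation-value (XCC) or response densities in pCCD-optimized orbitals.

mu_z is reported in debye in the molecular frame (H at the origin, F on
+z), where the equilibrium HF-molecule value is negative: stretching first
lowers mu_z to a minimum (the turning point, near 1.27 A at FCI) before it
rises back to 0 D at dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import linear_sum_assignment

from . import bigfci, ccsd, fixtures, oopccd, pccd
from .integrals import MolecularIntegrals, PropertyOperators, freeze_core
from .properties import DEBYE
from .xcc_density import build_xcc_1rdm

__all__ = ["ScanResult", "scan_dms", "turning_point", "npe",
           "METHODS"]

METHODS = ("scf", "fci", "pccd_response", "xpccd", "xccd", "xccsd",
           "xfpccd", "xfpccsd", "xfplccd", "xfplccsd")


@dataclass
class ScanResult:
    R: np.ndarray                # bond lengths, Angstrom (strictly increasing)
    mu_z: np.ndarray             # dipole z component, debye (molecular frame)
    energy: np.ndarray           # total energy, hartree
    method_tag: str
    orbital_tag: str = "OO"
    failures: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"R_angstrom": self.R, "mu_z_debye": self.mu_z,
                             "energy_hartree": self.energy})


def _align_mos(C_prev, C_new, e_new, irreps, n_occ, S_cross):
    """Match orbital order and sign to the previous geometry's MOs.

    Uses the true cross-geometry AO overlap; permutations are restricted
    to within the occupied and virtual blocks of each irrep (aufbau
    filling preserved); sign fixing keeps the CI vector continuous.
    """
    n = C_new.shape[1]
    O = C_prev.T @ S_cross @ C_new     # <MO_prev_i | MO_new_j>
    perm = np.arange(n)
    for ir in sorted(set(irreps)):
        for block in (range(0, n_occ), range(n_occ, n)):
            idx = [i for i in block if irreps[i] == ir]
            if len(idx) < 2:
                continue
            M = np.abs(O[np.ix_(idx, idx)])
            rows, cols = linear_sum_assignment(-M)
            perm[np.array(idx)] = np.array(idx)[cols]
    C = C_new[:, perm]
    signs = np.sign(np.diag(C_prev.T @ S_cross @ C))
    signs[signs == 0] = 1.0
    return C * signs[None, :], e_new[perm]


def _active_props(props: PropertyOperators, n_frozen):
    a = slice(n_frozen, None)
    core_dip = 2.0 * np.array([np.trace(M[:n_frozen, :n_frozen])
                               for M in props.dip])
    act = PropertyOperators(atoms=list(props.atoms),
                            dip=props.dip[:, a, a].copy(),
                            quad=props.quad[:, a, a].copy())
    return act, core_dip


def _mu_z(gamma_active, act_props, core_dip_z):
    el = core_dip_z + np.sum(gamma_active * act_props.dip[2])
    return act_props.mu_nuc[2] - el


def scan_dms(R_grid, methods=("fci", "xpccd"), molecule="hf_ccpvdz",
             n_frozen=1, fci_tol=1e-5, verbose=False, method_filter=None,
             oo_seed=12345):
    """Scan mu_z(R) for the requested methods; returns {method: ScanResult}.

    All post-HF methods run in the frozen-core active space; the OO-labeled
    methods use warm-started pCCD orbital optimization, FCI uses aligned
    canonical orbitals.  ``method_filter(method, R) -> bool`` restricts
    expensive methods to a sub-grid; ``oo_seed`` seeds the cold-start
    perturbations of the orbital optimizer.  Failed points are recorded per
    method and skipped; more than 20% failures for a method raises.
    """
    R_grid = np.asarray(sorted(R_grid), dtype=float)
    need_oo = any(m not in ("scf", "fci") for m in methods)
    out = {m: {"R": [], "mu": [], "E": [], "fail": []} for m in methods}

    C_prev = None
    ab_prev = None
    civec = None
    ci_sub = None
    U_prev = None
    prev_oo = None
    prev_cc = {}
    for R in R_grid:
        import time
        t0 = time.time()
        ab = fixtures._basis_for(molecule, R)
        from . import scf as _scf
        from . import basis as _bas
        res = _scf.rhf(ab)
        if C_prev is not None:
            S_cross = _bas.cross_overlap(ab_prev, ab)
            C, e_mo = _align_mos(C_prev, res.mo_coeff, res.mo_energy,
                                 res.mo_irrep, res.n_occ, S_cross)
            res.mo_coeff, res.mo_energy = C, e_mo
        C_prev, ab_prev = res.mo_coeff, ab
        ints_full, props_full = fixtures._mo_transform_all(ab, res, 0)
        ints = freeze_core(ints_full, n_frozen)
        act_props, core_dip = _active_props(props_full, n_frozen)

        sol = None
        if need_oo:
            try:
                sol = oopccd.optimize_orbitals(
                    ints, act_props, start=U_prev,
                    restarts=2 if U_prev is None else 0, seed=oo_seed)
            except RuntimeError as exc:
                for m in methods:
                    if m not in ("scf", "fci"):
                        out[m]["fail"].append((R, str(exc)))
                sol = None
            # energy-continuity guard against hops between orbital-
            # optimization branches: retry cold if the step is anomalous
            if sol is not None and prev_oo is not None:
                thresh = max(0.08, 1.0 * abs(R - prev_oo[0]))
                if abs(sol.energy - prev_oo[1]) > thresh:
                    try:
                        retry = oopccd.optimize_orbitals(
                            ints, act_props, restarts=2, seed=oo_seed + 1)
                        if retry.energy < sol.energy - 1e-9:
                            sol = retry
                    except RuntimeError:
                        pass
                    if abs(sol.energy - prev_oo[1]) > thresh:
                        for m in methods:
                            if m not in ("scf", "fci"):
                                out[m]["fail"].append(
                                    (R, "orbital-optimization branch "
                                        "discontinuity"))
                        sol = None
                        U_prev = None
            if sol is not None:
                U_prev = sol.U
                prev_oo = (R, sol.energy)

        def _wanted(m):
            return method_filter is None or method_filter(m, R)

        if "scf" in methods and _wanted("scf"):
            out["scf"]["R"].append(R)
            out["scf"]["mu"].append(
                _mu_z(np.diag([2.0] * ints.n_occ
                              + [0.0] * (ints.n_orb - ints.n_occ)),
                      act_props, core_dip[2]))
            out["scf"]["E"].append(res.energy)

        if "fci" in methods and _wanted("fci"):
            try:
                ci = bigfci.DirectCI(ints)
                e_fci, civec = ci.solve(c0=civec, tol=fci_tol,
                                        subspace0=ci_sub)
                ci_sub = ci.last_subspace
                gam = ci.rdm1(civec)
                out["fci"]["R"].append(R)
                out["fci"]["mu"].append(_mu_z(gam, act_props, core_dip[2]))
                out["fci"]["E"].append(e_fci)
            except RuntimeError as exc:
                out["fci"]["fail"].append((R, str(exc)))
                civec = None
                ci_sub = None

        if sol is not None:
            oo_ints = sol.ints_rotated
            oo_props = sol.props_rotated
            amps = sol.amps
            cc_cache = {}

            def _density(m):
                if m == "pccd_response":
                    rd = pccd.pccd_response_rdms(amps, oo_ints.n_orb)
                    return rd.gamma, sol.energy
                if m == "xpccd":
                    return build_xcc_1rdm(amps, oo_ints.n_orb).gamma, sol.energy
                key = m[1:]           # strip the density marker "x"
                if key not in cc_cache:
                    g0 = prev_cc.get(key)
                    if key in ("ccd", "ccsd"):
                        cc_cache[key] = ccsd.solve_cc(oo_ints, key, guess=g0)
                    elif key.startswith("fpl"):
                        cc_cache[key] = ccsd.solve_fplcc(
                            oo_ints, amps, "sd" if key.endswith("sd") else "d",
                            guess=g0)
                    else:
                        cc_cache[key] = ccsd.solve_fpcc(
                            oo_ints, amps, "sd" if key.endswith("sd") else "d",
                            guess=g0)
                    prev_cc[key] = cc_cache[key]
                cc = cc_cache[key]
                return build_xcc_1rdm(cc, oo_ints.n_orb).gamma, cc.e_total

            for m in methods:
                if m in ("scf", "fci") or not _wanted(m):
                    continue
                try:
                    gam, en = _density(m)
                    out[m]["R"].append(R)
                    out[m]["mu"].append(_mu_z(gam, oo_props, core_dip[2]))
                    out[m]["E"].append(en)
                except (RuntimeError, np.linalg.LinAlgError) as exc:
                    out[m]["fail"].append((R, str(exc)))
        if verbose:
            print(f"R={R:.3f} done in {time.time()-t0:.1f}s", flush=True)

    results = {}
    for m in methods:
        nfail = len(out[m]["fail"])
        npts = max(1, len(out[m]["R"]) + nfail)
        if nfail > 0.2 * npts:
            raise RuntimeError(
                f"scan for {m} failed at {nfail}/{npts} points: "
                f"{out[m]['fail'][:3]}")
        mu = np.array(out[m]["mu"])
        results[m] = ScanResult(
            R=np.array(out[m]["R"]), mu_z=mu * DEBYE,
            energy=np.array(out[m]["E"]), method_tag=m,
            orbital_tag="OO" if m not in ("scf", "fci") else "HF",
            failures=out[m]["fail"])
    return results


def turning_point(scan: ScanResult) -> float:
    """Bond length (Angstrom) minimizing the cubic-spline interpolant."""
    if len(scan.R) < 4:
        raise ValueError("turning point location needs at least 4 points")
    cs = CubicSpline(scan.R, scan.mu_z)
    crit = cs.derivative().roots(extrapolate=False)
    crit = [r for r in np.atleast_1d(crit).real
            if scan.R[0] < r < scan.R[-1]]
    if not crit:
        raise ValueError("no interior minimum in the scanned window")
    vals = cs(crit)
    cand = [(v, r) for v, r in zip(vals, crit)]
    v0, r0 = min(cand)
    # compare against endpoints: the minimum must be interior
    if v0 >= min(cs(scan.R[0]), cs(scan.R[-1])):
        raise ValueError("no interior minimum in the scanned window")
    return float(r0)


def npe(scan: ScanResult, reference: ScanResult, npoints=2001) -> float:
    """Nonparallelity error: max minus min of the pointwise deviation (D)."""
    lo = max(scan.R[0], reference.R[0])
    hi = min(scan.R[-1], reference.R[-1])
    if hi <= lo:
        raise ValueError("scan ranges do not overlap")
    grid = np.linspace(lo, hi, npoints)
    d = CubicSpline(scan.R, scan.mu_z)(grid) \
        - CubicSpline(reference.R, reference.mu_z)(grid)
    return float(d.max() - d.min())
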