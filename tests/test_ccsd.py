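"""Spin-orbital CC solvers: oracle residuals, exactness limits, variants."""

import numpy as np
import pytest

from xccprop import ccsd, oracle, pccd
from conftest import (oracle_cluster_op, scale_fluctuation,
                      sz_conserving_random_amplitudes)


def test_two_electron_ccsd_equals_fci(h2, h2_space):
    e_fci, _ = h2_space.fci_solve(h2.ints)
    res = ccsd.solve_cc(h2.ints, "ccsd")
    assert res.e_total == pytest.approx(e_fci, abs=1e-9)


def test_residual_matches_determinant_space_on_random_amplitudes(h2o,
                                                                 h2o_space):
    """The analytic spin-orbital residual equals <mu|e^-T H e^T|0> computed
    by explicit operator algebra, for arbitrary Sz-conserving amplitudes."""
    no, nv = 10, 4
    rng = np.random.default_rng(0)
    t1, t2 = sz_conserving_random_amplitudes(no, nv, rng)
    f, eri = ccsd.spin_orbital_ints(h2o.ints)
    R1, R2 = ccsd._residual(f, eri, t1, t2, no)
    ds = h2o_space
    T = oracle_cluster_op(ds, 5, t1, t2)

    def somap(p, occ):
        return p // 2 + (0 if occ else 5), ("a" if p % 2 == 0 else "b")

    bras = []
    for (i, a) in [(0, 0), (1, 3), (4, 2), (9, 3)]:
        pi, si = somap(i, True)
        pa, sa = somap(a, False)
        if si == sa:
            bras.append(("s", (i, a), ds.exc(pi, pa, si)))
    for (i, j, a, b) in [(0, 1, 0, 1), (3, 4, 0, 2), (8, 9, 2, 3),
                         (2, 7, 1, 2), (0, 3, 2, 1)]:
        pi, si = somap(i, True)
        pj, sj = somap(j, True)
        pa, sa = somap(a, False)
        pb, sb = somap(b, False)
        if sa == si and sb == sj:
            bras.append(("d", (i, j, a, b), ds.exc(pi, pa, si) @ ds.exc(pj, pb, sj)))
    res = ds.projective_residual(h2o.ints, T, [b[2] for b in bras])
    for (kind, idx, _), r in zip(bras, res):
        mine = R1[idx] if kind == "s" else R2[idx]
        assert mine == pytest.approx(r, abs=1e-9)


def test_ccd_ccsd_bracket_fci(h2o, h2o_fci):
    e_fci, _ = h2o_fci
    ccd = ccsd.solve_cc(h2o.ints, "ccd")
    sd = ccsd.solve_cc(h2o.ints, "ccsd")
    assert ccd.e_total > e_fci and sd.e_total > e_fci
    assert sd.e_total < ccd.e_total  # singles recover more correlation here
    assert sd.residual_norm < 1e-8


def test_frozen_pair_channel_is_bit_identical(h2o):
    pa = pccd.solve_pccd(h2o.ints)
    fp = ccsd.solve_fpcc(h2o.ints, pa, "sd")
    pair = np.array([[fp.t2[i, i, a, a] for a in range(2)] for i in range(5)])
    assert np.array_equal(pair, pa.t)
    assert fp.pair_frozen


def test_spinfree_t2_permutational_symmetry(h2o):
    fp = ccsd.solve_fpcc(h2o.ints, pccd.solve_pccd(h2o.ints), "sd")
    t2 = fp.t2
    assert np.max(np.abs(t2 - t2.transpose(1, 0, 3, 2))) < 1e-12


def test_two_electron_fpccd_adds_nothing(h2):
    """With a single pair every double is a pair double: fpCCD == pCCD."""
    pa = pccd.solve_pccd(h2.ints)
    fp = ccsd.solve_fpcc(h2.ints, pa, "d")
    assert fp.e_total == pytest.approx(pa.e_total, abs=1e-10)


def test_unconverged_pair_input_rejected(h2o):
    bad = pccd.PairAmplitudes(t=np.zeros((5, 2)), converged=False)
    with pytest.raises(ValueError, match="converged"):
        ccsd.solve_fpcc(h2o.ints, bad)
    with pytest.raises(ValueError, match="converged"):
        ccsd.solve_fplcc(h2o.ints, bad)


def test_fplcc_approaches_fpcc_at_weak_fluctuation(h2o):
    """The fpCC-fpLCC difference is beyond linear order, so the relative
    amplitude difference must vanish faster than the amplitudes."""
    ratios = []
    for lam in (0.4, 0.2, 0.1):
        ints = scale_fluctuation(h2o.ints, lam)
        pa = pccd.solve_pccd(ints)
        a_fp = ccsd.solve_fpcc(ints, pa, "d")
        a_fl = ccsd.solve_fplcc(ints, pa, "d")
        num = np.max(np.abs(a_fl.t2so - a_fp.t2so))
        den = np.max(np.abs(a_fp.t2so))
        ratios.append(num / den)
    assert ratios[1] < 0.5 * ratios[0]
    assert ratios[2] < 0.5 * ratios[1]


def test_fplcc_linear_residual_matches_determinant_space(h2o, h2o_space):
    """fpLCC residual equals the projection of (H + [H, T'])|Psi_pCCD>."""
    ints = h2o.ints
    ds = h2o_space
    pa = pccd.solve_pccd(ints)
    fl = ccsd.solve_fplcc(ints, pa, "d")
    # determinant space: w = e^-Tp (H + [H,T']) e^Tp |0>, project nonpair
    no, nv = 10, 4
    Tp = oracle_cluster_op(ds, 5, None, ccsd._pair_seed(pa.t, 5, 2))
    Text = oracle_cluster_op(ds, 5, None,
                             fl.t2so - ccsd._pair_seed(pa.t, 5, 2))
    ref = ds.ref_vector(5)
    H = ds.hamiltonian(ints)
    v = ds.exp_apply(Tp, ref)
    w = H @ (Text @ v) - Text @ (H @ v) + H @ v + ints.e_core * v \
        + ints.e_core * 0.0
    w = ds.exp_apply(Tp, w, sign=-1.0)

    def somap(p, occ):
        return p // 2 + (0 if occ else 5), ("a" if p % 2 == 0 else "b")

    for (i, j, a, b) in [(0, 2, 1, 3), (3, 4, 0, 2), (2, 7, 1, 2)]:
        pi, si = somap(i, True)
        pj, sj = somap(j, True)
        pa_, sa = somap(a, False)
        pb, sb = somap(b, False)
        if not (sa == si and sb == sj):
            continue
        mu = (ds.exc(pi, pa_, si) @ ds.exc(pj, pb, sj)) @ ref
        assert mu @ w == pytest.approx(0.0, abs=1e-8)
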