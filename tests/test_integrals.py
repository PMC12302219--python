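"""Hamiltonian container, FCIDUMP I/O, rotations, frozen core, Fock."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from xccprop import oracle
from xccprop.integrals import (MolecularIntegrals, PropertyOperators,
                               fock_matrix, freeze_core, read_fcidump,
                               read_property_operators, transform_mo,
                               write_fcidump, write_property_operators)


def test_empty_hamiltonian_roundtrip(tmp_path):
    path = tmp_path / "empty.fcidump"
    path.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n0.0 0 0 0 0\n")
    ints = read_fcidump(path)
    assert ints.n_orb == 2 and ints.n_elec == 2
    assert ints.e_core == 0.0
    assert np.all(ints.h == 0.0) and np.all(ints.g == 0.0)


def test_h2_core_energy_is_point_charge_repulsion(h2, tmp_path):
    assert h2.ints.e_core == pytest.approx(1.0 / 1.4, abs=1e-12)
    p = tmp_path / "h2.fcidump"
    write_fcidump(h2.ints, p)
    back = read_fcidump(p)
    assert back.e_core == pytest.approx(h2.ints.e_core, abs=1e-12)
    assert np.max(np.abs(back.h - h2.ints.h)) < 1e-12
    assert np.max(np.abs(back.g - h2.ints.g)) < 1e-12
    back.check_symmetry()


def test_fcidump_writes_only_unique_elements(h2o, tmp_path):
    p = tmp_path / "h2o.fcidump"
    write_fcidump(h2o.ints, p)
    seen = set()
    for line in p.read_text().splitlines():
        parts = line.split()
        if len(parts) != 5 or "=" in line or "&" in line:
            continue
        i, j, k, l = map(int, parts[1:])
        if min(i, j, k, l) == 0 or k == 0:
            continue
        canon = set()
        for a, b, c, d in ((i, j, k, l), (j, i, k, l), (i, j, l, k),
                           (j, i, l, k), (k, l, i, j), (l, k, i, j),
                           (k, l, j, i), (l, k, j, i)):
            canon.add((a, b, c, d))
        key = min(canon)
        assert key not in seen, "symmetry-redundant quadruple emitted"
        seen.add(key)


def test_malformed_header_and_bad_index_raise(tmp_path):
    p = tmp_path / "bad.fcidump"
    p.write_text("&FCI NELEC=2,\n&END\n0.0 0 0 0 0\n")
    with pytest.raises(ValueError, match="NORB"):
        read_fcidump(p)
    p.write_text("&FCI NORB=2,NELEC=2,MS2=1,\n&END\n0.0 0 0 0 0\n")
    with pytest.raises(ValueError, match="MS2"):
        read_fcidump(p)
    p.write_text("&FCI NORB=2,NELEC=2,MS2=0,\n&END\n1.0 3 1 1 1\n")
    with pytest.raises(ValueError, match="out of range"):
        read_fcidump(p)


def test_transform_identity_and_permutation(h2o):
    n = h2o.ints.n_orb
    same = transform_mo(h2o.ints, np.eye(n))
    assert np.allclose(same.h, h2o.ints.h, atol=1e-14)
    P = np.eye(n)[:, ::-1]
    perm = transform_mo(h2o.ints, P)
    assert perm.h[0, 0] == pytest.approx(h2o.ints.h[n - 1, n - 1])
    assert perm.g[0, 0, 0, 0] == pytest.approx(h2o.ints.g[n - 1, n - 1,
                                                          n - 1, n - 1])


def test_fci_energy_invariant_under_orbital_rotation(h2, h2_space):
    e0, _ = h2_space.fci_solve(h2.ints)
    U = ortho_group.rvs(2, random_state=7)
    e1, _ = h2_space.fci_solve(transform_mo(h2.ints, U))
    assert e1 == pytest.approx(e0, abs=1e-10)


def test_nonorthogonal_rotation_rejected(h2):
    with pytest.raises(ValueError, match="orthogonal"):
        transform_mo(h2.ints, np.array([[1.0, 0.1], [0.0, 1.0]]))


def test_freeze_core_identity_and_decoupled_core(h2o):
    assert freeze_core(h2o.ints, 0) is h2o.ints
    # synthetic decoupled core: core orbital couples to nothing
    n = 3
    h = np.diag([-5.0, -1.0, 0.5])
    g = np.zeros((n, n, n, n))
    g[0, 0, 0, 0] = 0.9
    g[1, 1, 1, 1] = 0.6
    ints = MolecularIntegrals(n_orb=n, n_elec=4, e_core=0.3, h=h, g=g)
    fro = freeze_core(ints, 1)
    assert fro.e_core == pytest.approx(0.3 + 2 * (-5.0) + 0.9, abs=1e-12)
    assert fro.n_elec == 2 and fro.n_orb == 2


def test_frozen_core_fci_matches_constrained_parent(h2o, h2o_space):
    """Freezing the O 1s reproduces the core-doubly-occupied FCI energy."""
    fro = freeze_core(h2o.ints, 1)
    ds = oracle.DetSpace(fro.n_orb, fro.n_elec)
    e_frozen, _ = ds.fci_solve(fro)
    # constrained parent-problem FCI: core always doubly occupied
    full = oracle.DetSpace(7, 10)
    H = full.hamiltonian(h2o.ints)
    keep = []
    for ia, sa in enumerate(full.strings):
        for ib, sb in enumerate(full.strings):
            if (sa & 1) and (sb & 1):
                keep.append(ia * full.nstr + ib)
    keep = np.array(keep)
    Hc = H[np.ix_(keep, keep)].toarray()
    w = np.linalg.eigvalsh(Hc)
    assert e_frozen == pytest.approx(w[0] + h2o.ints.e_core, abs=1e-10)


def test_fock_matrix_properties(h2):
    ints = h2.ints
    f = fock_matrix(ints, 1)
    assert np.allclose(f, f.T, atol=1e-12)
    # canonical orbitals: off-diagonal occ-virt block vanishes
    assert abs(f[0, 1]) < 1e-7
    assert f[0, 0] == pytest.approx(h2.scf.mo_energy[0], abs=1e-7)
    zero_g = MolecularIntegrals(n_orb=2, n_elec=2, e_core=0.0,
                                h=ints.h, g=np.zeros((2, 2, 2, 2)))
    assert np.allclose(fock_matrix(zero_g, 1), ints.h, atol=1e-14)


def test_property_operator_roundtrip_and_nuclear_moments(hehp, tmp_path):
    p = tmp_path / "props.json"
    write_property_operators(hehp.props, p)
    back = read_property_operators(p)
    assert np.max(np.abs(back.dip - hehp.props.dip)) < 1e-15
    assert np.max(np.abs(back.quad - hehp.props.quad)) < 1e-15
    # He at origin, H at (0,0,1.4632): mu_nuc = (0,0,1*1.4632)
    assert back.mu_nuc[2] == pytest.approx(1.4632, abs=1e-12)
    tr = back.quad[0] + back.quad[3] + back.quad[5]
    assert np.max(np.abs(tr)) < 1e-9


from hypothesis import given, settings, strategies as st


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(min_value=2, max_value=4),
       seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_fcidump_roundtrip_random_hamiltonians(n, seed):
    """Any 8-fold-symmetric Hamiltonian survives the FCIDUMP round trip."""
    import tempfile
    import os
    rng = np.random.default_rng(seed)
    h = rng.standard_normal((n, n))
    h = 0.5 * (h + h.T)
    g = rng.standard_normal((n, n, n, n))
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        g = 0.5 * (g + g.transpose(perm))
    ints = MolecularIntegrals(n_orb=n, n_elec=2, e_core=rng.standard_normal(),
                              h=h, g=g)
    ints.check_symmetry(tol=1e-9)
    fd, path = tempfile.mkstemp(suffix=".fcidump")
    os.close(fd)
    try:
        write_fcidump(ints, path)
        back = read_fcidump(path)
    finally:
        os.unlink(path)
    assert back.e_core == pytest.approx(ints.e_core, abs=1e-12)
    assert np.max(np.abs(back.h - ints.h)) < 1e-12
    assert np.max(np.abs(back.g - ints.g)) < 1e-12
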