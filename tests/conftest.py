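import numpy as np
import pytest

from xccprop import fixtures, oracle


@pytest.fixture(scope="session")
def h2():
    return fixtures.make_system("h2_sto3g")


@pytest.fixture(scope="session")
def hehp():
    return fixtures.make_system("heh+_sto3g")


@pytest.fixture(scope="session")
def h2o():
    return fixtures.make_system("h2o_sto3g")


@pytest.fixture(scope="session")
def h2_space():
    return oracle.DetSpace(2, 2)


@pytest.fixture(scope="session")
def h2o_space():
    return oracle.DetSpace(7, 10)


@pytest.fixture(scope="session")
def h2o_fci(h2o, h2o_space):
    e, v = h2o_space.fci_solve(h2o.ints)
    return e, v / np.linalg.norm(v)


def sz_conserving_random_amplitudes(no, nv, rng, scale=0.02):
    """Random spin-orbital t1/t2 restricted to the Sz-conserving sector."""
    spin = lambda p: p % 2
    t1 = rng.standard_normal((no, nv)) * scale
    for i in range(no):
        for a in range(nv):
            if spin(i) != spin(a):
                t1[i, a] = 0.0
    t2 = rng.standard_normal((no, no, nv, nv)) * scale
    for i in range(no):
        for j in range(no):
            for a in range(nv):
                for b in range(nv):
                    if (spin(i) + spin(j)) != (spin(a) + spin(b)):
                        t2[i, j, a, b] = 0.0
    t2 = 0.25 * (t2 - t2.transpose(0, 1, 3, 2) - t2.transpose(1, 0, 2, 3)
                 + t2.transpose(1, 0, 3, 2))
    return t1, t2


def oracle_cluster_op(ds, no_sp, t1so, t2so):
    """Assemble the oracle sparse cluster operator from spin-orbital amps."""
    import scipy.sparse as sp
    no, nv = t2so.shape[0], t2so.shape[2]

    def somap(p, occ):
        return p // 2 + (0 if occ else no_sp), ("a" if p % 2 == 0 else "b")

    T = sp.csr_matrix((ds.dim, ds.dim))
    if t1so is not None:
        for i in range(no):
            pi, si = somap(i, True)
            for a in range(nv):
                pa, sa = somap(a, False)
                if si == sa and abs(t1so[i, a]) > 1e-15:
                    T = T + t1so[i, a] * ds.exc(pi, pa, si)
    for i in range(no):
        for j in range(no):
            for a in range(nv):
                for b in range(nv):
                    v = t2so[i, j, a, b]
                    if abs(v) < 1e-15:
                        continue
                    pi, si = somap(i, True)
                    pj, sj = somap(j, True)
                    pa, sa = somap(a, False)
                    pb, sb = somap(b, False)
                    if sa == si and sb == sj:
                        op = ds.exc(pi, pa, si) @ ds.exc(pj, pb, sj)
                    elif sa == sj and sb == si:
                        op = -(ds.exc(pj, pa, sa) @ ds.exc(pi, pb, sb))
                    else:
                        continue
                    T = T + 0.25 * v * op
    return T


def spin_adapted_so(t1_sp, t2_sp):
    """Map spin-free closed-shell amplitudes to antisymmetrized spin-orbital
    arrays (interleaved spins); t2_sp must satisfy t2[i,j,a,b]=t2[j,i,b,a]."""
    no, nv = t1_sp.shape
    t1so = np.zeros((2 * no, 2 * nv))
    t2so = np.zeros((2 * no, 2 * no, 2 * nv, 2 * nv))
    for i in range(no):
        for a in range(nv):
            t1so[2 * i, 2 * a] = t1so[2 * i + 1, 2 * a + 1] = t1_sp[i, a]
    for i in range(no):
        for j in range(no):
            for a in range(nv):
                for b in range(nv):
                    v = t2_sp[i, j, a, b]
                    t2so[2 * i, 2 * j + 1, 2 * a, 2 * b + 1] += v
                    t2so[2 * i + 1, 2 * j, 2 * a + 1, 2 * b] += v
                    t2so[2 * i, 2 * j + 1, 2 * b + 1, 2 * a] -= v
                    t2so[2 * i + 1, 2 * j, 2 * b, 2 * a + 1] -= v
                    t2so[2 * j + 1, 2 * i, 2 * a, 2 * b + 1] -= v
                    t2so[2 * j, 2 * i + 1, 2 * a + 1, 2 * b] -= v
                    t2so[2 * j + 1, 2 * i, 2 * b + 1, 2 * a] += v
                    t2so[2 * j, 2 * i + 1, 2 * b, 2 * a + 1] += v
                    w = t2_sp[i, j, a, b] - t2_sp[i, j, b, a]
                    if i != j and a != b:
                        for s_ in (0, 1):
                            t2so[2 * i + s_, 2 * j + s_,
                                 2 * a + s_, 2 * b + s_] += 2 * w
    return t1so, 0.5 * t2so


def scale_fluctuation(ints, lam):
    """Scale the two-electron fluctuation, keeping the HF mean field fixed."""
    from xccprop.integrals import MolecularIntegrals
    no = ints.n_occ
    o = np.arange(no)
    vhf = (2.0 * np.einsum("pqii->pq", ints.g[:, :, o][:, :, :, o])
           - np.einsum("piiq->pq", ints.g[:, o][:, :, o, :]))
    return MolecularIntegrals(n_orb=ints.n_orb, n_elec=ints.n_elec,
                              e_core=ints.e_core,
                              h=ints.h + (1.0 - lam) * vhf, g=ints.g * lam)
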