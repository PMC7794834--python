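import numpy as np
import pytest

import ionsite as isite


@pytest.fixture(scope="session")
def born_plus3():
    """+3 e single-atom solute (R = 2 A)."""
    return isite.fixtures.make_born_ion(3.0, 2.0)


@pytest.fixture(scope="session")
def chloride():
    return isite.get_ion("CL1")


@pytest.fixture(scope="session")
def calcium():
    return isite.get_ion("CA2")


@pytest.fixture(scope="session")
def patch_run(chloride):
    """Charged-patch (+3 e face) prediction with Cl-, shared across tests."""
    s, normal = isite.fixtures.make_charged_patch(18, 3.0)
    run = isite.predict_full(s, chloride, n_max=10)
    return s, normal, run


@pytest.fixture(scope="session")
def born_run(born_plus3, chloride):
    """Born +3 e solute with Cl- on a roomy 29^3 grid."""
    return isite.predict_full(born_plus3, chloride, n_max=10, perfil=30.0)


def exhaustive_predict(s, ion, run, n_max=10, min_sep=6.0,
                       include_desolvation=True):
    """Independent exhaustive-scan reference for the ranking algorithm.

    Scores every exterior interior node with the site energy, sorts the
    negative-energy nodes fully (ties by lexicographic index), then walks
    the sorted list applying the clash and mutual-separation filters with
    plain loops.  Shares the potential/dielectric maps with the run under
    test but none of its queue/filter code.
    """
    g = run.grid
    phi = run.potential.phi
    ex, ey, ez = run.eps.eps_mid
    eps_w = run.eps.params.eps_w
    kT = isite.kt_kcal(298.15)
    coul = isite.COULOMB_KCAL
    z = ion.valence
    pos_a = s.positions
    rad_a = s.radii
    n = g.n
    scored = []
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            for k in range(1, n - 1):
                p = g.origin + np.array([i, j, k]) * g.h
                d = np.linalg.norm(pos_a - p, axis=1)
                if np.any(d <= rad_a):
                    continue  # inside the vdW surface
                eps_avg = (ex[i - 1, j, k] + ex[i, j, k]
                           + ey[i, j - 1, k] + ey[i, j, k]
                           + ez[i, j, k - 1] + ez[i, j, k]) / 6.0
                gval = ion.charge * phi[i, j, k] * kT
                if include_desolvation:
                    gval = gval + coul / (2.0 * ion.effective_radius) \
                        * z**2 * (1.0 / eps_avg - 1.0 / eps_w)
                if gval < 0.0:
                    scored.append((gval, i, j, k))
    scored.sort()
    accepted = []
    for gval, i, j, k in scored:
        if len(accepted) >= n_max:
            break
        p = g.origin + np.array([i, j, k]) * g.h
        d = np.linalg.norm(pos_a - p, axis=1)
        if np.any(d < ion.clash_radius + rad_a):
            continue
        if any(np.linalg.norm(p - q) <= min_sep for _, q in accepted):
            continue
        accepted.append((gval, p))
    return accepted
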