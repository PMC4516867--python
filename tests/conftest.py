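import itertools

import numpy as np
import pytest

from bitterquant.hdx import state_distribution
from bitterquant.isotopes import (
    ELECTRON_MASS,
    ISOTOPE_TABLE,
    MolecularFormula,
    parse_formula,
)


@pytest.fixture(scope="session")
def denatonium():
    """The unlabeled denatonium cation C21H29N2O+."""
    return parse_formula("C21H29N2O", 1)


@pytest.fixture(scope="session")
def denatonium_d2():
    """The α-C dideuterated denatonium cation C21H27D2N2O+."""
    return parse_formula("C21H27D2N2O", 1)


@pytest.fixture(scope="session")
def full_label():
    """Completely α-dideuterated standard, amide back-exchanged to H."""
    return state_distribution(1.0, amide_d=False)


def brute_force_pattern(f: MolecularFormula, merge_tol: float = 1e-3):
    """Exhaustive isotopologue enumeration — the independent envelope oracle.

    Every atom independently picks one of its element's isotopes; each of the
    (prod of n_isotopes^n_atoms) assignments contributes its exact mass with
    its joint probability.  Feasible only for small formulas; stays fully
    independent of the convolution code it checks.
    """
    atoms = []
    for sym, n in sorted(f.counts.items()):
        atoms.extend([ISOTOPE_TABLE[sym].isotopes] * n)
    masses = {}
    for combo in itertools.product(*atoms):
        m = sum(x[0] for x in combo)
        p = 1.0
        for x in combo:
            p *= x[1]
        masses[round(m, 9)] = masses.get(round(m, 9), 0.0) + p
    mz = np.array(sorted(masses))
    ab = np.array([masses[m] for m in mz])
    # centroid within merge_tol, abundance-weighted, same convention as the
    # implementation but written independently
    out_m, out_a = [], []
    for m, a in zip(mz, ab):
        if out_m and m - out_m[-1][-1] <= merge_tol:
            out_m[-1].append(m)
            out_a[-1].append(a)
        else:
            out_m.append([m])
            out_a.append([a])
    cm = np.array([np.average(ms, weights=as_) for ms, as_ in zip(out_m, out_a)])
    ca = np.array([sum(as_) for as_ in out_a])
    ca = ca / ca.sum()
    if f.charge != 0:
        cm = (cm - f.charge * ELECTRON_MASS) / abs(f.charge)
    return cm, ca
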