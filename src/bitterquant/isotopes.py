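"""Molecular formulas, monoisotopic masses and aggregated isotope patterns.

The quantification strategy rests on comparing theoretical isotopic envelopes
of light (unlabeled) and heavy (deuterated) species, so this module is the
numerical foundation of the package.  Envelopes are computed by per-element
multinomial convolution: the single-atom isotope distribution of each element
is raised to the power of its atom count (convolution by repeated squaring),
and the per-element distributions are then convolved together.  Centroids
closer than ``merge_tol`` are merged by abundance-weighted mean, which yields
instrument-level *aggregated* patterns rather than fine isotopic structure.

Deuterium is treated as its own pseudo-element ``"D"`` (isotopically pure
:sup:`2`H), so a labeled species such as ``C21H27D2N2O`` is an ordinary
formula string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "ElementIsotopes",
    "ISOTOPE_TABLE",
    "MolecularFormula",
    "IsotopePattern",
    "parse_formula",
    "monoisotopic_mz",
    "average_mass",
    "isotope_pattern",
    "convolve",
]

#: CODATA electron mass in Da; subtracted once per positive charge so that
#: cation m/z values are correct at the sub-mDa level.
ELECTRON_MASS = 0.000548579909065


@dataclass(frozen=True)
class ElementIsotopes:
    """Stable isotopes of one element: (exact mass in Da, natural abundance)."""

    symbol: str
    isotopes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.isotopes]
        abunds = [a for _, a in self.isotopes]
        if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])):
            raise ValueError(f"{self.symbol}: isotope masses must be strictly increasing")
        if abs(sum(abunds) - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: abundances must sum to 1")
        if any(a < 0 for a in abunds):
            raise ValueError(f"{self.symbol}: negative abundance")


# IUPAC 2013 atomic masses and representative isotopic abundances.
# "D" is the deuterium label: isotopically pure 2H at the labeled position.
ISOTOPE_TABLE: dict[str, ElementIsotopes] = {
    e.symbol: e
    for e in [
        ElementIsotopes("H", ((1.00782503207, 0.999885), (2.01410177785, 0.000115))),
        ElementIsotopes("D", ((2.01410177785, 1.0),)),
        ElementIsotopes("C", ((12.0, 0.9893), (13.00335483507, 0.0107))),
        ElementIsotopes("N", ((14.00307400443, 0.99636), (15.00010889888, 0.00364))),
        ElementIsotopes(
            "O",
            (
                (15.99491461957, 0.99757),
                (16.99913175650, 0.00038),
                (17.99915961286, 0.00205),
            ),
        ),
        ElementIsotopes("F", ((18.99840316273, 1.0),)),
        ElementIsotopes("Na", ((22.98976928, 1.0),)),
        ElementIsotopes("P", ((30.97376199842, 1.0),)),
        ElementIsotopes(
            "S",
            (
                (31.9720711744, 0.9499),
                (32.9714589098, 0.0075),
                (33.967867004, 0.0425),
                (35.96708071, 0.0001),
            ),
        ),
        ElementIsotopes("Cl", ((34.968852682, 0.7576), (36.965902602, 0.2424))),
        ElementIsotopes(
            "K",
            (
                (38.9637064864, 0.932581),
                (39.963998166, 0.000117),
                (40.9618252579, 0.067302),
            ),
        ),
        ElementIsotopes("Br", ((78.9183376, 0.5069), (80.9162897, 0.4931))),
        ElementIsotopes("I", ((126.9044719, 1.0),)),
    ]
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with explicit deuterium and an integer charge.

    ``counts`` keeps ``"D"`` distinct from ``"H"``: labeled and unlabeled
    species of the same compound are different formulas.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v != 0}
        if not clean:
            raise ValueError("empty molecular formula")
        for sym, n in clean.items():
            if sym not in ISOTOPE_TABLE:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}")
        object.__setattr__(self, "counts", dict(clean))

    def replace(self, **changes: int) -> "MolecularFormula":
        """Return a copy with element counts adjusted by the given deltas."""
        counts = dict(self.counts)
        for sym, delta in changes.items():
            counts[sym] = counts.get(sym, 0) + delta
            if counts[sym] < 0:
                raise ValueError(f"count of {sym} would become negative")
        return MolecularFormula(counts, self.charge)

    def __str__(self) -> str:
        order = sorted(self.counts, key=lambda s: (s != "C", s != "H", s != "D", s))
        return "".join(f"{s}{n if n > 1 else ''}" for s, n in ((s, self.counts[s]) for s in order))


@dataclass
class IsotopePattern:
    """Centroided theoretical envelope: (m/z, relative abundance) pairs.

    Abundances sum to one when ``normalized``; m/z values are strictly
    increasing and no two centroids sit closer than the merge tolerance used
    to build the pattern.
    """

    mz: np.ndarray
    abundance: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.shape != self.abundance.shape or self.mz.ndim != 1:
            raise ValueError("mz and abundance must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.abundance < 0):
            raise ValueError("negative abundance")
        if self.normalized and abs(self.abundance.sum() - 1.0) > 1e-9:
            raise ValueError("normalized pattern must sum to 1")

    def __len__(self) -> int:
        return len(self.mz)

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.abundance.tolist()))


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse a Hill-like element–count string, e.g. ``"C21H27D2N2O"``.

    ``"D"`` is reserved for the deuterium label; the charge is passed
    separately rather than encoded in the string.
    """
    if not isinstance(text, str) or not text:
        raise ValueError("formula string must be non-empty")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula near {text[pos:]!r}")
        if not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if sym not in ISOTOPE_TABLE:
            raise ValueError(f"unknown element symbol: {sym!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"explicit zero count for {sym}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula near {text[pos:]!r}")
    return MolecularFormula(counts, charge)


def _lightest_mass(symbol: str) -> float:
    return ISOTOPE_TABLE[symbol].isotopes[0][0]


def monoisotopic_mz(f: MolecularFormula) -> float:
    """Monoisotopic m/z (Da per unit charge); neutral mass when charge is 0.

    Sums lightest-isotope masses (the deuterium pseudo-element contributes the
    2H mass) and subtracts one electron mass per unit of positive charge.
    """
    mass = sum(n * _lightest_mass(sym) for sym, n in f.counts.items())
    if f.charge == 0:
        return mass
    return (mass - f.charge * ELECTRON_MASS) / abs(f.charge)


def average_mass(f: MolecularFormula) -> float:
    """Abundance-weighted average molecular mass in Da (gravimetric MW)."""
    total = 0.0
    for sym, n in f.counts.items():
        iso = ISOTOPE_TABLE[sym].isotopes
        total += n * sum(m * a for m, a in iso)
    return total


def _merge_centroids(
    mass: np.ndarray, abundance: np.ndarray, merge_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge centroids closer than merge_tol by abundance-weighted mean."""
    order = np.argsort(mass, kind="stable")
    mass, abundance = mass[order], abundance[order]
    out_m: list[float] = []
    out_a: list[float] = []
    acc_m = mass[0] * abundance[0]
    acc_a = abundance[0]
    last = mass[0]
    for m, a in zip(mass[1:], abundance[1:]):
        if m - last <= merge_tol:
            acc_m += m * a
            acc_a += a
        else:
            out_m.append(acc_m / acc_a if acc_a > 0 else last)
            out_a.append(acc_a)
            acc_m, acc_a = m * a, a
        last = m
    out_m.append(acc_m / acc_a if acc_a > 0 else last)
    out_a.append(acc_a)
    return np.asarray(out_m), np.asarray(out_a)


def _convolve_raw(
    m1: np.ndarray, a1: np.ndarray, m2: np.ndarray, a2: np.ndarray, merge_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    mass = (m1[:, None] + m2[None, :]).ravel()
    ab = (a1[:, None] * a2[None, :]).ravel()
    return _merge_centroids(mass, ab, merge_tol)


def _element_distribution(
    symbol: str, n: int, merge_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Isotopologue distribution of n atoms of one element, by squaring."""
    iso = ISOTOPE_TABLE[symbol].isotopes
    base_m = np.array([m for m, _ in iso])
    base_a = np.array([a for _, a in iso])
    result_m, result_a = np.array([0.0]), np.array([1.0])
    while n > 0:
        if n & 1:
            result_m, result_a = _convolve_raw(result_m, result_a, base_m, base_a, merge_tol)
        n >>= 1
        if n:
            base_m, base_a = _convolve_raw(base_m, base_a, base_m, base_a, merge_tol)
    return result_m, result_a


def isotope_pattern(
    f: MolecularFormula,
    abundance_floor: float = 1e-5,
    merge_tol: float = 1e-3,
) -> IsotopePattern:
    """Aggregated isotope pattern of a formula by multinomial convolution.

    Parameters
    ----------
    f : MolecularFormula
        Species, including any deuterium label and its charge.
    abundance_floor : float
        Relative abundance below which centroids are dropped (after
        normalization); must lie in (0, 0.01].
    merge_tol : float
        Centroids closer than this (in Da) are merged by abundance-weighted
        mean.  The default 1e-3 Da is far below ESI-TOF peak spacing, so
        isobaric isotopologues (e.g. 13C vs 2H substitutions) are centroided
        together as the instrument would record them.
    """
    if not (0 < abundance_floor <= 0.01):
        raise ValueError("abundance_floor must be in (0, 0.01]")
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    # Intermediate products are merged only at a negligible tolerance (pure
    # dedup of isobaric exact masses), never pruned; the user-level merge_tol
    # is applied once, globally, at the end.  A single global merge makes the
    # grouping independent of element convolution order, so the result agrees
    # with exhaustive isotopologue enumeration peak for peak.  The exact-mass
    # state space of small-molecule formulas is a few thousand entries at
    # most, so skipping intermediate pruning costs nothing.
    raw_tol = min(merge_tol, 1e-9)
    mass, ab = np.array([0.0]), np.array([1.0])
    for sym, n in sorted(f.counts.items()):
        em, ea = _element_distribution(sym, n, raw_tol)
        mass, ab = _convolve_raw(mass, ab, em, ea, raw_tol)
    mass, ab = _merge_centroids(mass, ab, merge_tol)
    ab = ab / ab.sum()
    keep = ab >= abundance_floor
    mass, ab = mass[keep], ab[keep]
    ab = ab / ab.sum()
    if f.charge != 0:
        mass = (mass - f.charge * ELECTRON_MASS) / abs(f.charge)
    return IsotopePattern(mass, ab)


def convolve(a: IsotopePattern, b: IsotopePattern, merge_tol: float = 1e-3) -> IsotopePattern:
    """Convolve two normalized patterns: pairwise mass sums, abundance products."""
    if not (a.normalized and b.normalized):
        raise ValueError("convolve requires normalized patterns")
    mass, ab = _convolve_raw(a.mz, a.abundance, b.mz, b.abundance, merge_tol)
    ab = ab / ab.sum()
    return IsotopePattern(mass, ab)
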