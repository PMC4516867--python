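"""Decomposition of an observed isotopic envelope into light/heavy fractions.

The isotope-dilution readout is the molar ratio of unlabeled analyte (light)
to deuterated internal standard (heavy) in one mass spectrum.  Because the
heavy species sits only ~2 Da above the light one, their envelopes overlap:
the light M+2 centroid coincides with the heavy monoisotopic centroid.  A
naive two-peak intensity ratio is therefore biased; instead the observed
envelope is decomposed over full theoretical basis envelopes by non-negative
least squares (NNLS), which accounts for the shared centroids exactly and
reduces to the classical overlap-correction ratio in the two-species,
complete-labeling case.

The heavy basis column is itself a mixture: the standard's deuteration may be
incomplete, so its envelope is the label-state-probability-weighted sum of
the envelopes of each labeled species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .hdx import LabelStateDistribution, labeled_formula
from .isotopes import IsotopePattern, MolecularFormula, isotope_pattern

__all__ = [
    "EnvelopeBasis",
    "FractionEstimate",
    "CollinearBasisError",
    "mixture_pattern",
    "build_basis",
    "match_envelope",
    "estimate_fractions",
    "ratio_and_amount",
    "EnvelopeMixture",
]

#: Condition-number threshold on the 2×2 normal matrix above which the two
#: basis columns are declared collinear (hard failure beats silent nonsense).
COLLINEARITY_CONDITION = 1e8

#: Default peak-matching tolerance: ~30 ppm at m/z 325, generous for TOF
#: centroids yet far below the 1-Da isotopic spacing.
DEFAULT_MZ_TOL = 0.01

#: Default basis-grid merge tolerance in Da.  Centroids of different species
#: that an ESI-TOF cannot separate — notably the light M+2 cluster at ~6 mDa
#: below the heavy monoisotopic peak — must share one grid position for the
#: overlap correction to work; 0.02 Da is about twice the FWHM at m/z 325
#: for resolving power 30,000 while staying far below the 1-Da spacing.
DEFAULT_GRID_TOL = 0.02


class CollinearBasisError(ValueError):
    """Light and heavy basis envelopes are numerically indistinguishable."""


@dataclass
class EnvelopeBasis:
    """Reference m/z grid plus per-species abundance columns on that grid."""

    mz_grid: np.ndarray
    light: np.ndarray
    heavy: np.ndarray

    def __post_init__(self) -> None:
        self.mz_grid = np.asarray(self.mz_grid, dtype=float)
        self.light = np.asarray(self.light, dtype=float)
        self.heavy = np.asarray(self.heavy, dtype=float)
        if not (self.mz_grid.shape == self.light.shape == self.heavy.shape):
            raise ValueError("grid and columns must share shape")
        if np.any(np.diff(self.mz_grid) <= 0):
            raise ValueError("mz grid must be strictly increasing")
        for col in (self.light, self.heavy):
            if abs(col.sum() - 1.0) > 1e-9:
                raise ValueError("basis columns must each sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.light, self.heavy])


@dataclass
class FractionEstimate:
    """Light/heavy molar fractions plus the unexplained-intensity fraction."""

    light_fraction: float
    heavy_fraction: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.light_fraction < 0 or self.heavy_fraction < 0:
            raise ValueError("fractions must be non-negative")
        if abs(self.light_fraction + self.heavy_fraction - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def ratio(self) -> float:
        """Light:heavy molar ratio."""
        if self.heavy_fraction == 0:
            raise ZeroDivisionError("heavy fraction is zero")
        return self.light_fraction / self.heavy_fraction


def mixture_pattern(
    base: MolecularFormula,
    states: LabelStateDistribution,
    abundance_floor: float = 1e-5,
    merge_tol: float = 1e-3,
) -> IsotopePattern:
    """State-probability-weighted isotope pattern of a partially labeled species."""
    mz_parts: list[np.ndarray] = []
    ab_parts: list[np.ndarray] = []
    for state, prob in states.items():
        pat = isotope_pattern(labeled_formula(base, state), abundance_floor, merge_tol)
        mz_parts.append(pat.mz)
        ab_parts.append(pat.abundance * prob)
    mz, ab = _merge_weighted(np.concatenate(mz_parts), np.concatenate(ab_parts), merge_tol)
    return IsotopePattern(mz, ab / ab.sum())


def _merge_weighted(mz: np.ndarray, w: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    mz, w = mz[order], w[order]
    out_m, out_w = [mz[0] * w[0]], [w[0]]
    last = mz[0]
    for m, a in zip(mz[1:], w[1:]):
        if m - last <= tol:
            out_m[-1] += m * a
            out_w[-1] += a
        else:
            out_m.append(m * a)
            out_w.append(a)
        last = m
    m_arr = np.array(out_m) / np.maximum(np.array(out_w), 1e-300)
    return m_arr, np.array(out_w)


def build_basis(
    light: MolecularFormula,
    standard_states: LabelStateDistribution,
    merge_tol: float = DEFAULT_GRID_TOL,
    abundance_floor: float = 1e-5,
    pattern_merge_tol: float = 1e-3,
) -> EnvelopeBasis:
    """Theoretical light/heavy basis envelopes on a shared m/z grid.

    The grid is the union of both species' centroids merged at ``merge_tol``
    (the instrument-scale grid tolerance), so centroids the detector cannot
    separate — the light M+2 cluster with the heavy monoisotopic peak —
    share one grid position.  That shared position is exactly the overlap
    the NNLS decomposition corrects for.  ``pattern_merge_tol`` is the finer
    tolerance used when centroiding each theoretical pattern.
    """
    light_pat = isotope_pattern(light, abundance_floor, pattern_merge_tol)
    heavy_pat = mixture_pattern(light, standard_states, abundance_floor, pattern_merge_tol)
    grid, _ = _merge_weighted(
        np.concatenate([light_pat.mz, heavy_pat.mz]),
        np.concatenate([np.ones(len(light_pat)), np.ones(len(heavy_pat))]),
        merge_tol,
    )
    light_col = _project(light_pat, grid, merge_tol)
    heavy_col = _project(heavy_pat, grid, merge_tol)
    return EnvelopeBasis(grid, light_col, heavy_col)


def _project(pat: IsotopePattern, grid: np.ndarray, tol: float) -> np.ndarray:
    col = np.zeros_like(grid)
    idx = np.searchsorted(grid, pat.mz)
    for mz, ab, i in zip(pat.mz, pat.abundance, idx):
        cand = [j for j in (i - 1, i) if 0 <= j < len(grid)]
        j = min(cand, key=lambda j: abs(grid[j] - mz))
        if abs(grid[j] - mz) > tol:
            raise ValueError("pattern centroid missing from grid")
        col[j] += ab
    return col


def match_envelope(
    peaks: Sequence[tuple[float, float]] | np.ndarray,
    basis: EnvelopeBasis,
    mz_tol: float = DEFAULT_MZ_TOL,
) -> tuple[np.ndarray, float]:
    """Bin observed peaks onto the basis grid.

    Each grid centroid takes the summed intensity of observed peaks within
    ``mz_tol``.  Observed peaks inside the envelope's m/z span that match no
    grid centroid are summed into the returned *foreign intensity* — signal
    the two-species model cannot explain (e.g. a co-eluting interferent).

    Returns ``(vector, foreign_intensity)``.  An empty or non-matching peak
    list yields a zero vector.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    vec = np.zeros_like(basis.mz_grid)
    foreign = 0.0
    arr = np.asarray(peaks, dtype=float).reshape(-1, 2) if len(peaks) else np.empty((0, 2))
    lo = basis.mz_grid[0] - 1.5
    hi = basis.mz_grid[-1] + 1.5
    for mz, inten in arr:
        i = np.searchsorted(basis.mz_grid, mz)
        cand = [j for j in (i - 1, i) if 0 <= j < len(basis.mz_grid)]
        j = min(cand, key=lambda j: abs(basis.mz_grid[j] - mz))
        if abs(basis.mz_grid[j] - mz) <= mz_tol:
            vec[j] += inten
        elif lo <= mz <= hi:
            foreign += inten
    return vec, float(foreign)


def estimate_fractions(observed: np.ndarray, basis: EnvelopeBasis) -> FractionEstimate:
    """Non-negative least-squares decomposition of an observed envelope.

    Solves ``observed ≈ a·light + b·heavy`` with ``a, b ≥ 0`` and reports the
    normalized fractions ``a/(a+b)``, ``b/(a+b)`` together with the L1
    residual as a fraction of total observed intensity.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != basis.mz_grid.shape:
        raise ValueError("observed vector must match the basis grid")
    if np.any(obs < 0):
        raise ValueError("observed intensities must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ValueError("observed vector is all zero — no signal to decompose")
    A = basis.matrix
    gram = A.T @ A
    if np.linalg.cond(gram) > COLLINEARITY_CONDITION:
        raise CollinearBasisError(
            "light and heavy envelopes are collinear; fractions are unidentifiable"
        )
    coef, _ = nnls(A, obs)
    a, b = coef
    if a + b == 0:
        raise ValueError("NNLS returned a null solution")
    resid = obs - A @ coef
    return FractionEstimate(
        light_fraction=a / (a + b),
        heavy_fraction=b / (a + b),
        residual_norm=float(np.abs(resid).sum() / total),
    )


def ratio_and_amount(est: FractionEstimate, standard_amount_pmol: float) -> float:
    """Isotope-dilution readout: analyte amount from the light/heavy ratio.

    ``amount = standard × light_fraction / heavy_fraction``.  Zero heavy
    fraction means the spiked standard was not detected and the ratio is
    undefined.
    """
    if est.heavy_fraction <= 0:
        raise ValueError("no internal standard detected (heavy fraction is zero)")
    return standard_amount_pmol * est.light_fraction / est.heavy_fraction


class EnvelopeMixture(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from observed peak lists to mixture fractions.

    ``fit`` builds the theoretical light/heavy basis from the analyte formula
    and the standard's label-state distribution; ``transform`` maps each
    observed centroid peak list to ``(light_fraction, heavy_fraction,
    residual_norm)``.

    Parameters
    ----------
    light_formula : MolecularFormula
        Unlabeled analyte ion.
    standard_states : LabelStateDistribution
        Deuteration-state distribution of the internal standard.
    grid_tol : float
        Instrument-scale merge tolerance for the shared basis grid (Da).
    pattern_merge_tol, abundance_floor : float
        Theoretical-envelope construction parameters
        (see :func:`~bitterquant.isotopes.isotope_pattern`).
    mz_tol : float
        Peak-to-grid matching tolerance in Da.
    """

    def __init__(
        self,
        light_formula: MolecularFormula | None = None,
        standard_states: LabelStateDistribution | None = None,
        grid_tol: float = DEFAULT_GRID_TOL,
        pattern_merge_tol: float = 1e-3,
        abundance_floor: float = 1e-5,
        mz_tol: float = DEFAULT_MZ_TOL,
    ):
        self.light_formula = light_formula
        self.standard_states = standard_states
        self.grid_tol = grid_tol
        self.pattern_merge_tol = pattern_merge_tol
        self.abundance_floor = abundance_floor
        self.mz_tol = mz_tol

    def fit(self, X=None, y=None):
        if self.light_formula is None or self.standard_states is None:
            raise ValueError("light_formula and standard_states are required")
        self.basis_ = build_basis(
            self.light_formula,
            self.standard_states,
            self.grid_tol,
            self.abundance_floor,
            self.pattern_merge_tol,
        )
        return self

    def transform(self, X) -> np.ndarray:
        out = np.empty((len(X), 3))
        for i, peaks in enumerate(X):
            vec, _ = match_envelope(peaks, self.basis_, self.mz_tol)
            est = estimate_fractions(vec, self.basis_)
            out[i] = (est.light_fraction, est.heavy_fraction, est.residual_norm)
        return out
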