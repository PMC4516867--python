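"""Isotope-dilution quantification: amounts, calibration, LOD, prep arithmetic.

The analyte amount in a run follows from the deconvolved light/heavy molar
ratio and the known spike of the internal standard — the classical isotope
dilution readout, insensitive to injection volume and ionization efficiency
because both species share them.  A calibration series then establishes
linearity of the response (light/heavy area ratio) against amount, and the
limit of detection is estimated ICH-style from the calibration residuals as
``3.3 · s / slope``.

Gravimetric unit conversion uses the *average* molecular weight of the
benzoate salt (C28H34N2O3, MW ≈ 446.58 g/mol), the convention for weighed
amounts; 0.68 ng of the salt is 1.52 pmol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import chrom
from .deconv import (
    EnvelopeBasis,
    estimate_fractions,
    match_envelope,
    ratio_and_amount,
)
from .isotopes import MolecularFormula, average_mass, parse_formula
from .synthgen import CentroidRun

__all__ = [
    "DENATONIUM_BENZOATE",
    "PrepScheme",
    "CalibrationResult",
    "QuantResult",
    "ng_to_pmol",
    "pmol_to_ng",
    "prep_amounts",
    "fit_calibration",
    "estimate_lod",
    "quantify_run",
    "CalibrationCurve",
]

#: Denatonium benzoate salt (the weighed form of the analyte).
DENATONIUM_BENZOATE = parse_formula("C28H34N2O3")


@dataclass(frozen=True)
class PrepScheme:
    """Volumetric sample-preparation chain for a liquid sample.

    A measured ``sample_volume_uL`` of the raw liquid is evaporated and the
    residue reconstituted in ``reconstitution_volume_uL`` of water; a
    ``aliquot_uL`` portion is diluted with ``diluent_uL`` of water and spiked
    with ``standard_volume_uL`` of the deuterated-standard solution at
    ``standard_conc_mg_per_mL``; ``injection_volume_uL`` of the final vial
    goes on column.
    """

    sample_volume_uL: float
    reconstitution_volume_uL: float = 200.0
    aliquot_uL: float = 20.0
    diluent_uL: float = 123.0
    standard_volume_uL: float = 2.0
    standard_conc_mg_per_mL: float = 0.5
    injection_volume_uL: float = 5.0

    def __post_init__(self) -> None:
        vols = (
            self.sample_volume_uL,
            self.reconstitution_volume_uL,
            self.aliquot_uL,
            self.diluent_uL,
            self.standard_volume_uL,
            self.standard_conc_mg_per_mL,
            self.injection_volume_uL,
        )
        if any(v <= 0 for v in vols):
            raise ValueError("all prep volumes and concentrations must be positive")
        if self.aliquot_uL > self.reconstitution_volume_uL:
            raise ValueError("aliquot cannot exceed the reconstitution volume")

    @property
    def vial_volume_uL(self) -> float:
        return self.aliquot_uL + self.diluent_uL + self.standard_volume_uL

    @property
    def standard_ng_in_vial(self) -> float:
        return self.standard_volume_uL * self.standard_conc_mg_per_mL * 1e6 / 1e3


@dataclass
class CalibrationResult:
    """Linear concentration–response fit plus the detection limit."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    lod_ng: float
    lod_pmol: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R² must lie in [0, 1]")


@dataclass
class QuantResult:
    """End product of one quantified run, with stage intermediates logged."""

    light_fraction: float
    heavy_fraction: float
    residual_norm: float
    ratio: float
    analyte_pmol: float
    analyte_ng: float
    peak: chrom.PeakRegion
    foreign_intensity: float
    sample_conc_ug_per_mL: float | None = None
    non_detect: bool = False


def ng_to_pmol(mass_ng: float, f: MolecularFormula = DENATONIUM_BENZOATE) -> float:
    """Convert a gravimetric amount to pmol via the average molecular weight."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng / average_mass(f) * 1000.0


def pmol_to_ng(amount_pmol: float, f: MolecularFormula = DENATONIUM_BENZOATE) -> float:
    if amount_pmol < 0:
        raise ValueError("amount must be non-negative")
    return amount_pmol * average_mass(f) / 1000.0


def prep_amounts(
    scheme: PrepScheme, analyte_conc_ug_per_mL: float
) -> tuple[float, float]:
    """On-column analyte and standard masses (ng) for a given sample concentration.

    Evaporation carries all analyte from the sampled volume into the
    reconstitution volume; the aliquot/dilution/spike chain then sets the
    vial concentrations, and the injected fraction of the vial goes on
    column.
    """
    if analyte_conc_ug_per_mL < 0:
        raise ValueError("concentration must be non-negative")
    analyte_ng_sampled = analyte_conc_ug_per_mL * scheme.sample_volume_uL  # µg/mL × µL = ng
    analyte_ng_vial = analyte_ng_sampled * scheme.aliquot_uL / scheme.reconstitution_volume_uL
    inj_frac = scheme.injection_volume_uL / scheme.vial_volume_uL
    return analyte_ng_vial * inj_frac, scheme.standard_ng_in_vial * inj_frac


class CalibrationCurve(RegressorMixin, BaseEstimator):
    """Ordinary least-squares concentration–response line, sklearn-style.

    ``fit(amounts, responses)`` estimates slope and intercept; fitted
    attributes expose R² (squared Pearson correlation), the residual
    standard deviation ``sqrt(SSR / (n − 2))`` and the ICH-style detection
    limit ``3.3 · residual_sd / slope`` in both ng and pmol of the salt.

    Parameters
    ----------
    salt_formula : MolecularFormula
        Weighed form of the analyte for the ng ↔ pmol conversion.
    """

    def __init__(self, salt_formula: MolecularFormula = DENATONIUM_BENZOATE):
        self.salt_formula = salt_formula

    def fit(self, X, y=None):
        amounts = np.asarray(X, dtype=float).ravel()
        responses = np.asarray(y, dtype=float).ravel()
        if amounts.size != responses.size:
            raise ValueError("amounts and responses must have equal length")
        if amounts.size < 3:
            raise ValueError("at least 3 calibration points required")
        if len(np.unique(amounts)) < 2:
            raise ValueError("calibration design is rank-deficient (one distinct amount)")
        res = stats.linregress(amounts, responses)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        # guard: constant responses give a NaN correlation; rounding can push
        # r² epsilon-past 1 for near-perfect fits
        r2 = float(res.rvalue**2)
        self.r_squared_ = 0.0 if math.isnan(r2) else min(max(r2, 0.0), 1.0)
        fitted = self.slope_ * amounts + self.intercept_
        ssr = float(np.sum((responses - fitted) ** 2))
        self.residual_sd_ = math.sqrt(ssr / (amounts.size - 2))
        if self.slope_ > 0:
            self.lod_ng_ = 3.3 * self.residual_sd_ / self.slope_
            self.lod_pmol_ = ng_to_pmol(self.lod_ng_, self.salt_formula)
        else:
            self.lod_ng_ = math.nan
            self.lod_pmol_ = math.nan
        self.n_points_ = int(amounts.size)
        return self

    def predict(self, X):
        amounts = np.asarray(X, dtype=float).ravel()
        return self.slope_ * amounts + self.intercept_

    def result(self) -> CalibrationResult:
        return CalibrationResult(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            residual_sd=self.residual_sd_,
            lod_ng=self.lod_ng_,
            lod_pmol=self.lod_pmol_,
            n_points=self.n_points_,
        )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    salt_formula: MolecularFormula = DENATONIUM_BENZOATE,
) -> CalibrationResult:
    """OLS line through (amount_ng, response) points, with R², residual sd, LOD."""
    amounts = [p[0] for p in points]
    responses = [p[1] for p in points]
    return CalibrationCurve(salt_formula).fit(amounts, responses).result()


def estimate_lod(
    cal: CalibrationResult, salt_formula: MolecularFormula = DENATONIUM_BENZOATE
) -> tuple[float, float]:
    """Detection limit ``3.3 · residual_sd / slope`` in ng, and in pmol of the salt.

    A zero residual sd signals a noise floor below what the data can
    resolve; the LOD is then reported as 0 rather than a spurious positive
    number.
    """
    if cal.slope <= 0:
        raise ValueError("LOD requires a positive calibration slope")
    lod_ng = 3.3 * cal.residual_sd / cal.slope
    return lod_ng, ng_to_pmol(lod_ng, salt_formula)


def quantify_run(
    run: CentroidRun,
    basis: EnvelopeBasis,
    standard_pmol: float,
    scheme: PrepScheme | None = None,
    salt_formula: MolecularFormula = DENATONIUM_BENZOATE,
    mz_tol: float | None = None,
    min_snr: float = 3.0,
) -> QuantResult:
    """Quantify one run end to end.

    Stages: locate the chromatographic peak on the summed light+heavy trace,
    sum the spectra across the peak region, bin onto the basis grid,
    NNLS-decompose into light/heavy fractions, convert the molar ratio to an
    analyte amount via the standard spike, and (when a prep scheme is given)
    back-calculate the concentration in the original liquid sample.
    """
    from .deconv import DEFAULT_MZ_TOL

    tol = DEFAULT_MZ_TOL if mz_tol is None else mz_tol
    mono_light = basis.mz_grid[np.argmax(basis.light)]
    mono_heavy = basis.mz_grid[np.argmax(basis.heavy)]
    span = abs(mono_heavy - mono_light) + 3.0
    center = 0.5 * (mono_light + mono_heavy)
    try:
        tic = chrom.extract_xic(run, center, span)
        region = chrom.find_peak(tic, min_snr)
    except chrom.NoPeakError:
        empty = chrom.PeakRegion(run.scans[0].rt_min, run.scans[0].rt_min,
                                 run.scans[0].rt_min, 0.0, 0, 0, 0)
        return QuantResult(0.0, 1.0, 0.0, 0.0, 0.0, 0.0, empty, 0.0,
                           0.0 if scheme else None, non_detect=True)
    mz_all, in_all = [], []
    for i in range(region.start_index, region.end_index + 1):
        mz_all.append(run.scans[i].mz)
        in_all.append(run.scans[i].intensity)
    peaks = np.column_stack([np.concatenate(mz_all), np.concatenate(in_all)])
    vec, foreign = match_envelope(peaks, basis, tol)
    est = estimate_fractions(vec, basis)
    if est.heavy_fraction <= 0:
        raise ValueError("quantification stage 'ratio': no internal standard detected")
    amount_pmol = ratio_and_amount(est, standard_pmol)
    amount_ng = pmol_to_ng(amount_pmol, salt_formula)
    conc = None
    if scheme is not None:
        # invert prep_amounts: on-column analyte ng -> sample concentration
        inj_frac = scheme.injection_volume_uL / scheme.vial_volume_uL
        vial_ng = amount_ng / inj_frac
        sampled_ng = vial_ng * scheme.reconstitution_volume_uL / scheme.aliquot_uL
        conc = sampled_ng / scheme.sample_volume_uL  # ng/µL == µg/mL
    return QuantResult(
        light_fraction=est.light_fraction,
        heavy_fraction=est.heavy_fraction,
        residual_norm=est.residual_norm,
        ratio=est.light_fraction / est.heavy_fraction,
        analyte_pmol=amount_pmol,
        analyte_ng=amount_ng,
        peak=region,
        foreign_intensity=foreign,
        sample_conc_ug_per_mL=conc,
    )
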