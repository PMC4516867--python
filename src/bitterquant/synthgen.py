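"""Seeded synthetic centroid LC-MS runs of co-eluting isotopologue pairs.

Emulates the measurement situation of the isotope-dilution experiment on a
standard ESI-TOF instrument: an unlabeled analyte and its α-dideuterated
internal standard co-elute exactly (they share one Gaussian chromatographic
profile), their isotopic envelopes sit ~2 Da apart and overlap at the light
M+2 / heavy M+0 position, intensities carry multiplicative lognormal noise,
and a constant-level random baseline can be added.

Not emulated: matrix interferents beyond the flat baseline, in-source
fragmentation, detector saturation, and profile-mode peak shapes — the
pipeline consumes centroids, so only centroids are synthesized.

All randomness flows from ``AcquisitionModel.seed``: the same seed yields a
bit-identical run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .deconv import mixture_pattern
from .hdx import LabelStateDistribution
from .isotopes import IsotopePattern, MolecularFormula, isotope_pattern

__all__ = [
    "AcquisitionModel",
    "Scan",
    "CentroidRun",
    "render_spectrum",
    "simulate_run",
    "simulate_calibration_series",
    "superpose_runs",
]

#: Default analyte: the denatonium cation, C21H29N2O+.
DEFAULT_RT_APEX_MIN = 18.83
DEFAULT_RT_SIGMA_MIN = 0.05


@dataclass(frozen=True)
class AcquisitionModel:
    """ESI-TOF-like acquisition parameters for the generator.

    ``rt_start_min`` anchors the simulated window so a realistic apex
    retention time (18.83 min by default) does not force simulating the
    whole gradient; scans cover ``[rt_start, rt_start + rt_window]``.
    """

    resolving_power: float = 30_000.0
    scan_interval_s: float = 1.0
    rt_start_min: float = 18.0
    rt_window_min: float = 1.6
    noise_cv: float = 0.0
    baseline_level: float = 0.0
    n_baseline_peaks: int = 20
    mz_range: tuple[float, float] = (300.0, 360.0)
    intensity_per_pmol: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.resolving_power, self.scan_interval_s, self.rt_window_min) <= 0:
            raise ValueError("resolving power, scan interval and rt window must be positive")
        if self.noise_cv < 0 or self.baseline_level < 0:
            raise ValueError("noise_cv and baseline_level must be non-negative")
        if self.intensity_per_pmol <= 0:
            raise ValueError("intensity_per_pmol must be positive")

    @property
    def scan_times_min(self) -> np.ndarray:
        dt = self.scan_interval_s / 60.0
        n = int(np.floor(self.rt_window_min / dt)) + 1
        return self.rt_start_min + dt * np.arange(n)


@dataclass
class Scan:
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class CentroidRun:
    """Ordered centroid scans; retention times strictly increasing."""

    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")
        for s in self.scans:
            if np.any(s.intensity < 0):
                raise ValueError("negative intensity")

    def __len__(self) -> int:
        return len(self.scans)

    def rt_minutes(self) -> np.ndarray:
        return np.array([s.rt_min for s in self.scans])


def _merge_fwhm(mz: np.ndarray, inten: np.ndarray, resolving_power: float):
    """Merge centroids closer than one FWHM, intensity-weighted."""
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_m: list[float] = []
    out_i: list[float] = []
    for m, a in zip(mz, inten):
        if out_m and m - out_m[-1] / max(out_i[-1], 1e-300) <= m / resolving_power:
            out_m[-1] += m * a
            out_i[-1] += a
        else:
            out_m.append(m * a)
            out_i.append(a)
    m_arr = np.array(out_m) / np.maximum(np.array(out_i), 1e-300)
    return m_arr, np.array(out_i)


def render_spectrum(
    components: Sequence[tuple[IsotopePattern, float]],
    model: AcquisitionModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One centroid spectrum: weighted superposition of patterns plus noise.

    Each component's abundances are scaled by its weight (already in
    intensity units); centroids closer than one FWHM (mz / resolving_power)
    are merged intensity-weighted; every surviving intensity is multiplied by
    unit-mean lognormal noise with coefficient of variation ``noise_cv``; a
    flat random baseline is appended when ``baseline_level > 0``.
    """
    if not components:
        raise ValueError("empty component list")
    mz_parts, in_parts = [], []
    for pat, weight in components:
        if weight < 0:
            raise ValueError("negative component weight")
        if weight > 0:
            mz_parts.append(pat.mz)
            in_parts.append(pat.abundance * weight)
    if not mz_parts:
        return np.empty(0), np.empty(0)
    mz, inten = _merge_fwhm(np.concatenate(mz_parts), np.concatenate(in_parts), model.resolving_power)
    if model.noise_cv > 0:
        sigma = np.sqrt(np.log1p(model.noise_cv**2))
        inten = inten * rng.lognormal(-0.5 * sigma**2, sigma, size=inten.shape)
    if model.baseline_level > 0 and model.n_baseline_peaks > 0:
        b_mz = rng.uniform(*model.mz_range, size=model.n_baseline_peaks)
        b_in = rng.exponential(model.baseline_level, size=model.n_baseline_peaks)
        mz = np.concatenate([mz, b_mz])
        inten = np.concatenate([inten, b_in])
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    return mz, inten


def simulate_run(
    analyte_pmol: float,
    standard_pmol: float,
    standard_states: LabelStateDistribution,
    analyte_formula: MolecularFormula,
    model: AcquisitionModel,
    rt_apex_min: float = DEFAULT_RT_APEX_MIN,
    rt_sigma_min: float = DEFAULT_RT_SIGMA_MIN,
    rt_shift_heavy_scans: float = 0.0,
) -> CentroidRun:
    """Simulate one LC-MS run of analyte plus internal standard.

    Both isotopologues ride the same Gaussian elution profile (apex and width
    shared exactly — the co-elution assumption the real chemistry justifies,
    since the deuterons sit at the α carbon next to the charged center).
    Per-scan component weights are ``amount × intensity_per_pmol × g(rt)``
    with ``g`` the unit-apex Gaussian.  ``rt_shift_heavy_scans`` deliberately
    breaks co-elution (for testing purity diagnostics) by shifting the heavy
    profile by that many scan intervals.

    Deterministic for a given ``model.seed``.
    """
    if analyte_pmol < 0 or standard_pmol < 0:
        raise ValueError("amounts must be non-negative")
    times = model.scan_times_min
    if not (times[0] <= rt_apex_min <= times[-1]):
        raise ValueError("rt_apex must lie inside the acquisition window")
    rng = np.random.default_rng(model.seed)
    light_pat = isotope_pattern(analyte_formula)
    heavy_pat = mixture_pattern(analyte_formula, standard_states)
    shift_min = rt_shift_heavy_scans * model.scan_interval_s / 60.0
    scans: list[Scan] = []
    for rt in times:
        g_light = np.exp(-0.5 * ((rt - rt_apex_min) / rt_sigma_min) ** 2)
        g_heavy = np.exp(-0.5 * ((rt - rt_apex_min - shift_min) / rt_sigma_min) ** 2)
        w_light = analyte_pmol * model.intensity_per_pmol * g_light
        w_heavy = standard_pmol * model.intensity_per_pmol * g_heavy
        mz, inten = render_spectrum([(light_pat, w_light), (heavy_pat, w_heavy)], model, rng)
        scans.append(Scan(rt, mz, inten))
    return CentroidRun(scans)


def simulate_calibration_series(
    amounts_pmol: Sequence[float],
    standard_pmol: float,
    standard_states: LabelStateDistribution,
    analyte_formula: MolecularFormula,
    model: AcquisitionModel,
    rt_apex_min: float = DEFAULT_RT_APEX_MIN,
    rt_sigma_min: float = DEFAULT_RT_SIGMA_MIN,
) -> list[CentroidRun]:
    """One run per analyte amount, shared standard spike, distinct child seeds."""
    if len(amounts_pmol) == 0:
        raise ValueError("empty amount list")
    children = np.random.SeedSequence(model.seed).spawn(len(amounts_pmol))
    runs = []
    for amount, child in zip(amounts_pmol, children):
        m = replace(model, seed=int(child.generate_state(1)[0] % (2**31)))
        runs.append(
            simulate_run(
                amount, standard_pmol, standard_states, analyte_formula, m,
                rt_apex_min, rt_sigma_min,
            )
        )
    return runs


def superpose_runs(a: CentroidRun, b: CentroidRun) -> CentroidRun:
    """Scan-wise superposition of two runs acquired on the same time grid."""
    if len(a) != len(b):
        raise ValueError("runs must have the same number of scans")
    scans = []
    for sa, sb in zip(a.scans, b.scans):
        if abs(sa.rt_min - sb.rt_min) > 1e-9:
            raise ValueError("runs must share scan times")
        mz = np.concatenate([sa.mz, sb.mz])
        inten = np.concatenate([sa.intensity, sb.intensity])
        order = np.argsort(mz, kind="stable")
        scans.append(Scan(sa.rt_min, mz[order], inten[order]))
    return CentroidRun(scans)
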