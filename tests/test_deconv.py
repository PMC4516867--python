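"""Envelope deconvolution: basis construction, NNLS fractions, overlap handling."""

import numpy as np
import pytest

from bitterquant.deconv import (
    CollinearBasisError,
    EnvelopeMixture,
    FractionEstimate,
    build_basis,
    estimate_fractions,
    match_envelope,
    mixture_pattern,
    ratio_and_amount,
)
from bitterquant.hdx import LabelState, LabelStateDistribution, state_distribution
from bitterquant.isotopes import isotope_pattern
from bitterquant.synthgen import AcquisitionModel, render_spectrum


@pytest.fixture(scope="module")
def basis(denatonium, full_label):
    return build_basis(denatonium, full_label)


@pytest.fixture(scope="module")
def patterns(denatonium, full_label):
    return isotope_pattern(denatonium), mixture_pattern(denatonium, full_label)


def _observed(patterns, basis, w_light, w_heavy, noise_cv=0.0, seed=0):
    """Render a spectrum at given weights and bin it onto the basis grid."""
    lp, hp = patterns
    model = AcquisitionModel(noise_cv=noise_cv, seed=seed)
    rng = np.random.default_rng(seed)
    mz, inten = render_spectrum([(lp, w_light), (hp, w_heavy)], model, rng)
    vec, foreign = match_envelope(np.column_stack([mz, inten]), basis)
    return vec, foreign


class TestBuildBasis:
    def test_columns_normalized_and_grid_increasing(self, basis):
        assert basis.light.sum() == pytest.approx(1.0, abs=1e-9)
        assert basis.heavy.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(basis.mz_grid) > 0)

    def test_fully_labeled_heavy_column_is_d2_pattern(self, denatonium, full_label, basis):
        from bitterquant.hdx import labeled_formula

        d2 = isotope_pattern(labeled_formula(denatonium, LabelState(2, False)))
        # heavy column starts at the d2 monoisotopic grid slot
        j = int(np.argmax(basis.heavy > 0))
        assert abs(basis.mz_grid[j] - d2.mz[0]) < 0.02
        assert basis.heavy[j] == pytest.approx(d2.abundance[0], abs=1e-6)

    def test_shared_overlap_slot(self, denatonium, full_label, basis):
        """Light M+2 and heavy M+0 occupy the same grid position."""
        overlap = basis.mz_grid[(basis.light > 1e-4) & (basis.heavy > 0.5)]
        assert len(overlap) == 1

    def test_partial_labeling_mixes_three_patterns(self, denatonium):
        states = state_distribution(0.95)
        hp = mixture_pattern(denatonium, states)
        mono_d0 = isotope_pattern(denatonium).mz[0]
        # d0 contamination appears at the light monoisotopic position
        assert np.any(np.abs(hp.mz - mono_d0) < 0.01)
        assert hp.abundance[np.argmin(np.abs(hp.mz - mono_d0))] == pytest.approx(
            0.05**2 * isotope_pattern(denatonium).abundance[0], rel=1e-6
        )

    def test_unlabeled_standard_is_collinear(self, denatonium, basis):
        degenerate = LabelStateDistribution.pure(LabelState(0, False))
        b = build_basis(denatonium, degenerate)
        with pytest.raises(CollinearBasisError):
            estimate_fractions(b.light * 100.0, b)


class TestMatchEnvelope:
    def test_noiseless_light_spectrum_matches_light_column(self, patterns, basis):
        vec, foreign = _observed(patterns, basis, 1.0, 0.0)
        assert foreign == 0.0
        np.testing.assert_allclose(vec / vec.sum(), basis.light, atol=1e-6)

    def test_foreign_peak_reported_not_matched(self, basis):
        peaks = [(basis.mz_grid[0], 100.0), (basis.mz_grid[0] + 5.0, 7.0)]
        vec, foreign = match_envelope(peaks, basis)
        assert vec.sum() == pytest.approx(100.0)
        assert foreign == pytest.approx(7.0)

    def test_all_outside_tolerance_gives_zero_vector(self, basis):
        vec, foreign = match_envelope([(basis.mz_grid[0] + 0.5, 50.0)], basis)
        assert vec.sum() == 0.0
        assert foreign == pytest.approx(50.0)

    def test_invalid_tolerance_rejected(self, basis):
        with pytest.raises(ValueError):
            match_envelope([(325.0, 1.0)], basis, mz_tol=0.0)


class TestEstimateFractions:
    @pytest.mark.parametrize(
        "weights, expected",
        [((1.0, 1.0), 0.5), ((2.0, 1.0), 2.0 / 3.0), ((1.0, 2.0), 1.0 / 3.0)],
    )
    def test_noiseless_mixture_recovery(self, patterns, basis, weights, expected):
        vec, _ = _observed(patterns, basis, *weights)
        est = estimate_fractions(vec, basis)
        assert est.light_fraction == pytest.approx(expected, abs=1e-9)
        assert est.light_fraction + est.heavy_fraction == pytest.approx(1.0, abs=1e-12)

    def test_pure_heavy_gives_zero_light(self, patterns, basis):
        vec, _ = _observed(patterns, basis, 0.0, 1.0)
        est = estimate_fractions(vec, basis)
        assert est.light_fraction == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_vector_rejected(self, basis):
        with pytest.raises(ValueError):
            estimate_fractions(np.zeros_like(basis.mz_grid), basis)

    def test_sweep_of_mixing_ratios_noiseless(self, patterns, basis):
        """Round trip over the whole usable fraction range at zero noise."""
        for frac in np.linspace(0.01, 0.99, 15):
            vec, _ = _observed(patterns, basis, frac, 1.0 - frac)
            est = estimate_fractions(vec, basis)
            assert est.light_fraction == pytest.approx(frac, abs=1e-6)

    def test_matches_exhaustive_grid_search(self, patterns, basis):
        """NNLS agrees with a brute-force scan over fractions (step 1e-4)."""
        rng = np.random.default_rng(2024)
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        A_light, A_heavy = basis.light, basis.heavy
        for _ in range(20):
            frac = rng.uniform(0.05, 0.95)
            vec, _ = _observed(patterns, basis, frac, 1 - frac, noise_cv=0.02, seed=rng.integers(2**31))
            # best least-squares scale for each candidate fraction, vectorized
            M = np.outer(grid, A_light) + np.outer(1 - grid, A_heavy)
            scale = (M @ vec) / np.einsum("ij,ij->i", M, M)
            resid = np.linalg.norm(M * scale[:, None] - vec, axis=1)
            brute = grid[np.argmin(resid)]
            est = estimate_fractions(vec, basis)
            assert est.light_fraction == pytest.approx(brute, abs=2e-4)

    def test_noise_robustness_of_fraction_estimates(self, patterns, basis):
        """1% multiplicative noise keeps fraction errors within 0.02 (95th pct)."""
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frac = rng.uniform(0.2, 0.8)
            vec, _ = _observed(patterns, basis, frac, 1 - frac, noise_cv=0.01, seed=seed)
            est = estimate_fractions(vec, basis)
            errors.append(abs(est.light_fraction - frac))
        assert np.quantile(errors, 0.95) <= 0.02

    def test_full_model_beats_naive_two_peak_ratio(self, patterns, basis):
        """Ignoring the shared M+2/M+0 slot biases the estimate; the full
        decomposition must beat the naive monoisotopic-peak ratio."""
        lp, hp = patterns
        vec, _ = _observed(patterns, basis, 1.0, 1.0)
        est = estimate_fractions(vec, basis)
        i_light = np.argmin(np.abs(basis.mz_grid - lp.mz[0]))
        i_heavy = np.argmin(np.abs(basis.mz_grid - hp.mz[0]))
        naive = vec[i_light] / (vec[i_light] + vec[i_heavy])
        bias_full = abs(est.light_fraction - 0.5)
        bias_naive = abs(naive - 0.5)
        assert bias_naive > 0.005  # the overlap really biases the naive ratio
        assert bias_full < bias_naive


class TestRatioAndAmount:
    def test_equimolar(self):
        est = FractionEstimate(0.5, 0.5, 0.0)
        assert ratio_and_amount(est, 10.0) == pytest.approx(10.0)

    def test_two_to_one(self):
        est = FractionEstimate(2 / 3, 1 / 3, 0.0)
        assert ratio_and_amount(est, 3.0) == pytest.approx(6.0)

    def test_blank(self):
        est = FractionEstimate(0.0, 1.0, 0.0)
        assert ratio_and_amount(est, 123.0) == 0.0

    def test_missing_standard_rejected(self):
        est = FractionEstimate(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            ratio_and_amount(est, 10.0)


class TestEnvelopeMixtureEstimator:
    def test_fit_transform_matches_functions(self, denatonium, full_label, patterns):
        est = EnvelopeMixture(denatonium, full_label).fit()
        lp, hp = patterns
        model = AcquisitionModel()
        rng = np.random.default_rng(0)
        spectra = []
        for w in (0.3, 0.5, 0.7):
            mz, inten = render_spectrum([(lp, w), (hp, 1 - w)], model, rng)
            spectra.append(np.column_stack([mz, inten]))
        out = est.transform(spectra)
        assert out.shape == (3, 3)
        np.testing.assert_allclose(out[:, 0], [0.3, 0.5, 0.7], atol=1e-9)

    def test_sklearn_params_round_trip(self, denatonium, full_label):
        est = EnvelopeMixture(denatonium, full_label, mz_tol=0.02)
        params = est.get_params()
        assert params["mz_tol"] == 0.02
        est.set_params(mz_tol=0.005)
        assert est.mz_tol == 0.005
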