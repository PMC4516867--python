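# Methods

`bitterquant` models the quantification of denatonium benzoate (Bitrex) by
isotope-dilution LC-MS with an α-C-dideuterated internal standard. This note
describes the models behind each stage, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was open.

## The measurement principle

Denatonium is a quaternary-ammonium cation (C21H29N2O⁺) carrying a
betaine-derived fragment whose two α-CH₂ protons are acidic enough for
base-catalysed hydrogen–deuterium exchange: incubation in 1 % triethylamine
(TEA) in D₂O converts the analyte into its α-d2 isotopologue, while the
amide N–H exchanges spontaneously with whatever protic solvent it sits in.
Critically, the α-C deuterons are stable in acidic and neutral water, so the
labeled cation survives reversed-phase chromatography, and because the label
sits adjacent to the charged center the two isotopologues co-elute.

Spiking a known amount of the α-d2 standard into a sample and measuring the
light:heavy molar ratio in the shared chromatographic peak gives the analyte
amount directly:

    amount_analyte = amount_standard × (light fraction) / (heavy fraction)

independent of injection volume and ionization efficiency, which the two
isotopologues share.

## Isotope patterns (`isotopes`)

Theoretical envelopes are computed by per-element multinomial convolution:
each element's single-atom isotope distribution is raised to its atom count
by repeated squaring, the per-element distributions are convolved, and the
full product is centroided once, globally, by an abundance-weighted merge of
masses closer than `merge_tol`. Merging only at the end (intermediates are
deduplicated at 1e-9 Da and never pruned) makes the grouping independent of
convolution order, so the result agrees with exhaustive isotopologue
enumeration peak for peak; the exact-mass state space of a small molecule is
a few thousand entries, so this costs nothing.

Parameters:

* `merge_tol` (default 1e-3 Da): far below ESI-TOF peak spacing; produces
  aggregated, instrument-level centroids rather than fine structure.
* `abundance_floor` (default 1e-5): relative abundance below which centroids
  are dropped after normalization.
* Atomic masses and abundances are an embedded IUPAC 2013 table; the
  CODATA electron mass is subtracted once per positive charge, which matters
  at the sub-mDa level for cations. The deuterium label is its own
  pseudo-element `D`, treated as isotopically pure ²H.

Key computed values: m/z 325.2274 (d0), 326.2337 (amide-d1), 327.2400
(α-d2) for the three denatonium cations.

## Deuteration states (`hdx`)

The label state of the standard is `(n_alpha_d, amide_d)` with `n_alpha = 2`
equivalent α sites. Forward exchange under base catalysis is pseudo-first-
order per site, `p(t) = 1 − exp(−k·t)` toward the medium's equilibrium label
(D in TEA/D₂O, H in TEA/H₂O; rate zero without base), and the α-deuteron
count is binomial because the two α-CH₂ hydrogens are chemically equivalent
and no site asymmetry is known. Amide exchange is modelled as instantaneous
and complete in the matching solvent; solvent deuterium fraction is fixed at
1.0 (neat D₂O — deuteration completeness is an experimentally confirmed
property of the labeling chemistry).

No numeric α-C exchange rate is published for denatonium; the default
`rate_k = 0.23 /min` is a modelling choice placing the per-site extent near
0.9 at 10 min and above 0.999 at 60 min, bracketing the qualitative time
course (substantial exchange at 10 min, complete by 60 min). `fit_rate` /
`ExchangeKinetics` recover the rate from an observed mean-deuteron time
course by non-negative nonlinear least squares; an all-zero series is
flagged degenerate rather than fitted.

## Synthetic runs (`synthgen`)

The generator emulates the study conditions on an ESI-TOF-class instrument:

* both isotopologues ride one shared Gaussian elution profile (apex
  18.83 min, σ 0.05 min by default) — co-elution is the generative
  assumption, and `rt_shift_heavy_scans` exists solely to break it for
  testing the diagnostics;
* per-scan component weights are `amount × intensity_per_pmol × g(rt)` with
  a single response factor shared by light and heavy species (equal
  ionization efficiency of isotopologues);
* centroids closer than one FWHM (`mz / resolving_power`, default
  resolving power 30,000 → ~11 mDa at m/z 325) merge intensity-weighted —
  this is what collapses the light M+2 cluster onto the heavy monoisotopic
  peak, the overlap the deconvolution must resolve;
* intensities carry unit-mean multiplicative lognormal noise with
  coefficient of variation `noise_cv`, plus an optional flat random
  baseline (`baseline_level`, exponential intensities at random m/z);
* scans are 1 s apart over a window `[rt_start, rt_start + rt_window]`
  (default 18.0–19.6 min), so the realistic apex time does not force
  simulating a whole gradient;
* all randomness flows from `AcquisitionModel.seed`; a calibration series
  spawns one child seed per level. Same seed ⇒ bit-identical run.

Not emulated: matrix interferents beyond the flat baseline, in-source
fragmentation, detector saturation, retention drift between runs, and
profile-mode peak shapes. Passing tests therefore demonstrate the
correctness of the computational chain under the stated noise model, not
robustness to structured chemical interference — the foreign-intensity
accounting in `match_envelope` is the hook for detecting the latter.

Absolute intensities are arbitrary units (`intensity_per_pmol = 1e4` by
default); only ratios enter the quantification, so the response factor
cancels everywhere except the noise floor.

## Envelope deconvolution (`deconv`)

The observed envelope is decomposed over two theoretical basis columns —
the light pattern and the label-state-weighted heavy mixture — by
non-negative least squares (NNLS). Fractions are normalized after the
solve (`a/(a+b)`, `b/(a+b)`) so the residual stays interpretable; any
overall scale sits in the elution profile. This reduces to the classical
two-peak overlap-correction ratio when exactly two species with complete
labeling are present, and generalizes to partial labeling for free.

Numerical choices:

* basis grid: union of both species' centroids merged at `grid_tol`
  (default 0.02 Da ≈ 2 FWHM at m/z 325) so centroids the detector cannot
  separate — light M+2 with heavy M+0, ~6 mDa apart — share one grid slot;
* peak matching: `mz_tol` 0.01 Da (~30 ppm), generous for TOF centroids yet
  far below the 1-Da isotopic spacing; observed peaks inside the envelope
  span that match nothing are reported as foreign intensity, never silently
  absorbed;
* collinearity: if the 2×2 normal matrix's condition number exceeds 1e8
  (e.g. an unlabeled "standard"), the solve raises rather than returning
  unidentifiable fractions;
* residual: L1 norm as a fraction of total observed intensity.

Per-peak and summed-spectrum estimation are both available; the default
quantification path sums spectra across the detected peak bounds, which
averages scan-level noise before the (nonlinear) ratio is formed. Per-scan
estimates remain the basis of the purity diagnostic.

## Chromatography (`chrom`)

XICs are per-scan summed intensities within ±`tol` of a target m/z. Peak
detection takes the global maximum as apex and walks outward until the trace
falls below `max(baseline + min_snr·noise, 1 % of apex)`, with baseline and
noise estimated robustly from the trace itself (lower quartile, MAD of the
sub-median points); the area is trapezoidal over those bounds. The 1 %
descent floor keeps the area of a Gaussian peak within 1 % of
`amplitude·σ·√(2π)` for σ ≥ 5 scan intervals (a 5 % floor would truncate at
±2.45 σ and lose ~1.4 %); no smoothing is applied by default because the
synthetic traces are clean — smoothing belongs upstream of `find_peak` if
real data need it.

Co-elution is reported as the apex offset between light and heavy XICs in
whole scans (converted to minutes only via the scan interval), deliberately
avoiding sub-scan claims; the default "practically identical" threshold used
in tests is ≤ 1 scan, a choice, since no quantitative criterion is
published. Peak purity is the standard deviation of the per-scan
deconvolved light fraction across the peak: exactly zero for shared-profile
noiseless runs at any mixing ratio, and monotonically increasing with an
imposed retention offset. The dispersion-of-fractions metric was chosen over
a spectral contrast angle because it reuses the deconvolution core and is
directly interpretable as ratio stability.

## Quantification and calibration (`quant`)

`quantify_run` chains: peak detection on the summed light+heavy trace →
spectrum summation over the peak bounds → grid binning → NNLS fractions →
`amount = standard × light/heavy` → optional back-calculation through the
volumetric prep scheme (evaporation of a measured sample volume,
reconstitution in 200 µL, 20 µL aliquot + 123 µL water + 2 µL of 0.5 mg/mL
standard solution = 145 µL vial, of which `injection_volume` goes on
column). The injection volume (default 5 µL, configurable) cancels out of
every ratio-based result; it only scales absolute on-column amounts.

Calibration fits an ordinary least-squares line of the internal-standard-
normalized response (light/heavy envelope ratio) against amount; R² is the
squared Pearson correlation; the residual standard deviation is
`sqrt(SSR/(n−2))`. The limit of detection is ICH-style, `3.3 ·
residual_sd / slope`, reported in ng and — via the *average* molecular
weight of the benzoate salt C28H34N2O3 (446.58 g/mol, the convention for
weighed amounts; 0.68 ng ↔ 1.52 pmol) — in pmol. A residual sd of zero
reports LOD 0, flagging that the simulation's noise floor, not the
estimator, is the limit.

## Default problem sizes

Simulated runs use a 1.6-min window of 1-s scans (97 spectra) around the
18.83-min apex; replicate studies use 100 seeded runs; calibration uses 8
levels geometrically spaced over 0.68–47.5 ng with the standard spike at the
geometric mean of the range. These sizes make every property of interest
(exact noiseless recovery, fraction errors under 1 % noise, calibration
linearity, detection of a 3-scan co-elution offset) measurable while keeping
the full test suite and the acceptance script fast on a single core.

## Known limitations

* Two species classes only (light analyte, heavy standard with a state
  mixture); unrelated co-eluting compounds are flagged as foreign intensity,
  not deconvolved.
* The exchange model is pseudo-first-order with equivalent sites; no
  pH-dependent rate law, no enolization mechanism.
* The noise model is unstructured (i.i.d. lognormal per centroid);
  real matrix effects, drift and saturation are out of scope.
* Elemental-composition inference and fine isotope structure are non-goals;
  the embedded isotope table covers H/D, C, N, O, F, Na, P, S, Cl, K, Br, I.
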