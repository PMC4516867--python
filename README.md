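# bitterquant

Isotope-dilution LC-MS quantification of denatonium (Bitrex) with an
α-C-dideuterated internal standard.

Denatonium benzoate is the intensely bitter aversive agent added to
industrial alcohols, washer fluids and household chemicals; regulations set
minimum levels (e.g. 1 g per 100 dm³ of denatured ethanol), so laboratories
need to quantify it at trace amounts. The denatonium cation
(C21H29N2O⁺, m/z 325.227) carries a permanently charged betaine-derived
fragment whose two α-CH₂ protons undergo base-catalysed H/D exchange in
1 % triethylamine/D₂O — a one-pot route to an α-d2 labeled standard
(m/z 327.240) whose deuterons are stable in acidic and neutral water and
which co-elutes with the unlabeled analyte.

This package implements the computational side of that assay, for analytical
chemists and method developers:

* **theoretical isotopologue envelopes** by per-element multinomial
  convolution, with explicit deuterium and electron-mass-corrected m/z;
* **a deuteration-state model** of the exchange chemistry (binomial α-site
  occupancy, pseudo-first-order kinetics, amide/back-exchange rules);
* **envelope deconvolution**: the light/heavy molar ratio is recovered by
  non-negative least squares over full theoretical envelopes, correcting
  the overlap of the light M+2 cluster with the heavy monoisotopic peak
  (the isotopic-distribution decomposition classically used for
  light/heavy envelope mixtures);
* **chromatographic diagnostics**: XIC extraction, peak detection,
  co-elution offset in scans, and peak purity as the dispersion of the
  per-scan deconvolved light fraction;
* **quantification**: `amount = standard × light/heavy`, volumetric
  sample-prep back-calculation, ordinary least-squares calibration with R²,
  and an ICH-style limit of detection `3.3·s/slope`;
* **a seeded synthetic-run generator** (Gaussian co-elution, ESI-TOF-like
  centroid merging, lognormal noise, flat baseline) so the whole chain is
  testable without instrument data; runs read/write mzML and a simple CSV
  dialect.

The fit-shaped pieces are scikit-learn-style estimators
(`EnvelopeMixture`, `ExchangeKinetics`, `CalibrationCurve`) and compose
with sklearn tooling; module-level functions wrap them for one-call use.

## Worked example

Quantify a synthetic run containing 6.8 ng of denatonium benzoate
(15.23 pmol) against a 10 pmol spike of the fully labeled standard, with 1 %
multiplicative intensity noise:

```python
from bitterquant import (
    AcquisitionModel, build_basis, parse_formula, state_distribution,
    simulate_run, quantify_run,
)
from bitterquant.quant import ng_to_pmol

analyte = parse_formula("C21H29N2O", charge=1)      # denatonium cation
standard = state_distribution(p_alpha=1.0, amide_d=False)  # complete α-d2

basis = build_basis(analyte, standard)
model = AcquisitionModel(noise_cv=0.01, seed=7)
run = simulate_run(
    analyte_pmol=ng_to_pmol(6.8), standard_pmol=10.0,
    standard_states=standard, analyte_formula=analyte, model=model,
)
result = quantify_run(run, basis, standard_pmol=10.0)
print(f"light fraction  {result.light_fraction:.4f}")
print(f"heavy fraction  {result.heavy_fraction:.4f}")
print(f"amount          {result.analyte_pmol:.3f} pmol "
      f"({result.analyte_ng:.3f} ng of the benzoate salt)")
print(f"peak apex       {result.peak.rt_apex_min:.2f} min")
print(f"residual        {result.residual_norm:.4f}")
```

prints

```
light fraction  0.6042
heavy fraction  0.3958
amount          15.265 pmol (6.817 ng of the benzoate salt)
peak apex       18.83 min
residual        0.0007
```

The light fraction is the analyte's share of the summed envelope across the
chromatographic peak; dividing by the heavy fraction and multiplying by the
10 pmol spike recovers 15.27 pmol against a ground truth of 15.23 pmol
(0.3 % error at 1 % intensity noise). The residual is the fraction of
observed intensity the two-species model leaves unexplained.

The same pipeline is scriptable from the shell:

```bash
bitterquant simulate --config cfg.yaml --analyte-pmol 15.2 --standard-pmol 10 --out run.mzML
bitterquant quantify run.mzML --config cfg.yaml
bitterquant purity run.mzML --config cfg.yaml
bitterquant calibrate --config cfg.yaml --amounts-ng 0.68,2,6,15,47.5 --standard-pmol 12
```

See `tests/test_cli.py` for a complete config example.

## Layout

```
src/bitterquant/
  isotopes.py   formulas, masses, isotope-pattern convolution
  hdx.py        deuteration states, exchange kinetics (ExchangeKinetics)
  synthgen.py   seeded synthetic centroid LC-MS runs
  deconv.py     envelope basis + NNLS mixture fractions (EnvelopeMixture)
  chrom.py      XICs, peak detection, co-elution, peak purity
  quant.py      amounts, prep arithmetic, calibration + LOD (CalibrationCurve)
  io.py         mzML / CSV readers and writers, YAML config
  cli.py        bitterquant {simulate,quantify,calibrate,purity}
docs/methods.md   model assumptions, parameters, numerical choices
```
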