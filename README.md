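# spcpanel

Quantification and cohort statistics for the ¹H-NMR five-marker
inflammatory panel — the acute-phase glycoprotein signals **GlycA**
(δ 2.05–2.09) and **GlycB** (δ 2.09–2.12) and the three sub-regions of the
Supramolecular Phospholipid Composite, **SPC₁** (δ 3.20–3.236, HDL
subfraction 4), **SPC₂** (δ 3.236–3.262, HDL subfractions 1–3) and
**SPC₃** (δ 3.262–3.30, LDL-associated) — together with a synthetic-data
layer that emulates diffusion-and-relaxation-edited (DIRE) plasma spectra
and realistic cohort structure, so the entire analysis is testable end to
end with no external data.

The package is aimed at metabolomics researchers who want a transparent,
reproducible reference implementation of the panel pipeline:

1. **Preprocessing** — per-sample ERETIC quantification scaling, chemical
   shift referencing to the water suppression frequency (SR = 0),
   asymmetric least-squares (Whittaker) baseline removal, and exclusion of
   the residual water band (δ 4.50–4.90) and noise regions (δ < 0.4,
   δ > 9.5).
2. **Quantification** — plain point-summation over the five fixed,
   half-open ppm windows above; derived SPC total, Glyc total and
   SPC/Glyc ratio.
3. **Cohort statistics** — healthy-participant selection, age×sex and
   BMI×sex stratified two-sided Mann–Whitney tests with
   Benjamini–Hochberg adjustment and star annotation, sex adjustment by
   residualisation with grand-mean add-back, percent-excess summaries, and
   Pearson correlations of the SPC sub-regions against HDL/LDL
   phospholipid subfraction concentrations.
4. **Synthetic data** — log-normal marker marginals with per-stratum
   medians, a participant-level random intercept across timepoints, a
   rank-calibrated Gaussian copula linking SPC sub-regions to lipoprotein
   phospholipids, and spectrum emulation as Lorentzian lines whose
   windowed point-sums equal the requested panel values exactly on the
   acquisition grid.

## Core model

For marker $m$, sex $s$ and BMI class $c$, marker values are drawn

$$X_{m} = \mathrm{med}_{m,s,c}\,\exp\!\big(\sigma_m (\sqrt{\rho}\,u_i + \sqrt{1-\rho}\,e_{it})\big),$$

where $u_i$ is a participant intercept, $e_{it}$ a sample deviate
(intraclass correlation $\rho = 0.5$) and $\mathrm{med}_{m,s,c}$ the
configured stratum median (the log-normal median equals the scale
parameter). Lipoprotein fractions are tied to the markers on the latent
Gaussian scale with coefficients inverted from the bivariate log-normal
closed form, so the realised Pearson correlations approach their targets
(SPC₂–HDL1-3 r = 0.94, SPC₁–HDL4 r = 0.53, SPC₁–HDL1-3 r = 0.16) at
large n. Quantification is raw point-summation, so values are in
grid-dependent arbitrary units (A.U.); the pipeline refuses to mix grids
within one cohort.

## Worked example

```python
import spcpanel as sp

acq = sp.AcquisitionConfig(noise_sd=0.0, baseline_amplitude=0.0, water_height=0.0)
panel = {"glyca": 1800.0, "glycb": 950.0, "spc1": 3300.0, "spc2": 5124.0, "spc3": 1150.0}
spec = sp.generate_spectrum(panel, acq, seed=3, eretic_factor=1.0)
out = sp.quantify_panel(sp.preprocess(spec))
print({m: round(getattr(out, m), 1) for m in sp.MARKERS})
print(round(out.spc_glyc_ratio, 3))
```

prints

```
{'glyca': 1798.9, 'glycb': 949.1, 'spc1': 3296.8, 'spc2': 5121.7, 'spc3': 1146.7}
3.481
```

i.e. a noise- and baseline-free spectrum synthesized from a known panel is
recovered by preprocessing + window integration to within 0.3% on every
marker (the residue is the small asymmetric-baseline bump under the peak
clusters), and the SPC/Glyc ratio ≈ (3296.8+5121.7+1146.7)/(1798.9+949.1).

The full seeded study replica runs from the shell:

```sh
spcpanel run-all --seed 1 --out run1          # simulate + quantify + analyze
spcpanel run-all --seed 1 --healthy --out run1h
```

which writes `cohort.csv`, `quantified.csv`, tidy results CSVs and a
markdown report, all stamped with the config hash and seed.

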