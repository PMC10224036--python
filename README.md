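# glucest

Quantification pipeline for **glutamate-weighted chemical exchange
saturation transfer (GluCEST) MRI**, built for preclinical single-slice
studies of hippocampal glutamate — e.g. rodent models of
sepsis-associated encephalopathy — and for anyone who needs a tested,
reproducible reference implementation of the standard GluCEST processing
chain.

## What it computes

CEST imaging saturates exchangeable solute protons (glutamate amine at
+3.0 ppm from water) and reads out the transferred loss of water signal.
The per-voxel **Z-spectrum** `Z(Δω) = S_sat(Δω)/S0` is processed as:

1. **Normalisation** of the saturated series by the unsaturated S0 image.
2. **B0 correction (WASSR)** — a low-power, narrow Z-spectrum whose
   minimum locates the true water frequency per voxel; each CEST
   spectrum is re-referenced so water sits at 0 ppm. The spectral
   minimum is found by a cubic-spline (or symmetric-Lorentzian) fit
   refined on a 0.001 ppm sub-grid; re-sampling uses rational (AAA)
   interpolation, exact for Lorentzian line shapes, with a spline
   fall-back under noise.
3. **B1 correction (double-angle)** — from gradient-echo images at
   nominal flip angles α and 2α, `cos(b1·α) = S_2α / (2·S_α)` gives the
   relative RF field per voxel; a declared policy (`scale`, `exclude`
   or `none`) applies it to the output map.
4. **GluCEST map** — the MTR asymmetry at the glutamate resonance:

   `GluCEST (%) = 100 × (S_sat(−3.0 ppm) − S_sat(+3.0 ppm)) / S_sat(−3.0 ppm)`

5. **ROI statistics and group inference** — ROI mean ± SD per subject;
   Kolmogorov–Smirnov (Lilliefors) and Shapiro–Wilk normality tests,
   one-way ANOVA (from raw values or published `n, mean, SD` summaries —
   algebraically identical routes), Tukey HSD via the studentized-range
   distribution, and ANOVA power / sample size via the noncentral F
   distribution with the G*Power convention `λ = f²·N`.

A synthetic-data module generates complete single-slice studies
(25-offset CEST stack, 33-offset WASSR stack, dual-angle image pair)
from a sum-of-Lorentzians forward model with known ground-truth B0/B1
fields and glutamate pool sizes, plus Rician noise; a two-pool
Bloch–McConnell integrator serves as an independent physics oracle in
the tests.

## Worked example

```python
from glucest import RunConfig, run_study

report = run_study(RunConfig(seed=1))   # 3 groups x 7 subjects, 16x16 slice
print(report.group_table)
```

```
group  n  mean_pct   sd_pct
 CTRL  7  2.103845 0.239962
SEP05  7  2.660122 0.159773
SEP10  7  3.654964 0.207124
```

Each row is one simulated animal group: `mean_pct`/`sd_pct` are the
across-subject mean and SD of the hippocampal-ROI GluCEST percentage.
The groups were simulated with increasing glutamate pool amplitudes, and
the recovered contrast is strictly ordered CTRL < SEP05 < SEP10. The
accompanying ANOVA (`report.anova_table`) gives F(2,18) = 102.91,
p = 1.4e-10, and Tukey HSD (`report.tukey_table`) finds every pairwise
difference significant.

The same analyses are scriptable from the shell:

```sh
glucest power                      # n per group: 7  total N: 21  achieved power: 0.86285
glucest run --out study/ --seed 1  # full simulated study with CSV reports
glucest simulate / process / stats # individual stages on NIfTI + JSON data
```

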