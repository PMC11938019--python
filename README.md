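# dendro-isophys

Tree-ring stable-isotope ecophysiology: from raw ring widths and δ¹³C /
δ¹⁵N / δ¹⁸O series to intrinsic water-use efficiency, leaf-water ¹⁸O
enrichment, growth releases, trend breakpoints, and mixed-effects
attribution of those signals to atmospheric drivers.

The package is aimed at dendroecologists and ecophysiologists who hold
multi-century tree-ring chronologies (ring widths plus wood or α-cellulose
isotope measurements) and want a reproducible, tested pipeline for the full
analysis chain, including a synthetic-data generator with known ground
truth so that every stage can be validated by parameter recovery.

## The science in brief

**Carbon.** Measured tree-ring δ¹³C, corrected for post-photosynthetic
fractionation (2‰), gives discrimination against the contemporaneous
atmosphere, Δ¹³C = (δ¹³C_atm − δ¹³C_p)/(1 + δ¹³C_p/1000).  Under the C3
discrimination model with stomatal (a = 4.4‰), carboxylation (b = 28‰) and
photorespiratory (f = 12‰) fractionations,

    ci = [(Δ¹³C − a)·ca + f·Γ*] / (b − a),     iWUE = (ca − ci)/1.6,

with the CO₂ compensation point Γ* following an Arrhenius response anchored
at 42.75 ppm (25 °C, sea level) and corrected to site pressure (default
elevation 1030 m); leaf temperature defaults to the April–August mean.

**Oxygen.** Cellulose δ¹⁸O referenced to precipitation water gives the
tree-ring enrichment Δ¹⁸O_tr = (δ¹⁸O_cell − δ¹⁸O_p)/(1 + δ¹⁸O_p/1000), and
leaf-water enrichment follows by removing the biochemical water–cellulose
fractionation ε_wc (27‰) and the exchange of a fraction
p_ex = 0.36·VPD + 0.13 of oxygen atoms with stem water:

    Δ¹⁸O_lw = (Δ¹⁸O_tr − ε_wc) / (1 − p_x·p_ex).

Precipitation δ¹⁸O is hindcast to the chronology start by regressing the
instrumented series on annual mean temperature and annual SPI.

**Growth.** Basal area increment BAI_t = π(r_t² − r_{t−1}²) from cumulative
ring widths; canopy releases are years whose percent growth change exceeds
50 % of a boundary line (the maximum growth response attainable at a given
prior growth rate).

**Trends and attribution.** Species chronologies (per-year means under a
50 % replication rule) are tested for 0–2 trend breakpoints by segmented
regression (iterative linearization with Davies-type supremum tests), and
annual/segment observations are modelled as

    y = Xβ + b_tree + ε,   b ~ N(0, σ_b²),  Corr(ε_t, ε_s) = ρ^|t−s|,

fitted by ML, with all-subsets AICc selection over Z-scored drivers and
their CO₂ interactions, and conditional model averaging of the ΔAICc < 2
set (Nakagawa marginal/conditional R², VIF diagnostics, PCA summary).

## Worked example

```python
import dendro_isophys as di

sc = di.make_scenario("paper_like", seed=1)          # synthetic study
res = di.analyze(sc.env, sc.isotopes, sc.rings,
                 options=di.AnalysisOptions(
                     mains=sc.truth.candidate_mains,
                     interactions=sc.truth.candidate_interactions))

f = res["breakpoints"][("spruce", "d18o_lw")]
print(f"break {f.psi[0]:.0f} +/- {f.psi_se[0]:.0f} yr, "
      f"slopes {f.slopes[0]:+.4f} / {f.slopes[1]:+.4f} permil/yr")
avg = res["lme"][("spruce", "iwue")]
print(avg.table.round(2)[["estimate", "se", "z", "p"]])
```

prints

```
break 1874 +/- 5 yr, slopes +0.0068 / -0.0027 permil/yr
             estimate    se      z     p
term
Intercept       51.22  1.24  41.42  0.00
cellulose        7.20  1.80   4.00  0.00
cambial_age      4.19  0.25  16.79  0.00
ca               8.39  0.43  19.37  0.00
ndep             4.73  0.42  11.38  0.00
ca:ndep          1.75  0.23   7.68  0.00
ph              -0.29  0.48   0.59  0.56
```

The leaf-water enrichment chronology was generated with a prescribed trend
change in 1877 (+0.007 to −0.003 ‰ yr⁻¹): the fitted break year and slopes
recover it within their standard errors.  The averaged mixed-model table
recovers the generator's spruce iWUE coefficients (cellulose offset 9.5,
cambial age 4, CO₂ 9, N deposition 5, CO₂:N interaction 2, all in Z-score
units; pH is a zero-effect decoy) within twice their unconditional SEs —
the offset term, identified from only 11 trees, is the least precise.

A shell workflow is available through the CLI:

```sh
dendro-isophys simulate --scenario paper_like --seed 1 --out data/
dendro-isophys run config.yml
```

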