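# spectraits

Leaf-to-canopy hyperspectral trait prediction for wheat canopies.

Screening wheat genotypes for photosynthetic performance in the field is a
bottleneck: a single light-saturated assimilation measurement with a gas
analyzer takes 15–25 minutes per leaf, while a leaf reflectance spectrum
takes about a minute.  This package implements the chemometric pipeline
that turns leaf reflectance (350–2500 nm) into predictions of
photosynthetic (A_sat, g_s, Fv′/Fm′, ΦPSII), biochemical (SPAD chlorophyll
index, total C and N) and biophysical (SLA, LMA, LAI) traits for the top
(flag leaf), middle (second leaf) and bottom (third leaf) layers of the
canopy — per layer and with all layers combined — then upscales leaf
predictions to canopy photosynthesis through layer LAI and relates genotype
means of the predictions to radiation use efficiency (RUE).  It is aimed at
crop physiologists and phenotyping teams who want a tested, reproducible
implementation of this workflow, and it ships a synthetic field-trial
generator so every stage can be exercised end to end without field data.

## The methods in brief

**PLS1 regression (orthogonal scores / NIPALS).**  For centered spectra
X (n × p) and one centered trait y, components a = 1 … A are extracted as

    w_a = Xᵀy / ‖Xᵀy‖,  t_a = X w_a,  p_a = Xᵀt_a / t_aᵀt_a,
    q_a = yᵀt_a / t_aᵀt_a,  then X ← X − t_a p_aᵀ,  y ← y − q_a t_a

giving mutually orthogonal scores.  Regression coefficients for A
components are B = W(PᵀW)⁻¹q with intercept ȳ − x̄ᵀB.  The component count
is chosen at the minimum cross-validated RMSEP (= √(PRESS/n) under
leave-one-out).  Before fitting, trait outliers beyond ±3 σ are removed
(single pass, within each layer × stage stratum) and the samples are split
70/30 into training and validation at random.

**VIP scores.**  With SSYₐ = qₐ² tₐᵀtₐ, the importance of wavelength j is
VIPⱼ = √(p · Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ); mean VIP² is 1, so bands with
VIP > 1 carry above-average weight.  Contiguous runs above the threshold
are reported as wavelength regions.

**Canopy upscaling.**  A_canopy = Σ_layers A_sat^layer · LAI^layer
(μmol m⁻² ground s⁻¹); pooled g_s is the unweighted mean of the three
layers.

**RUE and BLUEs.**  RUE is the OLS slope of accumulated dry biomass on
accumulated intercepted PAR (daily irradiance × 0.45 × fAPAR).  Genotype
adjusted means (BLUEs) come from a REML mixed model with genotype (and an
optional phenology covariate) fixed and environment, replicate-in-
environment and environment × genotype random.

## Worked example

```python
from spectraits import TrialConfig, ExperimentConfig, run_experiment

config = ExperimentConfig(trial=TrialConfig(seed=1),
                          traits=("Asat", "gs", "SPAD"))
report = run_experiment(config)
cols = ["trait", "layer", "n_train", "n_validation", "n_comp",
        "r2_validation", "rmse_v"]
print(report.summary[cols].round(3).to_string(index=False))
```

simulates the default trial (11 genotypes × 3 replicates × 3 years × 2
growth stages × 3 canopy layers = 594 leaf spectra) and prints

```
trait    layer  n_train  n_validation  n_comp  r2_validation  rmse_v
 Asat      Top      139            59       4          0.362   3.296
 Asat   Middle      138            59       5          0.588   4.229
 Asat   Bottom      139            59       2          0.586   2.935
 Asat Combined      415           178       4          0.578   4.593
   gs      Top      139            59       3          0.098   0.115
   gs   Middle      139            59       9          0.207   0.162
   gs   Bottom      139            59      11          0.332   0.122
   gs Combined      416           178       3          0.284   0.135
 SPAD      Top      139            59       3          0.979   0.415
 SPAD   Middle      139            59       2          0.947   0.460
 SPAD   Bottom      138            59       2          0.930   0.632
 SPAD Combined      415           178       3          0.977   0.446
```

Each row is one model: the trait, the layer strategy (three single-layer
models and the pooled-spectra combined model), training/validation sizes
after outlier filtering and the 70/30 split, the component count selected
at the RMSEP minimum, and validation R² (squared Pearson correlation of
observed vs predicted) and RMSE in trait units.  The chlorophyll-driven
SPAD index is recovered almost perfectly; A_sat and g_s are recovered
partially, with the combined model matching the best single layer while
covering the whole canopy.  `report.vip_regions["SPAD"]` shows the
wavelength regions with VIP > 1 — dominated by the visible and red-edge
bands (e.g. 557–724 nm), where chlorophyll absorbs:

```
SPAD VIP > 1 regions: [(350, 354), (356, 526), (528, 530), (532, 540),
                       (543, 555), (557, 724), (1878, 1878), (1880, 1988)]
```

`report.canopy_eval`, `report.rue` and `report.rue_correlations` carry the
canopy-level comparison of predicted vs observed BLUEs per stage, the
per-genotype RUE slopes per growth interval, and the genotype-level
correlation between predicted canopy photosynthesis (or pooled g_s) and
RUE.  The same experiment is available from the shell:

```
spectraits run --out-dir results/            # default synthetic experiment
spectraits simulate --seed 1 --out-dir trial/  # write the trial as CSVs
spectraits upscale --layers layers.csv --out canopy.csv
```

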