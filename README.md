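# seagrassrs

Semi-automated monitoring of subtidal seagrass from 30 m multiband
surface-reflectance imagery: per-pixel classification of the submarine
landscape, leaf area index (LAI) and blue-carbon retrieval through the water
column, multi-decade trend statistics, and agreement assessment against
reference maps. It is aimed at coastal remote-sensing scientists who need a
reproducible, testable pipeline for decadal seagrass/carbon time series in
shallow lagoons — together with a synthetic scene generator so every stage
can be exercised and validated without any satellite downloads.

## The model in brief

Light reflected by the seabed and seen by the sensor in the green band
(560 nm) follows a two-path water-column model,

    R_rs = (R_b / π) · exp(−(K_d + K_Lu) · H),        K_Lu = K_d / 2π,

where R_b is bottom reflectance, H the tide-adjusted depth (m) and
K_d, K_Lu the diffuse attenuation coefficients (m⁻¹). Inverting it per
pixel gives R_b, and a log-linear law gives leaf area index:

    LAI = a + b · ln(R_b) + c,        b < 0.

Carbon stocks follow from LAI through fixed transfer coefficients —
fresh biomass 500 g m⁻² per unit LAI, dry = 0.2 × fresh, aboveground
C = 0.34 × dry, belowground C = 3 × aboveground C — i.e. 102 g C m⁻² of
belowground carbon per unit LAI.

Around that core: a five-class per-pixel neural classifier (land,
optically-deep water, seagrass, submerged sand, intertidal) trained on
balanced ROI spectra with exact-Shapley band attribution; dark-object
atmospheric correction keyed on the darkest NIR water pixel; a strict
2.5 m optically-deep mask and 900 m²-per-pixel extent accounting; seasonal
Mann–Kendall / Theil–Sen trend tests with the γ detectability statistic and
per-pixel frequency maps; climate-driver multiple regression (ENSO, NAO);
and presence/absence agreement (precision/recall/F, overall accuracy,
Cohen's κ, McNemar). Details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

End-to-end on one synthetic scene (128×128 pixels at 30 m, default optics
K_d = 0.734 m⁻¹, tide 0.24 m):

```python
import numpy as np
import seagrassrs as sg

cfg = sg.SceneConfig(seed=42)
scene, truth = sg.simulate_scene(cfg)

# atmospheric correction off the darkest NIR water pixel
offsets = sg.find_dark_offset(scene, truth.water_mask)
corrected = sg.dos_correct(scene, offsets)

# classify, mask optically-deep water, measure extent
rois = sg.make_rois(truth, cfg)
ts = sg.balance_classes(sg.extract_training(scene, rois),
                        n_per_class=20000, seed=42)
train, test = sg.split_train_test(ts, seed=42)
model = sg.train_classifier(train, sg.NetworkConfig(seed=42))
cmap = sg.apply_depth_mask(sg.predict_map(model, scene), truth.dem,
                           tide=cfg.tide_height)
extent = sg.compute_extent(cmap, pixel_size=cfg.pixel_size)

# retrieve LAI through the water column and run the carbon chain
depth = sg.tide_adjust(truth.dem, cfg.tide_height)
rb, valid = sg.retrieve_rb(corrected.band("green"), depth, cfg.optics)
valid &= (cmap.labels == sg.SEAGRASS) & ~cmap.mask
lai = sg.invert_lai(rb, cfg.lai_coeffs, valid=valid)
carbon = sg.carbon_summary(lai, pixel_size=cfg.pixel_size)
```

Output:

```
held-out accuracy : 1.0000
seagrass extent   : 3514 px = 3.1626 km^2
mean LAI          : 1.602 (truth 1.601)
fresh biomass     : 2.5337 Gg
belowground C     : 0.5169 Gg
BGC density       : 163.4 g C m^-2
```

Reading it: the classifier separates the five synthetic classes on held-out
ROI pixels; 3,514 unmasked seagrass pixels × 900 m² give 3.16 km² of meadow;
the water-column inversion recovers the scene's mean LAI (1.602 retrieved vs
1.601 simulated); and the transfer chain turns that standing leaf area into
bay-integrated biomass and belowground carbon — 163 g C m⁻² at LAI ≈ 1.6,
i.e. 102 g C m⁻² per unit LAI.

For trend analysis, feed per-scene extent/LAI/carbon rows to
`seagrassrs.trends`:

```python
res = sg.trend_summary(sg.AnnualSeries(years, extents_km2))
# res.tau, res.p_value, res.sen_slope, res.percent_change_per_year,
# res.gamma_years, res.strength_label
```

A `seagrassrs` console script exposes the same stages as subcommands
(`simulate`, `preprocess`, `classify`, `carbon`, `trends`, `freq`, `agree`);
run `seagrassrs --help`.

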