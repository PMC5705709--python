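# ehtkit

Analysis toolkit for engineered human heart tissue ("cardiopatch")
experiments: optical-mapping electrophysiology, isometric contractile
mechanics, intravital hyperspectral vascular imaging, gCaMP calcium
transient quantification, and scalar expression/morphometry calculators —
together with synthetic-data generators that provide ground truth for every
stage.

## Modules

| Module | What it does |
| --- | --- |
| `ehtkit.synthetic_data` | Kinematic action-potential wave movies, parametric twitch trains, Beer-Lambert hyperspectral vessel phantoms, calcium flash movies, and arrhythmia episodes — all with closed-form or dense-grid ground truth. |
| `ehtkit.optical_mapping` | Movie conditioning, activation maps (50 % upstroke or max-dV/dt), isochrones, conduction velocity (local plane fit or radial fit), APD80 maps, burst-pacing protocol, arrhythmia episode classification (60 s sustained boundary), graft-host coupling assessment. |
| `ehtkit.mechanics` | Twitch segmentation and 10-90 % rise/decay/total kinetics, force-length curves, passive stiffness (top-three strain levels / CSA), specific force, force-frequency relationship, force per input cardiomyocyte. |
| `ehtkit.vascular_imaging` | Hemoglobin unmixing by non-negative least squares against packaged extinction spectra, CLAHE contrast enhancement, Otsu/fixed vessel segmentation, blood-vessel density and fold changes. |
| `ehtkit.calcium` | ROI placement, dF/F = (F_peak − F_base)/F_base, transient timing and rate. |
| `ehtkit.quantify` | Relative cell counts, percent differences, pooled percentages, delta-delta-Ct expression, protein/DNA ratios, densitometry normalization. |
| `ehtkit.io` / `ehtkit.runner` / `ehtkit.cli` | TIFF+JSON / CSV readers and writers, provenance-stamped stage runs, umbrella CLI. |

Conventions: arrays are `[t, row, col]`, times in ms (episode traces in s),
lengths in mm, forces in mN, conduction velocity in cm/s; undefined pixels
are NaN.

## CLI

```sh
# full synthetic round trip (simulate -> map, mech, bvd, calcium)
ehtkit demo --out demo_out --seed 1

# map a movie (multi-page TIFF + JSON sidecar with dt_ms / pixel_size_mm)
ehtkit map --input movie.tif --meta movie.json --method half_amplitude --out outdir/

# mechanics from a force trace CSV (time_ms,value) + YAML protocol
ehtkit mech --trace t.csv --protocol p.yaml --out outdir/

# blood-vessel density from a hyperspectral stack
ehtkit bvd --stack hs.tif --meta hs.json --roi roi.json --out outdir/

# calcium dF/F
ehtkit calcium --input movie.tif --meta movie.json --roi-size-um 400 --n-rois 3
```

Every stage writes a `provenance.json` (package version, config hash, seed,
parameters); identical configs reproduce identical outputs for deterministic
stages.

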