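# epiquant

Spatially resolved quantification of epithelial integrity and cell-fate
markers in fluorescence microscopy, for labs studying how local disruption
of an epithelial sheet — loss or fragmentation of the tight-junction (TJ)
network — shapes where cells respond to signaling and adopt new fates
(e.g. mesendoderm induction in human pluripotent stem cell layers).

Given multichannel images (DAPI, a junction stain such as ZO1, and nuclear
markers such as BRACH, pSMAD1/5 or LEF1), the package measures the core
statistic of such studies: the percentage of marker-positive cells as a
function of Euclidean distance from disrupted areas, summarized by an
ordinary-least-squares slope

&nbsp;&nbsp;&nbsp;&nbsp;*P(k) = m·k + b*, &nbsp; *k* ∈ {0 µm, +30, +60, +90, >+90}

where the bands are the half-open intervals [0, 30), [30, 60), [60, 90),
[90, ∞) µm away from the disrupted mask, and the 0 µm class is the
disrupted area itself. A strongly negative *m* means the marker
concentrates in and near disrupted regions; *m* ≈ 0 means expression is
blind to epithelial integrity.

Around that core it provides: ImageJ-style nuclei segmentation (median →
Huang threshold → watershed) and nuclear-marker calling (rolling ball →
top-hat → Otsu); automatic or manual disrupted-area masks with exact area
fractions; per-cell apical surface areas delimited by the junction network;
organized-area time courses; axial (z) peak-to-peak distances between two
stains in nm; radial intensity profiles of circular micropattern colonies
(700 µm 2D gastruloids) normalized to the control condition's maximum; and
RT-qPCR relative quantification (RQ = 2^−ΔΔCt). A synthetic-data module
generates monolayer and colony images with exact planted ground truth, so
every stage is validated by parameter recovery. See `docs/methods.md` for
the models and conventions.

## Worked example

Simulate a monolayer field with 40% planted TJ disruption and a marker
whose positivity decays with distance (planted band probabilities 0.9,
0.7, 0.5, 0.3), then run the full pipeline on it:

```sh
epiquant simulate --out sim --disrupted-fraction 0.4 --seed 7
# wrote field + truth to sim (disrupted 40.0%)

cat > config.yaml <<EOF
images:
  - path: sim/field.ome.tif
channels: {nuclei: DAPI, junction: ZO1, marker: BRACH}
output_dir: run
seed: 7
EOF

epiquant pipeline --config config.yaml
# 1 images analyzed (0 failed); results in run
```

`run/field.ome_distance_profile.csv` holds the distance profile:

```
bin,n_cells,n_positive,fraction_percent,image
0,437,394,90.16018306636155,field.ome
+30,183,148,80.8743169398907,field.ome
+60,171,117,68.42105263157895,field.ome
+90,152,64,42.10526315789474,field.ome
>+90,147,36,24.489795918367346,field.ome
```

1090 nuclei were segmented and binned by centroid distance from the
detected disrupted mask (40.6% of the field, vs 40.0% planted); the
positive percentages fall from 90% inside disrupted zones to 24% beyond
90 µm, tracking the planted probabilities. `run/slopes.csv` summarizes:

```
image,marker,n_nuclei,disrupted_percent,mask_provenance,m,intercept,r_squared,x_convention
field.ome,BRACH,1090,40.63148498535156,auto,-17.010982807798438,95.23208795841553,0.9677520034555249,bin_index
```

i.e. the marker loses about 17 percentage points per distance band
(m = −17.0, r² = 0.97 on the band-index scale) — the negative-slope
signature of fate markers that concentrate where the epithelium is
disrupted. `epiquant report --run-dir run` renders the profile with the
fitted line.

Other subcommands wrap the remaining stages: `segment`, `rings`,
`profile`, `micropattern` (radial aggregates with control-max
normalization) and `qpcr` (tidy Ct table in, RQ tables out). Everything is
also available as a library (`epiquant.segmentation`, `epiquant.spatial`,
`epiquant.micropattern`, `epiquant.qpcr`, `epiquant.synthetic`).

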