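# condensia

Quantitative image analysis of **mesenchymal condensations** — the dense
cell aggregates that initiate cartilage and bone formation — for two
experimental settings:

1. **Micromass morphometrics.** Brightfield images of micromass cultures
   are segmented into individual condensations (CLAHE → Otsu →
   morphological cleaning → distance-transform watershed with minima
   imposition), and eleven shape descriptors are computed per
   condensation: area, perimeter, eccentricity, minor/major axis, aspect
   ratio, roundness `4A/(πM²)`, number of condensations, roughness
   (convex perimeter / perimeter), mean 4-nearest-neighbour centroid
   distance, and occupancy (fraction of the circumscribing circle
   covered). Two populations (e.g. facial vs limb-bud condensations) can
   be compared by a standardized two-class Fisher discriminant,
   `w = S_w⁻¹(µ_a − µ_b)`, which ranks descriptors by |w|.
2. **Groove profiling.** Hoechst fluorescence time series of cultures
   confined in rectangular microgrooves (25–300 µm wide) are quantified
   from axis-averaged intensity profiles: condensations are peaks, their
   **length** is the FWHM along the groove, their **width** the FWHM
   across it (restricted to the peak's length extent), and peak
   **prominence** proxies cell density. The package derives aspect
   ratios (with the unconstrained-groove convention for 300 µm/TCP),
   condensations per 100 µm, backward tracks from the final frame to
   each condensation's establishment time, and per-timepoint summaries
   with plateau times.

A synthetic-image generator (`condensia.synthgen`) renders both kinds of
data with exact ground truth — dark ellipse scenes, and groove series of
anisotropic Gaussian condensations following logistic growth — so every
estimator is verifiable end to end without experimental data.

## Worked example

```python
import numpy as np
from condensia import synthgen, condseg, morphometrics, grooveprofile
from condensia.grooveprofile import GrooveROI

# segment a synthetic brightfield scene and describe it
spec = synthgen.MicromassSceneSpec(n_objects=10, seed=42)
image, truth = synthgen.generate_micromass_scene(spec)
labels = condseg.segment_micromass(image)
table = morphometrics.descriptor_table(labels, calibration=1.0)
print(f"condensations found: {labels.max()} (generated: {len(truth)})")
print(table[["area", "major_axis", "roundness", "occupancy"]].round(2).head(3))

# quantify a 36 h groove time series (72 frames, 30 min apart)
gspec = synthgen.GrooveSeriesSpec(
    groove_width_um=100, groove_length_um=500, n_timepoints=72,
    condensations=[
        synthgen.CondensationParams(center_um=150, final_length_um=80, final_width_um=40),
        synthgen.CondensationParams(center_um=370, final_length_um=70, final_width_um=45),
    ],
    seed=42,
)
stack, _ = synthgen.generate_groove_series(gspec)
roi = GrooveROI(x0=0, y0=0, x1=500, y1=100, nominal_width=100.0, pixel_size=1.0)
frames = [grooveprofile.measure_frame(stack[k], roi, timepoint=k * 0.5) for k in range(72)]
tracks = grooveprofile.track_backwards(frames)
summary = grooveprofile.summarize_series(frames, gspec.times_h, roi)
final = summary.iloc[-1]
print(f"tracks: {len(tracks)}; final mean length {final.mean_length_um:.1f} um, "
      f"width {final.mean_width_um:.1f} um, AR {final.mean_aspect_ratio:.2f}, "
      f"{final.per_100um:.1f} condensations per 100 um")
print(f"length plateau at {summary.attrs['plateau_time_h']['mean_length_um']:.1f} h")
```

prints

```
condensations found: 10 (generated: 10)
     area  major_axis  roundness  occupancy
0  1189.0       51.33       0.57       0.59
1   550.0       31.69       0.70       0.70
2   558.0       28.74       0.86       0.90
tracks: 2; final mean length 75.1 um, width 41.7 um, AR 1.81, 0.4 condensations per 100 um
length plateau at 12.5 h
```

The segmentation recovers all ten generated objects; the groove analysis
recovers the two condensations' final FWHMs within a few percent of the
generating truth (80/70 µm lengths, 40/45 µm widths), and the measured
length plateau (12.5 h) matches the closed-form time at which the
generating logistic (midpoint 8 h, rate 0.5 h⁻¹) enters the ±10% band of
its final value (12.4 h).

## Command line

```bash
condensia synth    --config synth.yaml --out data/            # synthetic data + truth
condensia segment  --image scene.tif --out labels.tif         # label map (16-bit TIFF)
condensia describe --labels labels.tif --calib 1.0 --out desc.csv
condensia lda      --a face.csv --b limb.csv --out lda.json   # descriptor ranking
condensia grooves  --stack series.tif --rois rois.yaml --calib 0.65 --out results/
condensia run      --config run.yaml                          # full pipeline from YAML
```

ROI files list groove rectangles in YAML (`grooves:` with `x0/y0/x1/y1`,
`nominal_width`, optional `long_axis`). Every run writes a manifest with
the resolved configuration and seed; reruns are byte-identical.

## Layout

```
src/condensia/
  synthgen.py       synthetic scenes and groove series with ground truth
  condseg.py        brightfield micromass segmentation
  morphometrics.py  the 11 shape descriptors + discriminant ranking
  grooveprofile.py  profile/FWHM quantification, tracking, summaries
  pipeline_io.py    orchestration, TIFF/CSV/YAML/JSON I/O, manifests
  cli.py            the `condensia` command
```
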