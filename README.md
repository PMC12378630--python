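# mrkymo — MR-based kymography of respiratory thoracic motion

`mrkymo` turns dynamic 2D thoracic MR series (free breathing, ~0.6 s per
frame, ~60 s) into quantitative directional measurements of thoracic
expansion.  It is aimed at researchers in respiratory physiology and
rehabilitation who need positional comparisons (supine vs. semi-prone) of
chest-wall and diaphragm motion from low-SNR body-coil acquisitions,
without breath-holds or phased-array coils.

The workflow:

1. **Preprocess** each frame: bilinear upsampling (192→512), 3×3 median
   denoising, Sobel gradient magnitude, automatic intermeans binarisation,
   and skeletonisation to single-pixel thoracic contours (optionally
   overlaid in green on the denoised frames).
2. **Kymograms**: a 1D kymogram tracks one image row/column across all
   frames (space × time).  Measurement axes are placed at midpoints of
   anatomical landmarks; the diaphragm trace extracted from a y-t kymogram
   gives the end-inspiratory and end-expiratory time points — the frames of
   lowest and highest diaphragm position over the whole acquisition, after
   excluding clearly inconsistent breathing cycles (median/MAD rule).
3. **Measure**: thoracic dimension = distance between lung contours along
   the kymogram's spatial axis at each end-phase frame, in mm;
   **expansion = end-inspiratory − end-expiratory dimension**, reported for
   five axes: right/left head–foot (H-F), bilateral right–left (R-L), and
   right/left anterior–posterior (A-P).
4. **Statistics**: intraclass correlation coefficients (one-way, two-way
   agreement/consistency; single measures) with F-based 95% CIs and
   qualitative bands, exact paired Wilcoxon signed-rank tests, and
   Benjamini–Hochberg adjustment.

Since raw participant images for such studies are generally not public,
the package includes a **synthetic breathing-thorax phantom** — elliptical
thorax, superellipse lungs, dome-shaped diaphragm with a liver band,
sin²-waveform motion, anti-aliased rendering, additive noise — whose
boundaries have closed forms.  Every pipeline stage is validated against
this ground truth; see `docs/methods.md`.

## Worked example

```python
from mrkymo import PhantomConfig, generate_phantom_series
from mrkymo.session import analyze_plane, phantom_landmarks, phantom_search_band

config = PhantomConfig(duration_s=18.0, seed=1)   # coronal, H-F 84/81 mm, R-L 4 mm
series, truth = generate_phantom_series(config)

analysis = analyze_plane(series, phantom_landmarks(config),
                         phantom_search_band(config))
print("end-insp frame:", analysis.phases.t_end_insp,
      " end-exp frame:", analysis.phases.t_end_exp)
for direction, m in analysis.measurements.items():
    print(f"{direction.value:12s} insp={m.end_insp_mm:6.1f} mm "
          f"exp={m.end_exp_mm:6.1f} mm expansion={m.expansion_mm:6.2f} mm "
          f"(true {truth.axes[direction].expansion_mm:.0f})")
```

Output:

```
end-insp frame: 5  end-exp frame: 0
right_HF     insp= 210.9 mm exp= 125.0 mm expansion= 85.94 mm (true 84)
left_HF      insp= 207.0 mm exp= 126.0 mm expansion= 81.05 mm (true 81)
bilateral_RL insp= 260.7 mm exp= 255.9 mm expansion=  4.88 mm (true 4)
```

The detected phases hit the ground-truth frames exactly (frame 5 is the
first sampled peak of the sin² waveform, frame 0 the first trough), and
each expansion is recovered to within ~2 mm — about two interpolated
pixels, the resolution limit of contour localisation on this data.

The same analysis runs from the shell on stacks stored as multi-frame
TIFF, DICOM series, or NIfTI 2D+t:

```bash
mrkymo phantom --plane coronal --seed 1 --out phantom.tif
mrkymo preprocess --in phantom.tif --target-size 512 --out-dir processed/
mrkymo run-session --manifest session.yaml --out-dir results/
mrkymo stats-icc --in ratings.csv --model twoway_agreement
```

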