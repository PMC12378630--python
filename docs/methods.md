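# Methods

`mrkymo` implements an MR-based kymography workflow for dynamic 2D thoracic
image series: contour-enhancing preprocessing, space-time (kymogram)
analysis of respiratory motion, directional expansion measurement, and
reproducibility statistics.  Because raw participant images for this kind of
study are typically not shareable, the package ships a synthetic
breathing-thorax phantom with closed-form ground truth, and every stage is
validated against it.

## Acquisition model

A series is a stack of square grayscale frames with isotropic pixel spacing
and a fixed frame interval.  The defaults mirror a body-coil fast-field-echo
protocol: 192×192 matrix over a 500×500 mm field of view (2.604 mm/px),
0.6 s temporal resolution, 60 s of free deep breathing.  Image coordinates
follow radiological convention for this package: `y` increases footward, so
the diaphragm's lowest position is its largest row index.

## Phantom

The phantom is the package's ground-truth generator, not a test fixture:

- **Anatomy.** An elliptical soft-tissue thorax (default semi-axes
  170×230 mm) contains two lung regions modelled as superellipses —
  exponent 8 along x for realistically flat lateral walls, 2 along y —
  bounded below by a dome-shaped diaphragm arc
  `y = d0 + A·φ(t) + c·((x−cx)/w)²`.  A liver-intensity region fills the
  space below the right hemidiaphragm.  Intensities: lung 15, liver 70,
  tissue 100 (arbitrary units), chosen so the lung/liver (diaphragm) edge
  has roughly half the contrast of the skin/air edge, as in fast low-SNR
  thoracic imaging.
- **Motion.** The breathing waveform is `φ(t) = sin²(πt/T)`: smooth,
  non-negative, with clear end-expiratory (φ=0) and end-inspiratory (φ=1)
  plateaus.  Each boundary is displaced by `φ·amplitude` along its axis:
  diaphragm footward (head-foot amplitude per hemithorax), both lateral
  walls outward by half of the bilateral right-left amplitude, and the
  anterior wall forward on sagittal planes.  Default amplitudes follow the
  supine magnitudes observed in adult males during deep breathing:
  head-foot 84/81 mm (right/left), right-left 4 mm, anterior-posterior
  14 mm.
- **Breathing period.** Default 6.0 s (10 cycles in 60 s, inside the
  plausible 6–10 s range).  The default and the randomised-study periods
  (6.0, 7.2, 8.4, 9.6 s) are multiples of twice the frame interval, so the
  sampled phase attains exactly 0 and 1 and the ground-truth end-phase
  frames are unambiguous.  Ties across identical cycle peaks resolve to the
  earliest frame.
- **Rendering.** Frames are rasterised with 4× supersampling and block
  averaging, i.e. area-weighted anti-aliasing, so sub-pixel wall motion
  (a few mm at 2.6 mm raw pixels) is encoded in partial-volume intensities.
  Noise is i.i.d. additive Gaussian (default σ=5, 5% of tissue intensity),
  clipped at zero; at the SNR regimes studied the difference from Rician
  magnitude noise is immaterial to contour detection, and Gaussian keeps
  the analytic oracle simple.
- **Irregular cycles.** `inject_irregular_cycle` regenerates one breathing
  cycle with a scaled amplitude and updates the ground truth (an upscaled
  cycle can relocate the global end-inspiratory frame).
- **What the phantom does not emulate:** cardiac motion, through-plane
  motion and body rotation, B1 inhomogeneity, Rician noise statistics,
  k-space artefacts, and anatomical texture.  Passing phantom tests shows
  the *analysis chain* is correct and unbiased under the modelled
  conditions; it does not certify performance on clinical images.

## Preprocessing

Per frame, in order: bilinear upsampling to 512×512 (spacing rescaled so
the physical extent is conserved), 3×3 median denoising, Sobel gradient
magnitude `sqrt(Gx²+Gy²)` kept in floating point, per-frame iterative
intermeans (IsoData) thresholding, and morphological thinning to
single-pixel-wide contours.  Filters replicate edges at the borders.
Choices where the workflow is conventionally underspecified:

- *Bilinear interpolation*: matches common default resize behaviour and
  introduces no ringing.
- *Per-frame thresholds* (logged): robust to slow brightness drift.
- *Thinning*: Zhang-style thinning iterated with a 2×2-block cleanup to a
  fixed point, so the result is idempotent and never contains a fully
  foreground 2×2 block.
- *Spur pruning* (default 5 px): junction-based — from each curve endpoint
  the branch is walked and deleted only if it reaches a junction within the
  pruning length; open curve fragments are preserved (naive endpoint
  erosion destroys noise-fragmented diaphragm ridges), and isolated specks
  of ≤3 px are dropped.

## Kymograms, diaphragm trace, and phases

A 1D kymogram is one row or column of the processed stack tracked across
all frames (space × time).  Measurement axes are placed from manually
identified anatomical landmarks exactly as a human observer would: each
head-foot column is the midpoint (rounded half-up) of the two
hemidiaphragm dome endpoints; the right-left row is the midpoint between
the lateral inferior diaphragm edge and the uppermost thorax point; the
anterior-posterior row the midpoint between the dorsalmost inferior
diaphragm edge and the uppermost thoracic cavity point.  For phantom runs
the landmarks come from the closed-form geometry.

The diaphragm trace is extracted from a y-t kymogram inside a user-supplied
search band: the contour crossing nearest the previous position (strongest
gradient at the first frame), refined to sub-pixel precision by the local
centroid of gradient magnitude.  When noise locally erases the binarised
contour, the strongest gradient ridge within 15 px of the previous position
substitutes (recorded in `fallback_mask`); times with neither remain
invalid, and a trace with >20% invalid times is rejected.

Two manual steps of the original workflow are replaced by deterministic,
configurable rules:

- **Cycle exclusion.** Cycles are segmented trough-to-trough; a cycle is
  excluded when its amplitude or duration deviates from the median by more
  than `k·max(MAD, floor)` with `k = 3` (floors 0.7 px / 0.5 frames keep a
  perfectly regular series, whose MAD is zero, from being flagged).  A
  trailing partial cycle is never amplitude-flagged.
- **Phase detection.** End-inspiration/end-expiration are the global
  extremes of diaphragm descent over all included times, regardless of
  cycle.  To make the choice noise-tolerant, a time is a candidate when it
  lies within 2 mm of the global extremum of any of three views of the
  trace — the raw values, a 3-frame temporal median, or a 3-frame temporal
  minimum of the signed trace.  The median bar discounts readout outliers
  sitting on a peak, the raw bar discounts outliers next to a peak, and
  the minimum bar is immune to any single-frame outlier (three consecutive
  frames must all be extremal).  The earliest candidate cluster wins, and
  the exact frame is the raw-trace extremum inside it.  With zero
  tolerance this reduces to "argmax, ties to the earliest frame", which is
  the behaviour on noiseless data.

## Measurement

At the two detected time points, the thoracic dimension along the
kymogram's spatial axis is the distance between lung contours, strictly
orthogonal to the time axis: upper-to-lower lung contour for head-foot,
outermost contours across both lungs for bilateral right-left, and
anterior-to-posterior lung contour for sagittal planes.  Contour crossings
partition the spatial line; interior segments are classified as lung when
their mean denoised intensity falls below the midpoint of the darkest and
brightest interior segment means, and extra crossings resolve to the
outermost qualifying pair with a logged note.  Distances are converted to
mm with the post-interpolation spacing (500/512 mm/px by default).

Expansion is defined as end-inspiratory minus end-expiratory dimension.
Negative values are reported, not clamped: the global-extremum phase rule
can in principle yield non-maximal spans in orthogonal directions, and
transparency is preferred.

## Statistics

- **ICC** (single measures) from the classical mean-squares decomposition:
  one-way random, two-way random absolute agreement (default), and two-way
  mixed consistency; 95% CIs from the corresponding F-distribution bounds
  (Satterthwaite approximation for the agreement form).  Negative estimates
  are reported as computed and interpreted as "negative/no agreement";
  zero-variance matrices yield a flagged degenerate result, not a silent 1.
  Interpretation bands: 0.00–0.20 slight, 0.21–0.40 fair, 0.41–0.60
  moderate, 0.61–0.80 substantial, 0.81–1.00 near-perfect.
- **Wilcoxon signed-rank** (paired, two-sided): exact null distribution via
  dynamic programming over doubled mid-ranks — equivalent to full 2ⁿ
  enumeration — for up to 25 nonzero differences; normal approximation with
  continuity and tie correction beyond.  Zero differences are dropped
  before ranking (classical convention); the inclusive Pratt convention is
  available via `zero_method="pratt"`.
- **Benjamini–Hochberg** step-up adjustment, returned in input order and
  capped at 1.  Note the adjustment is not idempotent in general
  (`bh([0.1, 0.9]) = [0.2, 0.9]`, adjusting again gives `[0.4, 0.9]`); the
  guaranteed invariants are `adjusted ≥ raw`, the cap at 1, and
  monotonicity in the sorted order.

## Validation studies and problem sizes

`mrkymo.validation` contains the seeded studies run by the test suite and
by `scripts/acceptance.py`:

- *Expansion recovery*: 50 three-plane phantom sessions, amplitudes drawn
  from observed physiological ranges (head-foot 60–90 mm, right-left
  3–10 mm, anterior-posterior 8–20 mm), with per-session resting anatomy
  (diaphragm rest row 35–45 mm, thorax semi-axes ±7 mm) emulating
  inter-subject variability — this also prevents a shared sub-pixel rest
  position from turning quantisation error into a systematic bias.
  Sessions use 18 s series (31 frames, 3 cycles) at the native 192→512
  resolution.  Checks: per-direction mean absolute error ≤ 2 mm and
  |bias| ≤ 1 mm.
- *Phase detection*: 100 runs at 128→352 resolution (frame indices, not
  millimetres, are under test), 24 s series, amplitude 20–90 mm, period
  from {6.0, 7.2, 8.4, 9.6} s, noise up to 10% of tissue intensity.
  Checks: ≥95% exact-frame recovery, 100% within ±1 frame.
- *Cycle flagging*: 100 synthetic traces (8 cycles) with one injected cycle
  at 0.2–0.5× or 1.8–2.2× amplitude; sensitivity ≥95% with zero false
  flags on clean noisy traces.
- *ICC CI coverage*: 1000 one-way variance-component matrices (n=5, k=2,
  true ICC 0.8) assessed with the matching one-way model, whose F-bounds
  are exact under that model; coverage must fall in 93–97%.

## Known limitations

- Landmark identification is not automated; the package implements the
  midpoint arithmetic and accepts landmark tables (or analytic phantom
  landmarks), matching the intentionally segmentation-free design.
- The published ICC form and CI method behind comparable studies is rarely
  stated; reported ICCs therefore always carry their model label.
- The measurement chain localises edges on the interpolated grid, so
  single-measurement precision is on the order of one interpolated pixel
  (~1 mm); sub-millimetre directions (right-left) are proportionally the
  noisiest, which mirrors what reproducibility analyses of this method
  observe.
- No area- or volume-based expansion, no breathing-rate spectral analysis,
  no registration between frames (the method deliberately observes motion).
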