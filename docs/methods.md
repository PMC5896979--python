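# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and direction conventions

Pixel coordinates are 0-based with y increasing downward. After
registration the constriction rows are horizontal, and successful passage
is movement toward decreasing y ("up"). The `migration_direction` setting
mirrors every boundary comparison for devices mounted the other way;
mirrored trajectories produce identical events (tested).

## Device registration

Pillars are detected on a transmitted-light frame: the intensity-normalized
frame is edge-filtered (Canny, σ 2), a circular Hough transform is
evaluated over a radius interval (`hough_radius_range_px`, default 6–14 px,
sized to the synthetic device — real devices should set it from their pillar
radius), accumulator peaks weaker than `sensitivity` (default 0.6) times the
strongest peak are dropped, and overlapping detections are suppressed
greedily, keeping the stronger peak. Because accumulator peaks are
integer-quantized, each accepted center is refined to the darkness-weighted
centroid of the pixels inside its circle; this brings center errors from
~1 px down to ~0.2 px and is what makes the 0.2° rotation target reachable
with 12–24 pillars.

Rows are clustered by scanning centers in y: a gap larger than twice the
median pillar radius starts a new row. The rotation estimate is the
size-weighted mean of per-row line-fit angles, negated (it is the
*correcting* angle) and wrapped into (−45°, 45°]. The whole stack is rotated
once, by the angle estimated from frame 1, with bilinear interpolation;
vacated corners are filled with the per-channel median. Pillars are
re-detected on the rotated frame before building geometry.

Each row gets a centerline (mean pillar-center y), entry/exit boundaries at
exactly `boundary_offset_um` (default 7 µm) above and below it in pixels,
and constriction x-centers at the midpoints between adjacent pillars. The
7 µm default reproduces the boundary placement that best matched expert
manual annotation of transit events in the experiments this pipeline
automates; it is the single most consequential tunable, since it defines
what "entering" and "exiting" a constriction means. A device with a row
count other than three triggers a warning, not an error.

## Pre-processing and stabilization

Fluorescence channels are smoothed with an isotropic Gaussian, σ 2.5 px,
kernel truncated at radius 5 (≈10-px support). Smoothing feeds the
*detection* path only; all reported intensities (and hence the rupture
ratio) are measured on raw channels, so ratios are not blur-dependent.

Stage drift is estimated on the transmitted-light channel — the most stable
content — as the integer-pixel offset maximizing the normalized
cross-correlation of each frame's central region (inset by `max_drift_px`,
default 20 px) against its predecessor, chained into offsets relative to
frame 1. Per-step estimates beyond `max_drift_px` are clamped with a
warning; flat frames yield (0, 0) with a warning. Stabilization translates
every channel of a frame by the same integer offset (no subpixel
resampling, so stabilization never blurs data), filling vacated borders
with the channel median. A brute-force search over all integer lags serves
as the test oracle for the correlation peak.

## Nucleus segmentation

Detection runs on the smoothed chromatin channel in five steps:

1. **Adaptive threshold.** Foreground is pixels above the local mean
   (window `threshold_window_px`, default 51 px) minus an offset of
   `threshold_offset_frac` (default 2 %) of the frame's dynamic range;
   robust to smooth illumination gradients. Holes (chromatin texture) are
   filled; border objects are kept.
2. **Half-maximum refinement.** The local-mean rule is deliberately
   inclusive and hugs the blurred skirt of each nucleus, inflating areas by
   tens of percent. Each candidate blob is therefore re-thresholded at the
   midpoint between the frame background (median) and the blob's own peak:
   for a Gaussian-blurred step edge the half-maximum contour sits on the
   true boundary. Blobs whose peak does not clear the background by
   `min_contrast_sigmas` (default 8) robust noise widths (1.4826 × MAD) are
   noise clusters and are dropped — a field of view without nuclei yields no
   objects.
3. **Watershed splitting.** Touching nuclei are separated on the inverted
   Euclidean distance transform of the mask. The EDT is first smoothed
   (σ 1 px) so boundary pixelation cannot spawn spurious minima; minima
   shallower than `h_depth` are removed with an h-minima transform
   (morphological reconstruction by erosion), the watershed is computed
   with watershed lines, and the mask is cut along the lines (4-connected
   relabeling, so a 1-px line genuinely severs the pieces). A single-basin
   object is left uncut. `h_depth` defaults to 1.0 px: with the smoothed
   EDT, spurious minima are far shallower than 1 px while the saddle between
   two genuinely touching nuclei — measured on rendered pairs after the
   10-px blur, which substantially fills the concave neck — is 1.3–2.3 px.
4. **Constriction exemption.** A nucleus squeezing through a pore assumes a
   dumbbell shape whose waist the watershed would cut. Any split object
   whose bounding box overlaps a row's boundary band near a constriction
   x-center (within half the median pore spacing) is restored to its
   pre-watershed connected component.
5. **Filtering and measurement.** Objects outside
   [`min_area_um2`, `max_area_um2`] (defaults 30–600 µm²) or with
   circularity 4πA/P² below `min_circularity` (default 0.3) are removed;
   in-band objects are exempt from the circularity test only (their
   deformation is physiological). Per-object centroid, half-open bounding
   box, area and per-channel raw means are measured with standard region
   properties.

## Tracking

Every pairing of a nucleus in one frame with one in the next is scored
E = d² + w_I·|ΔI| + w_A·|ΔA| with d the centroid distance in px, I the mean
chromatin-marker intensity, A the area in px², and w_I = w_A = 2. The units
are deliberately mixed — this is the established form of the cost, kept
verbatim; the weights are configurable. Candidates are limited to
centroid displacements of at most `max_distance_um` (default 40 µm,
converted by the pixel size). Pairs are accepted greedily in ascending E
(ties broken by lexicographic index order), each accepted object becoming
unavailable, until no admissible pair remains. Linking is strictly
frame-to-frame: a missed detection ends the track and a new track begins —
no gap closing, by design. A reference implementation that repeatedly
extracts the global-minimum admissible pair is the oracle in tests.

## Transit events

For each track and row, each frame is classified from the bounding box:
*attempting* if the leading edge has crossed the entry boundary while the
trailing edge has not cleared the exit boundary; *passed* once the trailing
edge fully clears the exit boundary; *outside* otherwise. Entry is the
first attempting frame; a success's exit is the first passed frame
(transit time = (exit − entry) × frame interval); a failure's exit is the
last attempting frame. Attempts lasting exactly one frame are discarded
regardless of outcome — they are grazes from motion parallel to the row —
so a genuine transit must spend at least two frames in the band (at the
default 7-µm boundaries and 2–10 min intervals this costs no real events).
A track ending mid-attempt yields outcome `ongoing`, excluded from
transit-time statistics. An event starting within one frame of the previous
event's end on the same track and row is flagged `adjacent_to_previous`:
such back-and-forth struggles are reported as two events, with the flag
marking that a human analyst might read them as one long attempt.

## NE rupture and mitosis

The per-track ratio r_t = mean chromatin marker / mean reporter is computed
on raw intensities; since both channels bleach together, r is invariant
under any per-frame global rescaling (tested exactly). A rupture starts at
frame t when Δr_t > `jump_frac`·r_{t−1} (default 20 %), or when r rises
over `rise_len` (default 5) consecutive time points, the start assigned to
the run's first frame. Each step of a qualifying rise must exceed
`min_rise_frac` (default 1 %) of the running ratio: a literal
strictly-increasing rule fires on chance monotone runs in pure noise at
rate 1/rise_len! per window, which is far too often for a usable detector,
while genuine slow ruptures rise several percent per frame. Plateaus and
sub-floor increments break the run.

The event ends at the first frame past the (running) peak where
r_t ≤ (1 + `baseline_tol_frac`)·baseline and |Δr_t| ≤
`delta_zero_tol`·baseline (defaults 0.10 and 0.05; the baseline is r at the
last pre-rupture frame). A trace that never recovers leaves the event open
and out of duration statistics. Triggers inside an open event are merged
into it. For cross-population repair-dynamics plots, an event's trace can
be normalized — expressed relative to its pre-rupture value and scaled to a
peak of 1 (range [0, 1], tested).

Mitotic envelope breakdown looks identical at onset, so each candidate is
checked for a new track appearing within `mitosis_window` (default 1)
frames of the start and within `vicinity_um` (default 40 µm, the tracking
gate) of the nucleus; if found, the candidate becomes a mitosis event
linking parent and daughter(s) — note the tracker continues the parent
track into one daughter, so a division typically yields one *new* track —
and no rupture is recorded.

## The synthetic generator

Scenarios script a pillar grid (three rows of round pillars; pitch 24 px,
radius 8 px, rows 55 px apart by default), nuclei as ellipses (default
semi-axes 12 × 8 px = 24 × 16 µm at the default 1 µm/px — a large, flat
adherent cancer-cell nucleus), per-frame centers and channel levels,
integer stage drift, a global photobleaching factor and per-channel
Gaussian noise (default σ 6–10 counts against 400–900 counts of nuclear
contrast). Frame intervals default to 10 min (2 min is the other
experimentally common choice). Device rotation and drift are applied
analytically to all scripted positions before rasterizing, so ground truth
is exact for the rendered images; per-nucleus ground-truth centroids,
bounding boxes and areas are measured on each nucleus' own noise-free mask.
A nucleus whose center lies within its semi-minor axis of a row centerline
is rendered as a dumbbell — two lobes bridged through the pore, with the
same total extent along the migration axis as the ellipse, so
bounding-box-based transit logic sees a consistent object. During scripted
ruptures the reporter level inside the nucleus drops to realize the
scripted ratio trace, with a cosmetic cytoplasmic halo.

Fixed, seeded suites drive the benchmarks: `registration_suite` (rotations
−5°…+5°, 12–24 pillars), `tracking_suite` (a standard scene: 12 nuclei over
50 frames, two overlapping pairs, sawtooth drift, mild bleaching),
`transit_suite` (20 scripted trajectories: 8 successes, 6 failures, 4
one-frame grazes, 2 ongoing attempts, with boundary crossings placed 5 px
clear of the decision lines so segmentation jitter cannot shift event
frames), and `rupture_suite` (24 ratio jumps of 10–60 %, 6 sustained rises,
10 divisions, 10 flat controls; recovery traces end with a small final step
so the scripted end frame coincides with the rule-based end). Scenario
problem sizes (≈200 × 220 px, 40–50 frames) keep the full benchmark suite
in the low minutes on one core.

**What the benchmarks do not show.** The generator renders hard-edged
ellipses with Gaussian noise — no optical point-spread function, shot
noise, chromatin texture, cytoplasmic autofluorescence, focus drift, or
cell-shape irregularity. Perfect scores on the suites therefore demonstrate
the correctness of the algorithms and their integration, not expected
performance on real microscopy, where segmentation thresholds, `h_depth`,
area/circularity bounds and the Hough radius range will all need
recalibration to the imaging conditions. Separations used for the
touching-pair fixtures (1.75 × the ellipse radius along the pair axis) were
likewise chosen so a neck exists after blurring; two nuclei overlapping
more deeply than that are not reliably separable at this blur-to-size
ratio by any distance-transform method.

## Other design choices and limitations

- The spatial calibration of all defaults is the synthetic device; nothing
  in the algorithms assumes it.
- Rotation is estimated once, from frame 1, and applied to all frames;
  devices do not rotate mid-experiment.
- Stabilization is integer-pixel and rigid; rotational or non-rigid drift
  is out of scope.
- The interactive correction GUI that a full deployment would offer is
  replaced by overlay rendering plus hand-editable CSVs.
- Input is multi-page TIFF / OME-TIFF (axis order from metadata, TCYX
  assumed for bare stacks); proprietary formats should be converted first.
- Cell-death detection (permanent reporter loss) is not implemented.
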