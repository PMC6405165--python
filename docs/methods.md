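# Methods

`fishscreen` re-implements, as one tested pipeline, the semi-automated
analyses used in 96-well time-lapse screening of fish embryos: ratiometric
fluorescent-protein quantification, anaesthesia movement scoring,
randomized plate design, cross-species intensity comparison and
codon-adaptation metrics. A synthetic plate generator with full ground
truth makes every stage verifiable without any external image data. This
note documents the models, the defaults and the design choices made where
the analysis recipe left the design open.

## The synthetic plate generator

The generator emulates two acquisition designs on a 96-well plate.

**Fluorophore assay.** Each occupied well holds one embryo, rendered as a
disk of radius `embryo_radius` (default 14 px in a 64 px field). Embryos
are injected at the one-cell stage with a test-fluorophore mRNA plus a
reference mRNA (mCherry-like); both scale with the same per-well
injection-volume factor *v*, drawn log-normal with mean 1 and the
configured coefficient of variation. That shared factor is the premise of
ratiometric normalization, and the generator enforces it by construction.
Expression follows a two-timescale kinetic,

    I(t) = v · b · (1 − exp(−t / τ_mat)) · exp(−t / τ_dec),

with *t* in hours post fertilization (hpf), a maturation time `τ_mat`
(default 3 h) and a slow decay `τ_dec` (default 30 h) reflecting the loss
of signal after an mRNA bolus. These defaults are stand-ins chosen to
expose both timescales inside a 40 h acquisition window; no per-embryo
kinetic parameters are available to calibrate them. A parabolic
attenuation across the z-stack (30% at the outer slices) is shared by
both channels, so it exercises z-aggregation without touching channel
ratios. Pixel noise is Gaussian with

    sd = noise_sd + noise_fraction · clean_intensity,

an absolute read-noise term plus a shot-like term proportional to the
noise-free intensity. Images are quantized to 16-bit grayscale TIFF,
matching plate-imager output.

**Anaesthesia assay.** A single brightfield slice per timepoint; the
embryo is rendered darker than background (8 000 vs 20 000 counts) and its
centroid performs a random walk with a fixed step length equal to the
condition's `movement_amplitude` (px/frame) and uniform heading, clamped
to keep the disk in the field (clamping is recorded in the ground truth).
A fully anaesthetized condition has amplitude 0.

**Dead wells.** Each well is dead with probability `dead_well_fraction`;
dead wells show background only in the fluorescence channels and a
motionless embryo in brightfield. Every drawn quantity — condition,
volume factor, per-channel brightness, death flag, centroid track,
clamping — is recorded in the `GroundTruth`.

Identical configuration and seed give bit-identical output; all draws go
through one seeded generator in a fixed well/time/channel/z order.

What the generator does **not** emulate: optics (PSF, chorion refraction,
pigment autofluorescence), intensity texture inside the embryo,
multi-embryo wells, stage-dependent morphology. Tests passing on this
material therefore validate the measurement arithmetic — segmentation
conventions, normalization algebra, QC logic, index definitions — not
robustness to real-world image texture.

## Segmentation and measurement

Otsu's threshold is computed on a 256-bin histogram over the observed
intensity range; the returned value is the centre of the best background
bin, ties going to the lowest threshold, and foreground is strictly above
the threshold. A constant image raises an error (no separable classes).
The implementation is verified per-image against an exhaustive
between-class-variance scan and, on float images, against scikit-image.

For the dual-channel assay the mask of a well/timepoint/z-slice is the
intersection of both channels' Otsu foregrounds — the only combination
under which one region is measured in both channels — and both channels
are measured with that same mask. Statistics (mean, median, sample sd,
area) are taken over masked pixels only: background is excluded, never
subtracted. The mean of the pixels outside the mask is carried along as
`bg_mean` for QC. A single-pixel region has sd defined as 0.

The 12-slice z-stack is collapsed per timepoint by area-weighted pooling:
the aggregate mean and sd equal those of all pooled masked pixels (the
pooled sd is reconstructed exactly from per-slice moments). A pooled
median is not recoverable from slice statistics, so the aggregate median
is the area-weighted mean of slice medians. Which z-aggregation the
original recipe used is unstated; pooling was chosen as the convention
that is exactly testable against a per-pixel oracle.

The light-sheet verification measurement divides the test stack by the
control stack per z-slice (control-zero pixels excluded so no non-finite
values propagate), masks the ratio image by its own Otsu foreground and
reports ratio statistics per slice — one measurement per z-slice is the
sample unit of the group comparisons. A constant ratio image (e.g. a
stack divided by itself) has no Otsu threshold; all control-positive
pixels are measured instead, which keeps the self-ratio identity exact.

## Normalization, QC, fusion, ranking

Each test trace is divided by its own well's reference-channel value at
the acquired timepoint nearest 10 hpf — no interpolation, since 20/33 min
grids never sample 10.000 hpf. Per-well division (rather than dividing by
the plate-mean reference) is the default because it is what cancels
per-well injection volumes; the two coincide when volumes are equal.
Wells whose reference value is missing or non-positive are excluded as
negative wells.

QC follows the checked-at-checkpoints rule: at the final timepoint and at
the series midpoint, a well must have mask area ≥ `min_area` (default 50
px) and masked mean ≥ `min_signal_ratio` (default 2) times the
outside-mask background mean. The thresholds are configuration, not
inference: the original recipe states no quantitative rule. The background-ratio
test presumes read noise well below the background level; with noise of
the order of the background, a noise-only well's Otsu mask skims the
upper noise tail and can pass the ratio test.

Plate fusion rescales every plate by the ratio of control-condition means
over the plates' common time window, the first plate being the reference.
A window mean, rather than a single timepoint, is robust to single-frame
noise and reduces to simple proportionality when curves are proportional.
Fusion is a fixed point: fusing an already-fused set returns factors of 1.

Conditions are ranked by descending mean normalized intensity at the
timepoint nearest the query time, ties broken alphabetically. The
cross-species comparison takes each condition's mean over an hpf window
(bounds inclusive; 23–30 hpf in the reference workflow) and rescales each
colour class so its normalizer maps exactly onto its external reference
value — the yellow normalizer (Venus) onto 1.2 — making the table
invariant to any common rescaling within a class.

Group comparisons use the two-sided Mann–Whitney rank-sum test (the
original workflow names only a plotting helper, not a test; rank-sum is
the distribution-free default for such figures). Stars follow the legend
thresholds as inclusive upper bounds: p ≤ 1e-4 `****`, ≤ 1e-3 `***`,
≤ 1e-2 `**`, ≤ 0.05 `*`, else `ns`.

## Movement index and stage alignment

The movement index of a frame pair is the mean over pixels of the squared
intensity difference, timestamped at the later frame. Mean rather than
sum makes the index independent of image size; the convention is recorded
on the trace. No registration or background subtraction is applied,
mirroring the minimal recipe. On integer frames the index is computed in
exact int64 arithmetic with one final division, so it is bit-reproducible
against any exact per-pixel evaluation. For a motionless embryo the index
equals the camera-noise floor, 2σ² for per-frame noise of sd σ (plus a
negligible quantization term); a moving embryo adds the squared
embryo/background contrast along the displaced outline, which makes the
index strictly monotone in the programmed displacement.

Plates started at different developmental stages are aligned by
user-supplied offsets (staging is manual): time 0 is the most advanced
plate's starting stage, and each plate's times are reduced by the native
time at which it reaches that stage. Rows outside the common overlap are
kept but flagged. Summaries (mean, sd, n per condition and timepoint) are
computed on each plate's native sampling grid; mixed 20/33-min plates are
not resampled.

## Codon metrics

Relative adaptiveness follows Sharp & Li: within each synonymous family,
w = f / max f, with zero frequencies replaced by a 0.5 pseudo-count
first. The CAI is the geometric mean of w over the sequence, computed in
the log domain; ATG, TGG (single-codon families, w ≡ 1) and stop codons
are excluded by default, configurably. Per-thousand frequencies and raw
counts are interchangeable because only within-family ratios enter.
Back-translation ("codon averaging") picks per residue either the
most-frequent codon (ties alphabetical) or a codon sampled from the
within-family frequencies with a fixed seed; the output always translates
back to the input protein. The exact optimizer used originally has
unpublished internals and unversioned usage-table snapshots, so published
CAI scatter values are not bit-reproducible and are not targeted.

## Plate design

Layouts are seeded uniform permutations of the requested condition labels
over the plate (row-major A1…H12 naming); unused wells are explicit
`empty` records so downstream joins can distinguish "empty by design"
from "missing file". Counts are preserved exactly; position frequencies
are uniform over seeds (chi-square checked in the tests). Blocking and
edge-well avoidance are out of scope.

## Problem sizes and numerical conventions

The canned protocols (`fishscreen.protocols`) fix the simulated study
conditions: the fluorophore panel is a full 96-well plate with 8
conditions × 8 wells, programmed ratios 0.25–4×, injection CV 30%,
signal-proportional noise at 5%, 64 px images, 3 z-slices and 21
timepoints (2–12 hpf at 30 min); the anaesthesia panel uses amplitudes
{0, 1, 2, 4} px/frame at read noise sd 50; the viability panel a 20%
dead-well rate with clear signal margins. These sizes preserve each
assay's signal-to-noise structure while keeping a full end-to-end run in
the seconds range. With no background subtraction, the residual
background inside the mask biases recovered brightness ratios by roughly
`bg/signal`; at the panel's 20-count background this is ~2% at the
dimmest condition, well inside the 10% recovery target the tests check.

## Known limitations

- Segmentation assumes the embryo brighter than background in
  fluorescence channels and darker in brightfield, as the simulator
  renders; inverted-contrast modalities need an inverted convention.
- The QC signal-ratio rule degrades when noise ≈ background (above).
- The uniform-disk embryo makes Otsu segmentation nearly exact; real
  embryos' texture would add mask jitter the tests do not probe.
- Stage alignment shifts time only; it does not warp developmental rate.
- Codon metrics use the standard nuclear genetic code only.
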