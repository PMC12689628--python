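# Methods

This note documents the models and procedures implemented in `sleepedit`,
the parameters that matter, what the synthetic-data generators emulate (and
what they do not), and the design choices made where the procedure left room.

## 1. EEG/EMG spectral analysis (`sleepedit.eeg`)

### Preprocessing

Signals stored at 512 Hz are band-pass filtered per channel — 0.1–48 Hz for
EEG, 10–30 Hz for EMG — with a 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), then decimated with an anti-aliasing FIR
stage to 128 Hz. Zero-phase filtering is used because epoch boundaries must
not shift relative to the hypnogram. The output rate must divide the input
rate; other combinations raise.

### Epoch spectra

Spectral power is computed per 4-s epoch with a Welch estimate at 0.25 Hz
resolution and no overlap. At 128 Hz a 4-s epoch is exactly 512 samples, so
this configuration *forces* a single Hann-windowed 512-sample segment: the
Welch estimate degenerates to one windowed periodogram per epoch, with the
standard window power correction (`scipy.signal.welch`, `detrend=False`).
This is the only configuration consistent with the stated parameters, and it
is what the implementation does. A trailing partial epoch is dropped.
White-noise total power is conserved within a few tenths of a percent
(Parseval), and a pure on-grid tone concentrates all of its power in its
quarter-bin ± one neighbour (Hann main lobe).

### Rebinning

Quarter-bins are averaged into a hybrid scheme: 0.5 Hz bins over 0.5–5 Hz
and 1 Hz bins over 5.25–25 Hz — 10 + 20 = 30 bins. Bin labels are **upper
edges**: the 0.5 Hz bin labeled *f* averages quarter-bins *f*−0.25 and *f*;
the 1 Hz bin labeled *g* averages *g*−0.75 … *g*. The 1 Hz range is read as
quarter-bins 5.25–25.0 grouped in fours, so the first 1 Hz bin is labeled
6. The source material does not pin the label convention; this one is
documented here and is what `default_bin_labels()` returns. Mean power over
any covered range is conserved by construction.

Band membership is inclusive at both edges in label space: delta/SWA
1.0–4.5 Hz resolves to labels {1.0, 1.5, …, 4.5} (8 bins), the narrower
delta 1.5–4.5 Hz to 7 bins, sigma 10–15 Hz to {10, …, 15} (6 bins), theta
6–9 Hz to 4 bins.

### Vigilance-state scoring

Machine-learning scorers are deliberately not reproduced; the package ships
a transparent rule-based stand-in built from the same physiological
signatures used to describe the states:

* **WAKE** — epoch EMG RMS > `k_emg` × median epoch EMG RMS over the
  recording (default `k_emg = 1.5`). The median is a robust proxy for the
  sleep-level muscle tone as long as the animal sleeps more than half of the
  recording; the synthetic defaults guarantee this (below).
* otherwise **REM** when the theta(6–9)/delta(1.0–4.5) band-mean ratio
  ≥ 2.0, **NREM** when ≤ 1.0, and **TREM** (transition to REM, mixed
  slow-wave/theta) in between.

All three thresholds are exposed in `ScoreThresholds`. On default synthetic
24-h recordings the scorer agrees with the generating hypnogram on ~96–98%
of epochs; residual disagreement is dominated by TREM epochs, whose
band-ratio distribution genuinely straddles both thresholds.

### Architecture, exclusion rule, normalizations

Minutes per state/phase/day are epoch counts × 4 s / 60. TREM epochs count
**into REM durations** but are **excluded from NREM and REM spectra**
everywhere — normalizations, band powers, and the SWA timecourse all honor
this.

Two normalizations are provided:

* **Cross-state**: for each bin *f* and state *s* ∈ {NREM, REM, WAKE}, the
  mean power over *s*-epochs in the queried phase/day divided by the summed
  power of *f* across the three states in the **light phase of recording
  day 1**, × 100. "Summed power across states" is read as the sum of the
  three state means (default, `method="state_mean_sum"`); an alternative
  pooled-epoch denominator is offered (`method="pooled"`) because the
  phrase is ambiguous, but only the default satisfies the identity that the
  three state values sum to 100% per bin on the reference window itself.
* **Within-state**: each bin as a percentage of the state's total power
  over the 30 bins (sums to 100% by construction).

Both are scale-invariant. The SWA timecourse divides each interval's mean
NREM delta power by the mean NREM delta power in **ZT8–12 of day 1** (the
last four hours of the light period), × 100; intervals without NREM are
NaN. The SWA band defaults to 1.0–4.5 Hz (the broader SWA definition);
1.5–4.5 Hz can be passed instead, as the source does not state which band
feeds the timecourse. The EEG derivation defaults to parietal (frontal is
equally supported); recordings are assumed to start at lights-on (ZT0),
with `start_zt` as the override.

No artifact rejection is applied by default; the channel containers make
amplitude-clip flagging easy to add, but none is claimed.

## 2. Editing quantification (`sleepedit.editing`)

Reads are globally aligned to the amplicon reference under affine gap
costs: match +2, mismatch −1, and a length-*L* gap costing 6 + *L* (i.e.
"open 6, extend 1" with the first gap base paying open + extend). The
alignment engine is Biopython's `PairwiseAligner` (its open/extend
convention differs by one extend; the adapter accounts for this); an
independent full-matrix Gotoh implementation exists only in the test suite
as an oracle. Ties take the aligner's first reported optimum, which is
deterministic.

Classification is mutually exclusive with precedence
**indel > edited > other_sub > unedited** over a half-open quantification
window [lo, hi) on the reference:

* *indel*: any deletion of a reference position in the window, or any
  insertion at an interior boundary point (strictly between lo and hi);
* *edited*: the in-window substitution set equals the **full** programmed
  set (edit plus silent mutations) — a partial install or any extra
  substitution in the window demotes the read;
* *other_sub*: any other non-empty in-window substitution pattern;
* *unedited*: no in-window difference.

Editing % = edited / total × 100; indel % = indel-containing / total × 100.
Substitutions and indels outside the window are ignored, mirroring
windowed amplicon quantification; the default window is the programmed
substitution span ± 10 nt and is fully configurable. Note that the read
simulator places indels within ± 20 nt of the edit site (where
nicking-induced indels occur), so indel-rate *recovery* experiments use a
window of at least ± 25 nt so that every simulated indel is eligible.
Reads identical to the reference or to the fully edited reference skip the
aligner — their optimal alignment is gap-free and their category follows
directly — which makes 10^5-read experiments cheap without changing any
result.

Reads are assumed merged and oriented; no quality trimming is applied.
pegRNA-scaffold integrations are not detected separately; such reads
classify as indels.

## 3. Open-field kinematics (`sleepedit.kinematics`)

Instantaneous speed uses a **trailing** 4-frame sliding window: the speed
at frame *i* is the path length over frames [*i*−3, *i*] divided by 3 frame
periods, so a straight line at *v* cm/s reads exactly *v* at every defined
frame. The first 3 frames are NaN. (Whether the window is centered or
trailing is not specified anywhere; trailing is chosen and documented, and
the window length is a parameter.)

Running episodes are maximal runs of frames with speed **strictly above**
5 cm/s (threshold configurable). Average speed = distance covered during
running ÷ time spent running, each running frame contributing one frame
period at its instantaneous speed. Raising the threshold can only shrink
the running set, so running time is monotone non-increasing in the
threshold. Center-zone time counts frames inside the central rectangle
(default: central 50% of each arena side, closed bounds) times the frame
period. Pixel-to-cm calibration is assumed done upstream; input is a
coordinates CSV (either `x_cm/y_cm` or plain `x/y` headers).

## 4. Volume quantification (`sleepedit.volumes`)

Probability maps are binarized at **strictly above 0.2**. Connected
components use 26-connectivity (`scipy.ndimage.label` with a full 3×3×3
structuring element), labeled deterministically in raster order of each
component's first voxel. Per candidate the voxel count, centroid, and
total/mean/standard deviation of the probability are computed; the
**population** standard deviation is used (this only matters for tiny
components). Candidates are retained iff 2 ≤ voxels ≤ 10000 **and**
std/mean ≥ 0.1, all bounds inclusive (the thresholds are described as
minima/maxima without strictness; inclusive is the natural reading).
Filtering is applied at full resolution, before any alignment-related
downsampling, following the order of operations in the procedure.

A plaque is *engulfed* iff at least one of its voxels lies in the binarized
microglia mask (no minimum overlap fraction is imposed); the global
engulfment metric is the microglia-overlapping plaque volume as a fraction
of total retained plaque volume.

Alignment preprocessing (provided for completeness; registration itself is
out of scope) is: 2×2×2 average downsampling (dimensions cropped to even),
intensity capping at a caller-chosen threshold, then an isotropic 3D
Gaussian blur with σ = 2 voxels. Region assignment accepts a precomputed
integer label volume in place of atlas registration and assigns each plaque
by nearest-voxel centroid lookup; label 0 is "unassigned".

## 5. Association statistics (`sleepedit.stats`)

`pearson_ci` implements the product-moment r, the two-sided p-value from
t = r√((n−2)/(1−r²)) on n−2 df, and the 95% CI tanh(atanh r ± 1.96/√(n−3)).
The 1.96 constant is used verbatim rather than the exact normal quantile;
the difference is below 10⁻⁴ in r units. Degenerate inputs (n < 3, zero
variance) raise. `group_summary` reports mean, sample sd (n−1), and
sem = sd/√n per group. Mixed-model ANOVA and post-hoc families are
deliberately not reimplemented — they are off-the-shelf everywhere — so the
module owns only what the analysis pipeline itself computes.

## 6. Synthetic data (`sleepedit.synthetic`)

### Hypnograms

Vigilance states evolve as a first-order Markov chain at the 4-s epoch
scale with separate light- and dark-phase transition matrices over
{WAKE, NREM, REM, TREM}. Structural constraints are enforced: TREM is
reachable only from NREM and leaves only to REM or WAKE. The default
matrices were calibrated once against their stationary distributions to
give ≈65% of total sleep in the light phase (≈71% of the light phase and
≈38% of the dark phase asleep, ≈55% of the day asleep overall, REM ≈15–18%
of sleep) — the qualitative structure of mouse sleep under a 12:12 cycle.
Total sleep deliberately exceeds 50% of the day so that the scorer's
median-EMG reference sits on the sleep side. Bout durations are geometric
(memoryless), which is a simplification of real bout statistics.

### EEG/EMG synthesis

Each epoch is drawn in the frequency domain: amplitude = state target PSD
(1/f^α background, α = 1, flattened below 0.5 Hz, plus Gaussian-shaped band
bumps), phases random. Epochs are stitched with a 0.25-s equal-power
(cos/sin) crossfade so boundaries are click-free. Defaults: NREM has a
strong delta bump (2.5 Hz, integrated power 5.0) and a sigma bump
(12.5 Hz, 1.2); REM a strong theta bump (7.5 Hz, 6.0); WAKE a mild theta
bump (7.0 Hz, 0.8) over the broadband background; TREM mixes a reduced
delta bump (0.6) with a theta bump (2.6), placing its theta/delta ratio
between the NREM and REM scoring thresholds. EMG is white noise at
state-dependent RMS (WAKE 3.0, NREM 0.5, REM 0.3, TREM 0.35, arbitrary
units). Only spectra and RMS levels are modeled — waveform morphology
(spindles as discrete events, slow-oscillation shape, movement artifacts,
electrode noise) is not, so passing tests demonstrate correctness of the
spectral pipeline, not scorer performance on real recordings.

### Reads, volumes, trajectories

Reads: each read is an indel read with probability `p_indel` (one
insertion/deletion, size 1–5 nt, uniform within ± 20 nt of the edit site),
an edited read with probability `p_edit` (full substitution set installed),
else unedited; per-base substitution errors at `p_error` are overlaid.
Quality scores are constant (Q40); quality modeling is a non-goal. Ground
truth is stored per read.

Volumes: plaques are spherical Gaussian blobs whose supra-threshold radius
equals the drawn radius (2–4 voxels by default → ≈30–300 voxels per blob),
peak probability 0.7–0.95, centers rejection-sampled with a minimum
separation of 4·r_max + 4 voxels (an error is raised after bounded
retries). Engulfed plaques (Bernoulli per plaque) receive an overlapping
microglia blob. Background noise is uniform below 0.15 of the binarization
threshold's reach (default 0.05) and combined by maximum so it can never
extend a blob's footprint — this is what makes exact count recovery a fair
test. Real plaques are neither spherical nor isolated; the generator tests
the component/filter/colocalization machinery, not segmentation robustness.

Trajectories: piecewise-constant speed segments with a random-walk heading
(σ = 0.25 rad/frame); steps that would exit the arena bounce, preserving
step length, so total path length equals Σ duration × speed essentially
exactly.

All generators are pure functions of their seed; FASTQ output is
byte-identical across runs.

## 7. Problem sizes in the acceptance script

`scripts/acceptance.py` regenerates everything from the command-line seed:
the worked-example and recovery read sets use 2×10⁴–10⁵ reads; scorer
recovery uses five full 24-h recordings; the cohort experiment runs 100
replicates of 8 control vs 8 treated animals, each animal a 4-h
single-channel recording spanning ZT10–14 (2 h light + 2 h dark) so that
both the day-1 light reference and a dark-phase window exist — the package's
chosen problem size for this experiment; the effect (a 20% NREM delta-bump
reduction) acts at the generator level and detection uses the full
preprocess-free spectral path (PSD → rebin → cross-state normalization).

## 8. Known limitations

* The rule-based scorer is a stand-in; its thresholds were chosen for the
  synthetic profiles and are not validated against scored recordings.
* The cross-state normalization's pooled-denominator variant is provided
  but untested against any external reference; the state-mean-sum default
  is the one with a provable identity.
* EDF files can be read (via `mne`) but not written; signal output is CSV.
  Volumes are TIFF stacks only.
* Alignment treats reads as full-length amplicons; soft-clipping,
  paired-end merging and demultiplexing are out of scope.
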