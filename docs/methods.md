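# Methods

## The inference the pipeline supports

The pipeline asks whether two task states — viewing an object as a
distractor (perception) and holding it as a memory target — engage the same
population code.  The measurement is pairwise linear cross-decoding: a
classifier trained to separate objects A and B in one state is tested on the
other state, and its accuracy is compared with the matched within-state
decoder.  The two accuracies are combined into the cross-decoding ratio
`(cross − 0.5) / (within − 0.5)`.  Under a shared code the ratio is ~1;
under an orthogonal code it is ~0; intermediate rotations give intermediate
values.  Everything else in the package exists to produce valid inputs to
that comparison: unbiased condition-wise response estimates, strictly
independent train/test data, and matched stimulus conditions on both sides
of the classifier.

## Generative model

Each of the four object categories has a perceptual pattern `p_o` (a random
unit vector over the ROI's vertices) and a memory pattern
`m_o = cos θ · p_o + sin θ · q_o`, with `q_o` unit and orthogonal to `p_o`.
θ is the single ground-truth parameter of interest.  A trial contributes:

- `gain_encoding · p_target` while the target image is on screen (one TR);
- `gain_delay · m_target` sustained from target offset to probe onset (a
  boxcar — the simplest course consistent with sustained delay decoding);
- `gain_distractor · p_distractor` at each of the 20 distractor-image onsets.

The neural signal is convolved with a hemodynamic kernel and i.i.d. Gaussian
noise (SD `noise_sd`) is added per vertex and TR; optional linear drift and
AR(1) noise exist but are off by default.  Event-to-TR assignment uses exact
decisecond integer arithmetic so every trial of a condition occupies the
same lags relative to its onset — this is what makes noiseless GLM recovery
exact to machine precision rather than approximately.

### Hemodynamic kernel

Three kernels are available.  `fir_identity` (a unit impulse) exists so that
FIR estimation can be checked against the generative truth exactly.
`double_gamma` is the community-standard shape (peak 5 s, undershoot 15 s,
ratio 6).  The default, `compact_gamma`, is a single gamma peaking at 4 s
with compact support (back to baseline by 8 s).  The default is deliberate:
the delay analysis window starts 8.6 s after target offset precisely so that
it contains no stimulus-evoked response, but the canonical double gamma is
still ~18% of peak 10 s after an event, and that tail is *aligned with the
perceptual code* of the target.  At high SNR the leak alone pushes
distractor→target cross-decoding above chance even when the memory code is
exactly orthogonal, corrupting the ratio's zero point.  With the compact
kernel the delay window is exactly free of stimulus-evoked signal, matching
the window's design intent.  Real HRFs do have long tails; this is a stated
idealization of the generator (see Limitations).

### Default parameters

| parameter | default | meaning / why |
|---|---|---|
| `n_vertices` | 200 | per synthetic ROI; large enough for stable linear decoding, small enough for seconds-scale runs |
| `gain_encoding` | 1.0 | target-evoked perceptual amplitude (arbitrary units) |
| `gain_delay` | 0.35 | sustained memory amplitude; weak relative to perception |
| `gain_distractor` | 0.8 | per distractor image (~2 images per TR), giving a per-TR distractor drive ~3.7× the memory signal: distractor decoding saturates at 1.0 while the memory signal stays the weaker of the two |
| `noise_sd` | 0.45 | per-TR, per-vertex; places default decoding in the high-SNR regime (see below) |
| session plan | [13, 14] | the canonical two-session run count with the fewest runs |

The noise default is chosen so that the ratio is *calibrated*: at θ = 0 it
sits at 1 and stays within a few percent of 1 when all gains are halved.
This requires both the within- and the cross-trained classifier to estimate
a near-ideal boundary.  At lower SNR (e.g. `noise_sd` ≈ 2–3, within-decoding
~0.6–0.7, closer to empirical accuracies) two opposing biases appear: the
classifier trained on the strong distractor signal beats the weakly-trained
within classifier (pushing the ratio above 1 under a shared code), and the
common signal components that differ between train and test sets shift the
decision boundary (pushing cross-decoding down).  Both are properties of the
measurement, not bugs; the package's defaults simply choose the operating
point where the ratio means what its name says, and both regimes are
reachable through configuration.

## Estimation

Runs are detrended per vertex (linear + quadratic).  The FIR design has one
indicator column per (condition, lag) — 16 × 30 = 480 columns spanning 24 s
from trial onset, with trial onsets rounded to the nearest TR (half-TR ties
round up).  Because each condition occurs once per run with mostly 2 s
intertrial gaps, single-run estimates are unidentifiable; runs are combined
under the split plan: runs are split by index parity within each session
(odd half takes the extra run), a 7-run half contributes its seven 6-run
combinations, a 6-run half its six 5-run combinations plus the full set —
seven estimates per split, 28 in total, with no run shared between splits.
Each combination is fitted jointly by OLS with per-run polynomial nuisance
regressors (order 0–2).  The nuisance order matches the detrending basis on
purpose: by the Frisch–Waugh argument the stimulus betas are then identical
to those of a joint fit on raw data, so noiseless recovery is exact; with
intercept-only nuisance the detrending step would leak the polynomial
projection of the stimulus signal into the betas.  Fitting uses per-run
sparse cross-products accumulated once and reused across all 28
combinations (a ~500×500 normal-equation solve each), so a full participant
estimates in under a second.  A rank-deficient design raises an error
naming the collinear (condition, lag) columns.

Period patterns average exactly four lags (closed intervals): encoding
4.0–6.4 s (lags 5–8), delay 9.6–12.0 s (lags 12–15).

## Decoding

Patterns are z-normalized across vertices (population SD) to remove
amplitude differences between conditions, periods and ROIs.  The classifier
is a linear SVM with C = 1 (the community default for this software
lineage); boundary ties resolve to the first class in sorted label order.
Decoding is always pairwise: with four categories, a target never shares a
trial with a same-category distractor, so distractor identity is unbalanced
across target classes and any four-way decoder would read out the much
stronger distractor signal.  The interface rejects multiway label sets with
an explanatory error.  For each unordered object pair the irrelevant object
(the trial's other role) is held fixed — matched between train and test by
default, with a `different` option for the control analysis.  Rotation:
train on three splits (21 patterns per class), test on the held-out split
(7 per class), average the four rotations; provenance guarantees no run
contributes to both sides.  Distractor→target cross-decoding runs in one
direction only, because distractor decoding saturates and would not track
signal strength in reverse; encoding↔delay cross-decoding averages both
directions (neither saturates in general).  Scheme accuracies average over
pair instances; ROI-level results average into sectors (posterior V1–V4,
ventral LOT/VOT, dorsal IPS2–IPS4) with equal ROI weights, so large ROIs do
not dominate.

The ratio is computed per participant and, separately, from
participant-mean accuracies (both appear in `ratios.tsv`; the choice of
level is not settled by convention, so both are reported).  A ratio whose
within-decoding margin over chance is ≤ 0.01 is flagged invalid rather than
dropped.

## Group statistics

Against-chance and drop tests are one-tailed by specification (only
above-chance decoding, and only within ≥ cross, are meaningful); sector
pairwise comparisons are two-tailed.  Benjamini–Hochberg correction is
applied within explicit families — the tests of the same type within a unit
(ROI or sector), and the three sector pairs — and every table carries both
raw and adjusted p values, with the family identifier, so the correction
can be re-audited.  The two-way repeated-measures ANOVA partitions
within-subject sums of squares with each effect tested against its own
subject-interaction error term; no sphericity correction is applied (noted
in the report metadata).  Degenerate designs reduce correctly: with a
2-level factor against a 1-level factor, F equals the paired t².  All-equal
data at the null mean reports t = 0, p = 0.5; zero-variance data away from
the null reports NaN rather than a fabricated statistic.

## What the synthetic tests do and do not show

The generator validates the *pipeline*: that beta estimation is unbiased,
that train/test independence holds, that the decoding stack manufactures no
information (zero-signal accuracy centers on 0.5; the vs-chance test's
type-I error matches α), and that the ratio tracks the true code rotation
monotonically with calibrated endpoints.  It does not emulate real fMRI
noise structure (spatial correlation, physiological noise, motion), real
HRF variability or tails, anatomical ROI geometry, or behavioral variation
— so passing tests certify the analysis machinery, not the empirical claim
itself.  Two measurement biases documented above (training-SNR asymmetry
and common-component shift) imply that on real, low-SNR data the ratio
should be read comparatively (across ROIs, sectors, periods) rather than as
an absolute calibrated quantity.

## Numerical and design choices

- Condition order, blank placement and distractor sequences are seeded
  uniform randomizations per run (no counterbalancing across runs is
  modeled); distractor exemplar sequences rejection-sample up to 1000
  permutations for the no-adjacent-repeat rule.
- The probe is scheduled but contributes no signal: decoding uses pre-probe
  TRs only.
- All 480 regressors are fitted in a single joint GLM per combination (not
  per-condition GLMs).
- Averaging order: rotations → pair instances → schemes → ROIs → sectors.
- Determinism: every stage takes an explicit seed or `numpy` Generator;
  the pipeline derives per-participant streams from a root `SeedSequence`,
  and identical configs reproduce identical output checksums.
- Problem sizes in the test suite and acceptance script (participants,
  seed counts, vertex counts) are scaled to finish in minutes on one CPU
  while keeping every check statistically meaningful; the cohort sweep uses
  the canonical [13, 14] plan at 200 vertices.

## Known limitations

- The ratio denominators come from within-decoding near ceiling under
  default settings; configurations with weak within-decoding trip the
  validity flag and should be interpreted through it.
- The split-combination rule generalizes beyond 13/14-run sessions (all
  (k−1)-subsets, plus the full set for k ≤ 6) but pattern counts then
  deviate from 28; a warning is emitted.
- Surface-file formats (GIFTI/CIFTI) are out of scope; the documented array
  + sidecar and TSV containers are the I/O surface, with events tables in
  the BIDS dialect so real datasets can be adapted.
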