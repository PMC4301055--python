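# Methods

This note documents the models, the measurement chain, the numerical
choices, and the limits of what the synthetic experiments can show.

## Call synthesis

A call is an additive stack of harmonics k·f0(t) whose fundamental follows
a cosine-segment contour through five landmarks: start frequency `f0beg`,
maximum `f0max` reached at `dur_to_max`, a fall to the contour minimum
`f0min`, and a short terminal rise to `f0end` over the final ~40 ms. All
segments have zero slope at their endpoints, so every landmark sits on a
locally flat stretch that windowed analysis can sample faithfully. The
spectral envelope is a linear tilt (default 2 dB per harmonic order) plus
a Gaussian emphasis (width 1.2 orders) centred on a target peak harmonic;
the emphasis is solved so that the level difference between the peak
harmonic and the fundamental equals the call's `power_f0` exactly. A 10 ms
raised-cosine fade avoids onset/offset clicks, and broadband Gaussian
noise is added at 30 dB SNR (clean-recording conditions). Synthesis runs
directly at the 11025 Hz analysis rate to avoid resampling artifacts in
round-trip tests. No vocal-tract filter (formants), no subharmonics or
deterministic chaos.

Population defaults are the published per-class, per-call-type means and
SDs of the 14 variables (hinds and calves; oral and nasal calls). Three
deliberate departures from a literal reading of that table:

- **The contour's fall target is the f0min column, not the f0end column.**
  The printed means put f0min above f0end in three of four cells, which no
  single contour can realize (the contour minimum cannot exceed its
  endpoint) — the two numbers come from different measurement conventions.
  Since Δf0 = f0max − f0min is the quantity the discriminant analysis
  uses, the generator honors f0min/Δf0 and lets f0end emerge from the
  terminal rise (drawn as f0min + 0.15·|N(0,1)|·Δf0 per call). The rise
  also keeps f0end from coinciding with f0min, which would make the
  extracted variable set {f0end, f0max, Δf0} exactly collinear and the
  11-variable discriminant fit singular.
- **Peak position is capped at 0.55·durat.** The printed calf dur-to-max
  mean exceeds the calf duration mean, again impossible per call; the cap
  keeps a fall segment long enough to carry the printed depth of frequency
  modulation inside short calf calls.
- **The spectral emphasis excess is capped at 6 dB per harmonic order of
  distance from the fundamental.** Independent draws of peak-harmonic
  order and power_f0 occasionally demand, e.g., a 2nd harmonic 20 dB above
  the fundamental — a degenerate single-partial "call" whose pitch is
  genuinely its peak partial, not f0. Bounding the envelope slope keeps
  every call's pitch physically well defined.

### Individuality model

The published SDs conflate between- and within-individual variance. An
intraclass correlation `icc` (default 0.7) splits them: each animal gets
latent per-feature means drawn with SD sd·√icc around the population mean,
and each call jitters around the latent means with SD sd·√(1−icc), so the
marginal variance is preserved while a fraction icc separates individuals.
The default was chosen once so that runs at the study's design sizes show
strong but imperfect individuality (observed accuracy well above the
permutation chance band, below 100%). The five f0 landmarks share one
between-individual deviate per animal and call type — an animal's "pitch
register" — which keeps the landmark ordering f0min ≤ f0beg ≤ f0max intact
across the between-individual spread without changing any marginal
variance. Within-call draws are repaired deterministically against the
same ordering constraints.

Between-year change is phenomenological: `apply_year_drift` adds an
independent N(0, (year_drift_sd·sd)²) shift to every latent mean, with
`year_drift_sd` expressed in units of each feature's population SD (one
dimensionless knob across features with heterogeneous units; default 0).

`sample_features_direct` bypasses audio and samples feature rows straight
from the latent model — statistically equivalent by construction and used
for the permutation-heavy statistical experiments; the audio path
(synthesize, then extract) is used wherever the measurement chain itself
is under test.

## Feature extraction

Preprocessing: resample to 11025 Hz (`scipy.signal.resample_poly`;
upsampling refused) and zero-phase 6th-order Butterworth high-pass at
50 Hz (>40 dB attenuation at 30 Hz).

**Pitch tracking.** Normalized cross-correlation per frame (window of 1.5
floor-periods, hop = class time step: 10 ms for hinds, 5 ms for calves;
search band 50–400 Hz for hinds, 100–1200 Hz for calves), on a signal
low-passed at 1.3× the band ceiling so that energy concentrated in high
harmonics cannot capture the correlator. Local correlation maxima become
per-frame candidates with parabolic lag interpolation; candidate strength
is the interpolated peak height (raw integer-lag samples systematically
favor subharmonic lags) minus a small octave cost (0.02 per octave below
the ceiling) that breaks the tie among period multiples, which correlate
equally well. A Viterbi path over candidates plus an unvoiced state
(emission 0.45, octave-jump cost 0.35 per octave, voicing-flip cost 0.14)
selects the contour; candidates down to 0.3 are kept so that continuity
can voice weak frames the hard threshold would discard. Two deterministic
repair passes stand in for the manual, spectrogram-based correction used
with real recordings: (1) a spectral harmonic-division pass that divides a
frame's f0 by d ∈ {2,3,4} when the local spectrum shows a prominent peak
at f0/d (local maximum, ≥ −25 dB re frame peak, ≥ 15× the valley median
around it) corroborated by a peak at its 2nd or 3rd multiple — the
signature of a correlator locked onto a high harmonic; (2) a running-median
octave repair that halves/doubles isolated frames deviating more than 60%
from the local median. Frame times carry a +τ/2 correction (the
correlation pairs span [start, start+win+τ], so the estimate belongs to
the centre of that span); on fast-sweeping contours this matters at the
percent level.

**Independent f0 estimator.** A spectrogram-ridge estimator (Hamming
window of three floor-periods, 4096-point FFT) takes, per frame, the
in-band spectral local maxima within 22 dB of the strongest in-band peak
(wide enough to keep a fundamental sitting under a rising envelope),
prefers the lowest-frequency one — the fundamental ridge a human reads
off a spectrogram — and runs the same continuity path finder over those
candidates. It shares no signal
path with the lag-domain tracker and serves only as a consistency oracle;
on clean synthetic calls the two estimators' per-call f0max correlate at
≥ 0.999.

**Temporal and power variables.** Call bounds from a smoothed RMS envelope
(10 ms window) at −25 dB re peak; synthetic calls may carry exact bounds
instead. The mean power spectrum is Welch's method on the 50 ms fragment
centred at the f0 maximum (Hamming, 256-sample segments, 75% overlap,
1024-point FFT; fragment clipped at call edges, never padded). Energy
quartiles are the first bins where cumulative power reaches 25/50/75% of
the total. A harmonic "band" is the bin set within ±f0/2 of k·f0;
power_f0 = 10·log10 of the strongest band over the f0 band (0 when the f0
band wins); peak_harm = round(fpeak / f0), floor 1.

## Discriminant analysis

Classification functions from group means and the pooled within-group
covariance, equal priors by default (the call designs are near-balanced; a
proportional option exists). The solve is done in per-variable
standardized space — exactly equivalent algebra with unit-free
conditioning — and the scatter is computed on globally centred data to
avoid cancellation under large offsets; condition numbers above 1e12 raise
a singularity error naming the suspect collinear variables (an explicit
ridge of 1e-8×mean-diagonal is available behind a flag). Resubstitution
is the primary accuracy (the published chance levels of ~24% for 22 groups
are only explicable by resubstitution overfitting; leave-one-out is
provided but not default). Ties break toward the lowest group index —
measure-zero with continuous features. The permutation null refits with
equal priors on labels shuffled preserving group sizes; group sizes for
simulated designs are drawn uniformly from the published per-animal range
and adjusted to the published total. Significance is one-sided: observed >
95th/99th/99.9th percentile of the null samples.

Partial Wilks' Λ for variable j is Λ(full)/Λ(without j) with
Λ = det(W)/det(T); F-to-remove = ((1−Λ)/Λ)·(n−k−p+1)/(k−1).

## Univariate statistics

Oral/nasal comparisons operate on per-individual means (each animal one
pair), as a two-level repeated-measures ANOVA = squared paired t with
df (1, n−1). Assignment-rate comparisons reconstruct correct/incorrect
counts from percentages by nearest-integer rounding and apply the
Yates-corrected 2×2 χ² (scipy); the reconstruction is validated by
reproducing published worked examples to two decimals. "Cube-law" body
mass enters Pearson correlations as the cube root (mass ∝ length³); a
literal log-base-3 transform is available since the conventional shorthand
is ambiguous. The calf ANCOVA is a Type-III OLS decomposition with
Sum-coded sex, continuous mass and their interaction (denominator
df = n−4).

## Between-year stability

Within-year analyses are the standard fit/classify/permute on one year's
table. Transfer scores year-B calls with year-A functions in the raw
variable space (no re-standardization). Drift sweeps average over seed
replicates; transfer accuracy is monotone non-increasing in
`year_drift_sd`, indistinguishable from within-year accuracy at zero
drift, and collapses into the permutation chance band by ~2 population
SDs of drift while within-year accuracy stays high — the signature of
signatures that must be relearned each season.

## Problem sizes

The test suite and analysis scripts use the study's own design sizes
(22 hinds / 17 calves / 5 stability hinds, 5–15 calls per animal, 1000
permutations) wherever the quantity under test depends on them; the
calibration experiments use 100 synthesized calls per class and call type,
and generator variance checks use enlarged populations (100–300 animals)
where Monte-Carlo error, not realism, is the constraint.

## What the synthetic experiments do and do not show

The generator reproduces the published marginal feature distributions, a
controllable between/within variance split, and the qualitative structure
of the study's findings (oral/nasal structural differences, chance levels
set by overfitting, pooled-sample dilution, between-year collapse). It
does not reproduce: real covariance between features beyond the shared
pitch register; formant cues; age- or mass-driven drift mechanisms (drift
is a phenomenological shift); overlapping callers, wind, or recording
noise beyond stationary broadband noise; or the true per-individual
spacing of latent means, which the source study does not report. Passing
tests therefore validate the measurement chain and the statistical
machinery under controlled conditions — they do not certify performance
on field recordings, where call-quality screening and manual contour
verification remain necessary. The published observed accuracies
(e.g. 77.0% for hind oral calls) depend on the real recordings and are
deliberately not targets; the package's substitute checks are the
permutation chance levels, the generator calibration, and the structural
properties above.
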