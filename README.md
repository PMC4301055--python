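# vocalid

Vocal individuality analysis of Iberian red deer (*Cervus elaphus
hispanicus*) mother and calf contact calls: synthesize calls with known
individual signatures, extract the 14 standard acoustic variables, quantify
individual discriminability with permutation-validated discriminant
analysis, and measure how stable those vocal signatures are between years.

## The scientific problem

Red deer hinds and their calves keep contact with two call types — oral
calls (mouth open) and nasal calls (mouth closed) — and mutual recognition
depends on those calls carrying individual signatures. The questions this
pipeline addresses:

1. How well do the acoustic variables of oral, nasal, and pooled call
   samples discriminate individual animals?
2. Is the observed discriminability better than chance — where "chance"
   must account for classifier overfitting?
3. Do the same variables carry individuality in both call types, and do
   sex and body mass confound it in calves?
4. Do a hind's discriminant functions from one year still recognize her
   calls the next year?

Each call is summarized by 14 variables: 2 temporal (durat, dur-to-max),
6 fundamental-frequency variables measured on the pitch contour (f0beg,
f0end, f0max, f0min, f0mean, Δf0 = f0max − f0min), and 6 power variables
from a mean spectrum of the 50 ms around the f0 maximum (fpeak, q25, q50,
q75, power-f0, peak-harm).

## The statistical core

Calls are assigned to individuals with linear discriminant classification
functions. For group (individual) g with mean vector **m**_g and pooled
within-group covariance **S**,

    score_g(x) = x' S⁻¹ m_g − ½ m_g' S⁻¹ m_g + ln π_g

and a call goes to the highest-scoring group. Accuracy is resubstitution
(training calls classified by the fitted functions), which overfits —
with 22 groups and ~9 calls each, pure noise classifies far above 1/22.
The honest chance level is therefore estimated by permutation: call labels
are shuffled 1000 times preserving group sizes, the model refitted and
rescored each time, and the observed accuracy is compared with the 95th /
99th / 99.9th percentile of that null distribution. Variable contributions
are ranked by partial Wilks' Λ (full-model Λ divided by the Λ without the
variable; smaller = more discriminative). Around this core: Yates 2×2 χ²
comparisons of assignment rates, repeated-measures ANOVA of oral vs nasal
per-individual means (F = paired t²), cube-root body-mass correlations,
and the sex × mass Type-III ANCOVA for calves.

Because the original recordings are not deposited, the package ships a
calibrated call synthesizer: an additive harmonic source whose contour and
spectral-envelope parameters are drawn from the published per-class
population statistics, with an intraclass-correlation knob (`icc`) that
splits each feature's variance into between- and within-individual parts,
and a `year_drift_sd` knob that shifts individual latent means between
years.

## Worked example

```python
from vocalid import RunConfig, run_end_to_end

cfg = RunConfig(seed=5, caller_class="hind", n_individuals=22,
                n_calls_per_type=10, icc=0.8, n_permutations=1000,
                synthesis="direct")
report = run_end_to_end(cfg)
for name, block in report["dfa"].items():
    obs = block["observed"]["average_pct_correct"]
    null = block["null"]
    print(f"{name:6s} observed {obs:5.1f}%  "
          f"chance {null['mean']:4.1f} ± {null['sd']:.1f}%  "
          f"{block['significance']}")
```

prints

```
oral   observed  99.5%  chance 21.8 ± 2.5%  p < 0.001
nasal  observed  98.2%  chance 21.9 ± 2.4%  p < 0.001
pooled observed  65.0%  chance 14.9 ± 1.4%  p < 0.001
```

Read: with 80% of feature variance between individuals, oral calls of 22
hinds are assigned to the right animal 99.5% of the time, while shuffled
labels still score ~22% (overfitting, not signal) — the observed value
exceeds every one of the 1000 permutation accuracies. Pooling oral and
nasal calls dilutes the signatures (65.0%) but stays far above its own
chance level, mirroring the qualitative finding that one set of cues
serves both call types.

The `analysis/` scripts run the full study line: `01` synthesizes call
audio, `02` extracts and calibrates features against the published
population table, `03` runs the three-sample discriminant analyses for
hinds and calves, `04` the oral/nasal and covariate statistics, `05` the
between-year stability sweep. Outputs land in `results/`.

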