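# Methods

## The analysis in brief

`synmap` implements a second-order similarity-mapping analysis of
grapheme–colour synesthesia. The question it operationalises is
relational: do graphemes that are more alike — in sequence position,
name phonology, visual shape, or familiarity — elicit more similar
synesthetic colours? The unit of analysis is therefore the unordered
*grapheme pair*, not the grapheme. For each pair the pipeline computes a
colour-difference profile from participants' palette choices, averages it
across participants, and regresses it on four pairwise grapheme
predictors.

The pipeline also includes the standard genuineness battery: synesthetes
are expected to re-choose nearly the same colour for a grapheme in a
second session weeks later, while random responders drift toward the
palette's chance level.

## Colorimetry

Colour arithmetic is done in CIE L\*a\*b\* (D65 white point, 2° standard
observer), obtained by nominal sRGB decoding of the palette's 8-bit
triplets (gamma companding per IEC 61966-2-1, via `skimage.color.rgb2lab`).
This is a deliberate stand-in for display-side colorimeter measurement:
it is device-independent and exactly reproducible, at the cost of
ignoring the colorimetric quirks of any particular monitor. The four
colour-difference measures are

- colour distance: Euclidean ΔE in L\*a\*b\*,
- luminance distance: |ΔL\*|,
- saturation distance: |ΔC\*| with C\* = √(a\*² + b\*²),
- hue distance: angular separation of h = atan2(b\*, a\*).

Hue is an angle, so the hue distance is circular by default
(min(|Δh|, 360° − |Δh|) ∈ [0°, 180°]); a `linear` mode (plain |Δh|) is
provided because either convention is defensible for re-analysis.
Achromatic colours (C\* < 1e−9) take h = 0 by convention; a diagnostic
counter in the pair-measure table reports how many (participant, pair)
combinations involved an achromatic colour, so an analyst can judge
whether the convention matters for a given dataset.

The packaged palette is the 138 distinct sRGB values among the classic
browser-supported named colours (147 names; the gray/grey, aqua/cyan and
fuchsia/magenta spelling duplicates collapse to 138 unique triplets).
The chance level — the expected colour distance between two uniformly
drawn distinct palette colours — is computed by exhaustive enumeration of
all 138·137/2 pairs rather than sampling: it is deterministic and equals
the sampling expectation. For this palette under nominal conversion it is
75.6 (SD 38.7).

## Pairwise grapheme predictors

With 1-based sequence positions i, j (gojūon order for the 46 basic
Hiragana; A–Z for the 26 uppercase Latin letters):

- ordinality difference: |i − j| / (i + j), in (0, 1); small for adjacent
  late-sequence pairs, large when an early grapheme meets a late one;
- phonological similarity: the number of shared phonemes in the two
  graphemes' *names* (multiset intersection, position-insensitive).
  Hiragana names equal their pronunciations (か = /k/ /a/); Latin letter
  names are transcribed in a packaged, editable fixture (B = /b/ /iː/,
  W = /d/ /ʌ/ /b/ /l/ /j/ /uː/, Z = US "zee" /z/ /iː/). Long vowels and
  diphthongs count as one phoneme; the moraic nasal ん is the single
  phoneme /N/;
- visual similarity: a symmetric 1–5 rated-similarity lookup, or — for
  Latin only — a shape *difference*, the Hamming distance between
  11-dimensional binary distinctive-feature vectors;
- familiarity difference: |f_x − f_y| of 1–7 subjective ratings.

The published rated-similarity norm matrices and the original
distinctive-feature chart are third-party print material and are not
redistributed. The packaged `gibson_features.csv` is a synthetic
reconstruction from uppercase stroke geometry (11 binary dimensions, all
26 vectors distinct); the synthetic-data module generates internally
consistent similarity norms. Real norms drop in as schema-compatible
CSVs.

## Binning and regression

Pairs are sorted ascending by the across-participant mean colour distance
(stable sort; ties keep canonical pair order, which makes bins
reproducible) and cut into consecutive equal-size bins: 15 pairs per bin
for the 1035 Hiragana pairs (69 bins) and 5 per bin for the 325 Latin
pairs (65 bins). Bin means of both the colour measures and the
predictors are the regression's observations, so N = 69 or 65. The pair
counts are divisible by the default bin sizes by design; for other
designs a `drop_remainder` policy truncates with a logged warning.

Each colour-difference measure is regressed on the four predictors by
OLS with intercept. Standardised coefficients use the identity
β_j = B_j · sd(x_j)/sd(y) with sample (n−1) standard deviations —
identical to refitting on z-scores. Coefficient t-tests are two-tailed
with N − k − 1 df; the model F uses (k, N − k − 1). Collinearity is
screened with VIF_j = 1/(1 − R²_j) from auxiliary regressions (equal, to
numerical precision, to the diagonal of the inverse predictor correlation
matrix). No multiple-testing correction is applied across the four
regressions, and the report says so. A raw-pair (unbinned) fit is
available through the same functions for sensitivity analysis by passing
the pair table instead of the binned table.

## Consistency battery

Per participant and script, the mean L\*a\*b\* distance between session-1
and session-2 choices over all graphemes. Groups are summarised by mean,
SE (n−1 SD / √n) and range. Synesthetes vs controls are compared by
Welch's unequal-variance two-tailed t-test. Degrees of freedom are
reported under two conventions — Welch–Satterthwaite, and the
conservative min(n_A, n_B) − 1 — because both circulate in this
literature; the Bonferroni correction (m = number of scripts, default 2)
is applied to the convention selected by `df_convention` ("min" by
default). Participants were conventionally instructed to answer "black"
for graphemes with no colour; such responses are kept as the colour black
by default, with an option to exclude those graphemes (count logged),
since either choice is defensible. Session-1 data feed the mapping
pipeline by default; configurable.

## Synthetic cohorts

The generator encodes the hypothesis the analysis is built to detect:
colours attach to *feature representations*, and a grapheme inherits a
blend of its features' colours. Per synesthete (mappings are
idiosyncratic), each domain contributes an anchor colour per grapheme:

- ordinality: anchors lie on a random straight segment through Lab space,
  parameterised by (position − 1)/(n − 1);
- phonology: one random Lab anchor per phoneme; grapheme anchor = mean
  over its name phonemes (shared phoneme ⇒ shared component ⇒ similar
  colours);
- shape: one random Lab anchor per binary feature; grapheme anchor =
  mean over active features. Feature vectors are Bernoulli(½) with at
  least one active bit, generated once per script; the synthetic rated
  norm is 5 − 4·Hamming/11, so the predictor and the colour-generating
  mechanism are mutually consistent;
- familiarity: ratings uniform on [1, 7], mapped affinely onto L\*
  (a\* = b\* = 0) — a continuous grapheme property driving the continuous
  colour dimension.

The latent colour is the weight-normalised anchor mean plus isotropic
Gaussian noise (sd `sigma_color`), clipped to the palette's Lab bounding
box (anchors are sampled uniformly inside that box so clipping is rare);
each session's response snaps latent + retest noise (sd `sigma_retest`)
to the nearest palette colour, ties to the earlier entry. Controls answer
with independent uniform palette draws. With all weights zero the latent
is itself a uniform palette draw (null mode). All randomness flows from
one integer seed.

Defaults are the emulated study design: 17 synesthetes, 6 controls, two
sessions, both scripts. Default weights (0.4, 0.3, 0.2, 0.1 for
ordinality, phonology, shape, familiarity) follow the qualitative
importance ordering reported for Hiragana; default noise
`sigma_color = sigma_retest = 10` Lab units puts simulated synesthete
retest distances near 20, the scale reported for genuine synesthetes and
far below the ~68–76 chance level. The generator parameters are
stand-ins chosen for plausibility, not estimates of any study's effect
sizes. "Low noise" in the recovery experiments is fixed at
`sigma_color = sigma_retest = 5`.

What the generator does *not* emulate: memory-driven colour sources
(coloured toy alphabets), cross-script transfer of colours, first-order
lexical associations ("y is yellow"), non-uniform familiarity
distributions, and response strategies of real controls. Passing
recovery tests therefore show that the pipeline detects the relational
structure it targets when that structure is present — not that real
synesthetic data contain only such structure.

## Validation experiments and problem sizes

- Parameter recovery: 100 seeded replicates per single-active-domain
  setting (Hiragana script, 17 synesthetes, low noise). The active
  domain's predictor attains the largest |β| on colour distance with the
  expected sign (positive for difference-type predictors, negative for
  similarity-type) in 100/100 replicates for all four domains.
- Consistency battery: 100 seeded replicates of the full 17-vs-6 design;
  Bonferroni-corrected Welch p < 0.01 in ≥ 95/100 for both scripts, and
  control retest distances average the palette chance mean.
- Null calibration: 100 all-weights-zero replicates, recording each
  predictor's rejection rate at α = 0.05 in the colour-distance
  regression.

## Known limitations

- **The binned-pair OLS inference is anticonservative for
  grapheme-anchored predictors.** Pairs sharing a grapheme have
  positively correlated colour distances (a grapheme whose colour is
  extreme shifts all of its pairs), and pair values of ordinality and
  familiarity are strong functions of single-grapheme attributes. The
  bin-level t-tests assume independent observations and inherit this
  dependence: under the null the ordinality and familiarity predictors
  reject at well above the nominal 5% rate (≈ 0.3–0.45 in our
  experiments), while the near-binary phonology and shape predictors stay
  close to nominal. A permutation control — shuffling colour-distance
  values across pairs before binning, which destroys only the
  shared-grapheme dependence — restores ≈ 5% for all four predictors,
  confirming the mechanism. Effect *ranking* (which domain has the
  largest |β|) is unaffected in our recovery experiments, but p-values
  from this procedure should be read with caution; a pair-level
  permutation test would be the principled fix and is out of scope here.
- The nominal sRGB→Lab conversion shifts absolute distance scales
  relative to any colorimeter-measured display (chance mean 75.6 here vs
  CRT-measured values near 68); comparisons across pipelines should be
  made on standardised quantities.
- Phoneme decompositions and the reconstructed shape-feature table are
  editable conventions, not measured norms; swapping in published norms
  changes predictor values but no code paths.
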