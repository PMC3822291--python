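# synmap

Second-order similarity mapping of grapheme–colour synesthesia.

In grapheme–colour synesthesia, letters and characters involuntarily
evoke colours. Beyond idiosyncrasy, these associations carry structure:
graphemes that are more alike — adjacent in their conventional sequence,
sharing name phonemes, visually similar, or alike in familiarity — tend
to elicit more similar colours. `synmap` is a pipeline for quantifying
that *second-order* structure (correlations between pairwise grapheme
differences and pairwise colour differences, as opposed to first-order
"y is yellow" mappings) for the 46 basic Japanese Hiragana characters
and the 26 uppercase English letters, from palette-choice data.

It is written for cognitive scientists and psychophysicists who want to
run, re-analyse, or power-check this design without access to the
original participant data: a seeded synthetic-synesthete generator stands
in for real cohorts, so every stage is testable end to end.

## The method

Participants choose, from a palette of 138 named web colours, the colour
closest to each grapheme's synesthetic colour, in two sessions weeks
apart.

**Genuineness battery.** Per participant, the mean CIE L\*a\*b\* distance
between session-1 and session-2 choices across graphemes. Genuine
synesthetes score far below the palette's chance level (the all-pairs
mean ΔE, 75.6 under nominal sRGB→Lab conversion); random responders land
on it. Groups are compared with Welch's two-tailed unequal-variance
t-test, Bonferroni-corrected across scripts.

**Second-order mapping.** For each of the n(n−1)/2 unordered grapheme
pairs (1035 Hiragana, 325 Latin), four colour-difference measures
(ΔE in L\*a\*b\*; |ΔL\*|; |ΔC\*|; circular Δh in L\*C\*h) are averaged
across synesthetes, and four pairwise predictors are computed:

| predictor | definition |
|---|---|
| ordinality difference | \|i − j\| / (i + j) of sequence positions |
| phonological similarity | shared phonemes in the graphemes' names |
| visual similarity | rated 1–5 norm (or 11-feature Hamming shape difference) |
| familiarity difference | \|f_x − f_y\| of 1–7 ratings |

Pairs are sorted by mean colour distance and grouped into equal-size
bins (69 bins of 15 pairs for Hiragana; 65 of 5 for Latin); bin means of
each colour measure are regressed on bin means of the four predictors by
OLS, reporting R², F, unstandardised B with SE, standardised β, t, p and
per-predictor VIF. See `docs/methods.md` for assumptions, conventions
and known limitations.

## Worked example

```python
import synmap as sm

palette = sm.load_default_palette()
mean, sd = sm.palette_chance_statistics(palette)
print(f"chance level: {mean:.1f} (SD = {sd:.1f})")

# a synthetic cohort: 17 synesthetes + 6 random controls, two sessions
ds = sm.generate_dataset(sm.GeneratorConfig(seed=42), palette=palette)

report = sm.run_consistency_analysis(ds.responses, palette)
for script, e in report["scripts"].items():
    s, w = e["synesthetes"], e["welch"]
    print(f"{script}: synesthetes {s['mean']:.1f} (SE {s['se']:.1f}), "
          f"Welch t({w.df_min}) = {abs(w.t):.2f}, "
          f"Bonferroni p = {w.p_bonferroni:.2g}")

mapping = sm.run_second_order_analysis(
    ds.responses, palette, ds.inventories, norms=ds.norms)
res = mapping["scripts"]["hiragana"]["regressions"]["color_distance"]
print(f"Hiragana colour distance: R^2 = {res.r_squared:.2f}")
print(res.coefficients.round(3))
```

prints

```
chance level: 75.6 (SD = 38.7)
hiragana: synesthetes 25.1 (SE 0.8), Welch t(5) = 24.87, Bonferroni p = 3.9e-06
latin: synesthetes 23.5 (SE 0.8), Welch t(5) = 36.99, Bonferroni p = 5.4e-07
Hiragana colour distance: R^2 = 0.89
                              B     SE   beta       t      p    vif
ordinality_difference    29.494  2.549  0.691  11.573  0.000  2.067
phonological_similarity  -9.072  2.348 -0.227  -3.864  0.000  1.999
visual_similarity        -1.118  1.598 -0.030  -0.700  0.487  1.069
familiarity_difference    2.301  0.593  0.172   3.882  0.000  1.140
```

Simulated synesthetes re-choose colours ~25 ΔE apart across sessions —
far below the 75.6 chance level, so the battery cleanly separates them
from the random controls (t on 5 conservative df, corrected p ≪ 0.01).
The regression recovers the generator's weight ordering: this cohort was
built with ordinality as the strongest domain, and ordinality difference
indeed has the largest standardised β (+0.69), with phonological
similarity negative (shared phonemes ⇒ more similar colours ⇒ smaller
colour distance). All VIFs are below 2.1, so collinearity is mild.

The same pipeline runs from the shell:

```sh
synmap simulate --seed 42 --out run/
synmap consistency --responses run/responses.csv --out run/
synmap map --responses run/responses.csv \
    --norms hiragana run/norms_hiragana.csv \
    --norms latin run/norms_latin.csv --out run/
```

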