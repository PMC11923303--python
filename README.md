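# tilscore

Patch-level scoring of tumor-infiltrating lymphocytes (TILs) in H&E
whole-slide images.

TIL density is a prognostic biomarker across many solid tumors, but
manual assessment is slow and inconsistent. `tilscore` implements the
automated patch-counting approach: a slide is tiled into 150×150 px
patches (×20 magnification), blank patches are filtered out
(gray mean > 230 and sd < 15), tissue patches are Macenko
color-normalized, and each patch is classified as

* **TIL-positive (0)** — ≥ 3 lymphocytes and ≥ 1 tumor cell,
* **TIL-negative (1)** — ≥ 1 tumor cell, < 3 lymphocytes,
* **other/necrotic (2)** — no tumor cells,

after which the TIL score of a slide (or of a patient with m slides) is
the pooled ratio

$$\mathrm{TIL\ score} = \frac{\sum_{i=1}^{m} N^{i}_{\text{TIL-positive}}}{\sum_{i=1}^{m}\left(N^{i}_{\text{TIL-positive}} + N^{i}_{\text{TIL-negative}}\right)}$$

Other/necrotic and blank patches count toward neither numerator nor
denominator, and a zero denominator is reported as undefined, never 0.
Patch-level class maps ("TIL maps") visualize the spatial distribution.

The package ships a pluggable classifier contract with a deterministic
rule-based reference backend (hematoxylin unmixing → nucleus
segmentation → area/circularity classification → counting rule), a
seeded synthetic H&E generator with exact ground truth (Beer–Lambert
stain model, known cell counts and labels), stratified split utilities,
and full multi-class evaluation (confusion matrix, accuracy, Cohen's
kappa, one-vs-rest AUC, precision/recall/specificity/F1). See
`docs/methods.md` for the model details and design choices.

## Worked example

Generate a synthetic 4×4-patch slide and run the full pipeline on it:

```bash
tilscore synth slide --rows 4 --cols 4 --tissue-fraction 0.7 --seed 3 \
    --out demo.png --manifest demo.manifest.tsv
tilscore run demo.png --out-dir runout
```

```
4x4 slide -> demo.png
1 slides scored, 0 failed -> runout
```

`runout/scores.tsv` then contains:

```
unit_id  level  m  n_positive  n_negative  n_other  score
demo     slide  1  4           2           5        0.666667
```

i.e. of the 16 patches, 5 were blank and ignored, 4 were classified
TIL-positive, 2 TIL-negative and 5 other/necrotic, giving a TIL score
of 4/(4+2) = 0.667. Because this slide is synthetic, the predictions
can be checked against the generator's ground truth:

```bash
tilscore classify demo.png --out preds.tsv
tilscore eval demo.manifest.tsv preds.tsv --out metrics.json
```

```
{"accuracy": 1.0, "kappa": 1.0}
```

`runout/demo.map.png` is the TIL map (red = positive, blue = negative,
green = other, white = blank). The same steps are available as library
calls (`tilscore.run_pipeline`, `tilscore.generate_slide`,
`tilscore.evaluate`, ...), and `tilscore --help` lists the individual
stage commands (`synth`, `tile`, `normalize`, `classify`, `score`,
`map`, `eval`, `run`).

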