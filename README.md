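# urolab

Urine-color hydration monitoring and rehydration guidance from cuvette
images, built on CIE L\*a\*b\* colorimetry.

Urine yellowness tracks solute concentration, so the CIELAB b\* value
(the blue→yellow chromaticity axis) is an objective, instrument-friendly
hydration index for athletes — more reproducible than visual urine-color
charts, which depend on lighting, container and observer. `urolab`
implements the full software chain of such an instrument: measure the
representative RGB color of a urine-filled cuvette image, convert it to
L\*a\*b\*, grade hydration on an eight-level standard, and scale the
rehydration recommendation by body weight. A synthetic-image generator
inverse-renders known b\* targets into noisy cuvette images, so the
whole pipeline is testable without hardware or real samples.

## The model

**Color conversion.** 8-bit RGB counts are normalized to fractions and
mapped linearly to tristimulus XYZ (scaled so white has Y ≈ 100):

```
[X Y Z]ᵀ = 100 · M [R G B]ᵀ,   M = ⎡0.4124 0.3575 0.1804⎤
                                   ⎢0.2126 0.7151 0.0721⎥
                                   ⎣0.0193 0.1191 0.9502⎦
```

then to L\*a\*b\* relative to the D65 white point
(Xn, Yn, Zn) = (95.047, 100.0, 108.883):

```
L* = 116 f(Y/Yn) − 16
a* = 500 [f(X/Xn) − f(Y/Yn)]      f(t) = t^⅓            if t > (6/29)³
b* = 200 [f(Y/Yn) − f(Z/Zn)]      f(t) = ⅓(29/6)²t + 4/29  otherwise
```

No sRGB gamma decoding is applied by default (the instrument path feeds
raw camera counts into the matrix); pass `srgb_gamma=True` to decode
standard images first.

**Grading.** Urine specific gravity (Usg) and b\* are linked by the
published regression `b* = −1220 + 1220·Usg` (R² = 0.657, n = 803
athlete samples). Substituting the clinical Usg grade thresholds
1.000, 1.005, …, 1.035 yields the b\* bounds of eight hydration levels:
0, 6.1, 12.2, 18.3, 24.4, 30.5, 36.6, 42.7, capped at 127. Levels 1–2
are well hydrated; 3–4 minimal, 5–6 significant and 7–8 serious
dehydration, each with a rehydration fraction of body weight
(0%, up to 0.25%, 0.25–0.5%, 0.5–1%, 1–1.5%, 1.5–2%). At fluid density
1 g/ml the volume is `frac × weight_kg × 10` ml — e.g. level 7 at 80 kg
gives 800–1200 ml.

**Measurement.** `measure_color` crops the key area (by default the
central 50%×50% cuvette window), denoises (Gaussian → bilateral →
morphology, each stage optional), takes a per-channel 10% trimmed mean,
optionally applies a per-channel affine standard-curve correction, and
converts once to Lab. The result carries quality flags (`clipped`,
`low-pixel-count`, `high-variance`, `negative-b-clamped`).

## Worked example

```sh
$ urolab grade --usg 1.032 --weight 80
b* = 39.04  →  level 7 (Serious dehydration)
You are seriously dehydrated. You need to add 1%–1.5% body weight in sports
drink. You are recommended to take 800 ml–1,200 ml of sports drinks. Pay
attention for a short period while rehydrating. You are recommended to take
100 ml–200 ml of sports drinks every 10 min–20 min. The amount of fluid
supplementation can be adjusted appropriately in accordance with the actual
situation.
```

Usg 1.032 maps through the regression to b\* = 39.04, which falls in
level 7's interval [36.6, 42.7); 1%–1.5% of 80 kg body weight at 1 g/ml
is the printed 800–1,200 ml range.

End-to-end on synthetic images:

```sh
$ urolab --seed 3 simulate --out demo --count 3
Wrote 3 images + manifest.csv to demo
$ urolab analyze demo/sample_0001.png --weight 80 --name "A. Athlete" \
    --store demo/store.jsonl
Hydration test report — A. Athlete
Time: 2026-09-18T01:03:28   Location: -
Measured color: RGB (183, 162, 131)  L*=84.17 a*=0.88 b*=10.80
Hydration level: 2
You are drinking enough.
```

The measured b\* = 10.80 sits in level 2's interval [6.1, 12.2) —
well hydrated, no fluid deficit to replace. Other subcommands:
`table` (print/export the derived grading table), `calibrate` (fit the
standard curve from paired samples), `review` and `export` (local
record store), all under a global `--config`/`--seed`.

The same operations are available as a library:

```python
from urolab import grading, imaging, synthgen

img, truth = synthgen.render_sample(
    synthgen.SyntheticSampleSpec(target_b=20.0, seed=42))
m = imaging.measure_color(img)              # b* ≈ 20.14
table = grading.build_grading_table()
grade, advice = grading.grade_from_lab(m.lab, table, weight_kg=80)
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the b\* grade bounds derived from
the regression and Usg thresholds; the L\* anchors of the full color
conversion at pure black and pure white; and the repeat-detection
stability of the complete pipeline — a seeded 100-image synthetic panel
measured and classified twice, with the Pearson correlation between the
two hydration-level vectors. Results are written as JSON keyed by
target id.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
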