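# cyeff — cyclist-effort texture features

`cyeff` extracts a two-number texture descriptor from grayscale images by
treating the image as a hilly terrain: intensity is elevation, and a
virtual cyclist rides straight-line "stage profiles" sampled at random
across the image.  Rough, high-relief texture (for example the dense
sinuous capillary patterns that distinguish malignant from benign lesions
in contact endoscopy with narrow-band imaging of the larynx) forces the
cyclist to climb constantly, so the average effort over many rides
summarizes surface roughness in two physically interpretable numbers:
mean trajectory energy **FE** (joules) and mean trajectory power **FP**
(watts).  The package is aimed at medical-image-analysis researchers who
want compact, explainable texture features for lesion classification, and
ships everything needed to study the descriptor without clinical data: a
patch-entropy baseline, a seeded synthetic-texture generator, and a
group-aware (patient-exclusive) classification and ranking harness.

## The model

Each trajectory's intensity profile `TP(i)` is cut into sections of `L`
index steps.  A section with grade fraction `S = Δy/L` resists the cyclist
with

    FG = g · sin(arctan S) · m          (gravity)
    FR = g · cos(arctan S) · m · Cr     (rolling resistance)
    FT = FG + FR + FA                   (FA: constant air resistance)

and, at constant velocity `v`, costs power `P = FT·v` and energy
`E = P·t` with `t = d(A, B)/v` the traversal time over the section's
Euclidean length.  Defaults: `g = 9.8 m/s²`, `m = 80 kg`, `Cr = 0.005`,
`v = 11 m/s`, `FA = 0`; pixel units are mapped to meters by assigning the
image diagonal a 200 km course.  Per-section powers and energies are
summed per trajectory (`Pk`, `Ek`) and averaged over 500 random
trajectories of at least 50 px into the image features `(FE, FP)`.

By default slopes enter the force terms by magnitude, so descents cost
effort like climbs; see `docs/methods.md` for the analysis behind that
choice and the `signed` variant.

## Worked example

```python
import dataclasses
from cyeff import EffortParams, SamplingConfig, extract_cyeff, make_texture, preprocess_image
from cyeff.synthetic import default_rough_spec, default_smooth_spec

cfg, params = SamplingConfig(seed=1), EffortParams()
for name, spec in [("smooth", default_smooth_spec()), ("rough", default_rough_spec())]:
    img = preprocess_image(make_texture(dataclasses.replace(spec, seed=3)))
    feats = extract_cyeff(img, cfg, params)
    print(f"{name:>6}: FE = {feats.fe:>14,.0f} J   FP = {feats.fp:>10,.0f} W")
```

prints

```
smooth: FE =      9,879,198 J   FP =     55,985 W
 rough: FE =    480,781,696 J   FP =    220,913 W
```

The vessel-like rough texture costs the virtual cyclists roughly 50× the
energy and 4× the power of the smooth low-relief texture — that contrast
is what a downstream classifier exploits.  `examples/` contains more
narrative scripts: the flat-terrain closed form (every section costs
exactly 43.12 W), a per-section walk through one stage profile, the
13-feature entropy baseline, and a full two-class benchmark
(`examples/two_class_benchmark.py` reaches accuracy 1.000 on held-out
patient groups and ranks FE, FP above ten noise features with both the
t-test and the rank-sum test).

A thin CLI wraps the same pipeline:

```sh
cyeff synth --out data/ --n-per-class 20 --seed 0
cyeff extract data/*.png --labels data/labels.csv --features cyeff,ef --out features.csv
cyeff evaluate --features-csv features.csv --out report/
```

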