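# limbalign

Automatic measurement of lower-limb alignment from standing anteroposterior
long-leg radiographs (LLRs), for knee-osteoarthritis assessment and
arthroplasty planning.

Surgeons quantify limb alignment by marking anatomical landmarks on an LLR
and reading angles off the lines connecting them. `limbalign` implements
that workflow end to end:

* **detector** — a two-branch network (Gaussian heatmap regression for ten
  landmarks per limb + normalised edge-vector prediction as a training-time
  geometric constraint) over a two-stream high-resolution backbone,
  implemented in NumPy with hand-written backprop so it trains on one CPU
  at desk scale;
* **geometry** — the five clinical angles from the ten landmarks
  (v1 femoral head … v10 ankle centre):
  HKA (hip–knee–ankle angle, varus negative), JCLA (joint-line convergence
  angle), AMA (femoral anatomical–mechanical angle), mLDFA and mMPTA, plus
  varus/neutral/valgus classification (varus iff HKA ≤ −2°, valgus iff
  HKA ≥ +2°);
* **phantom** — a synthetic LLR generator with analytically exact landmark
  ground truth (knee-OA cohort mixture: 54.5% varus / 30.7% neutral /
  14.8% valgus, optional knee prosthesis, sensor noise and handheld-capture
  degradation), so the whole pipeline trains and tests without any external
  data;
* **evalstats** — the agreement statistics used to compare automatic
  against manual measurements: mean radial error MRE = (1/n)·ΣRᵢ, mean
  absolute difference (MAD), angle-deviation rates (% AD < 1°, < 2°),
  Bland–Altman bias and 95% limits of agreement (bias ± 1.96·sd), and
  Pearson chi-square subgroup tests without continuity correction.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Generate 50 phantom limbs, measure their angles from the exact landmarks,
and score the (here trivially perfect) agreement:

```sh
limbalign simulate --n 50 --seed 7 --out data/
limbalign measure --landmarks data/landmarks.csv --out data/angles.csv
limbalign evaluate --reference data/angles.csv --prediction data/angles.csv \
    --out data/report.json
```

`data/angles.csv` holds one row per limb, e.g.

```
image_id,side,hka,jcla,ama,mldfa,mmpta,alignment
phantom_00000,right,1.5888...,-1.9349...,5.7258...,86.6641...,86.3179...,neutral
```

and `report.json` contains, per angle, `mad`, `ad_lt_1`, `ad_lt_2`,
`bias`, `loa_low`, `loa_high` (all zero / 100% in this self-comparison).
Training and prediction follow the same pattern:

```sh
limbalign train --data data/ --out model.npz --seed 1
limbalign predict --images data/ --model model.npz --out predicted.csv
limbalign measure --landmarks predicted.csv --out predicted_angles.csv
limbalign evaluate --reference data/angles.csv --prediction predicted_angles.csv \
    --out agreement.json
```

In Python the same pipeline is:

```python
import numpy as np
from limbalign import (CohortParams, DetectorConfig, measure_limb,
                       render, sample_spec, train, predict)

params = CohortParams(image_height=512, image_width=208)
rng = np.random.default_rng(0)
sample = render(sample_spec(params, rng))
print(measure_limb(sample.landmarks))   # the exact generation angles
```

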