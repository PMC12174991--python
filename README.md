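# xtalformer

A multi-modal transformer for predicting scalar properties of **molecular
crystals** — lattice energy, gas deliverable capacity, diffusivity, bulk
modulus, charge mobility and similar quantities whose direct computation
(force-field lattice sums, GCMC/MD, elastic tensors) is the bottleneck of
crystal structure prediction campaigns. The intended users are
computational chemists ranking polymorphs or screening CSP landscapes who
need a cheap, transferable surrogate that can be fine-tuned on small
property tables.

## The model

A crystal (CIF → P1 cell) is encoded along two modalities and fed to a
BERT-shaped transformer encoder (L = 12 layers, hidden H = 768, A = 12
heads by default):

* **atom tokens** — per-atom embeddings from edge-gated message passing on
  the periodic interatomic graph interleaved with line-graph (bond-angle)
  updates, combined with rotation/translation-invariant positional
  features built from the randomly perturbed structure;
* **persistence-image tokens** — persistent homology of the atomic point
  cloud under a growing-sphere (alpha-complex) filtration: channels (H₁)
  and voids (H₂) rasterized into per-image-scaled 50×50 persistence
  images, cut into 5×5 patches, with two [SCL] tokens per image carrying
  the maximum persistence and maximum birth.

The token sequence is
`[CLS] ATOM×n [SEP] PATCH1D×100 SCL SCL [SEP] PATCH2D×100 SCL SCL`.

Pre-training is self-supervised with four summed tasks: **MAP** (predict
the identity of 15% masked atoms, 80/10/10 corruption), **APC** (is a pair
of atoms from the same molecule — 200 balanced pairs per crystal, with an
order-symmetric head g([hᵢ;hⱼ]) + g([hⱼ;hᵢ])), **CDP** (crystal density
from [CLS]), and **SEP** (the 7-dim multi-hot of symmetry-element types —
no element / inversion / mirror / rotation / screw / rotoinversion /
glide — with inverse-frequency class weights w ∝ p^(−1/ε), ε = 1.1, and an
exact-match metric). Fine-tuning adds one dense layer on [CLS] and trains
all weights (AdamW, lr 1e-4, wd 1e-2, 5% warm-up then linear decay,
80/10/10 splits); a family-holdout few-shot protocol and attention-rollout
attribution (atoms + image patches, 0.005 display clipping) are built in.

Everything runs on CPU: the neural parts use a small numpy autodiff engine
shipped with the package, crystallography goes through `gemmi`, and the
alpha-complex persistence is computed from `scipy` Delaunay
triangulations. A synthetic-crystal generator (`xtalformer.fixtures`)
provides fully labelled toy corpora, so the entire pipeline is testable
without any external database.

## Worked example

```python
import numpy as np
from xtalformer.fixtures import make_dataset
from xtalformer.estimators import CrystalTransformerPretrainer, CrystalPropertyRegressor

data = make_dataset(60, seed=7)                    # synthetic molecular crystals
X = [s for s, _ in data]
y = np.array([rec["density"] for _, rec in data])  # g cm^-3

pre = CrystalTransformerPretrainer(
    layers=2, hidden=64, heads=4, graph_width=64, resolution=30,
    ff_mult=2, min_extent=12.0, epochs=10, batch_size=8, lr=2e-3,
    random_state=0)
pre.fit(X[:48], y=[rec for _, rec in data[:48]])
print(pre.score_tasks(X[48:], y=[r for _, r in data[48:]]))

reg = CrystalPropertyRegressor(pretrained=pre, epochs=8, batch_size=8,
                               lr=2e-3, min_extent=12.0, random_state=0)
reg.fit(X[:48], y[:48])
pred = reg.predict(X[48:])
print("density MAE: %.3f g cm^-3" % np.abs(pred - y[48:]).mean())
```

prints (10 pre-training epochs on 48 toy crystals — deliberately short):

```
{'map_accuracy': 0.769, 'apc_accuracy': 0.533, 'sep_exact_match': 0.5, 'cdp_mae': 0.165}
density MAE: 0.065 g cm^-3
```

i.e. after a brief pre-training the model already reads masked elements
from their environment 77% of the time and regresses density of unseen
crystals to 0.065 g cm⁻³; the full 50-epoch study in the test suite
reaches masked-atom accuracy 1.0, pair accuracy ≈ 0.98 and density MAE
≈ 0.03 g cm⁻³ on held-out fixtures. `pre.model_` is the underlying
transformer; both estimators follow scikit-learn conventions
(`get_params`, `clone`, pipelines).

A command-line interface covers the same workflow on directories of CIFs:

```bash
xtalformer make-fixtures crystals/ --n 200 --seed 1
xtalformer pretrain crystals/ model.npz -o pretrain.epochs=50
xtalformer finetune model.npz crystals/ crystals/properties.csv run/
xtalformer predict run/finetuned.npz crystals/ predictions.csv
xtalformer explain run/finetuned.npz crystals/fx0000-sg4-N2.cif attribution
```

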