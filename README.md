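# erfscope

Tools for probing **where a convolutional classifier's evidence comes
from**: from local surface statistics (texture-like cues), or from the
spatial arrangement of parts (shape-like cues).

The package is aimed at researchers studying object-recognition models —
in computer vision or computational neuroscience — who want to move past
the texture-vs-shape debate with manipulations of the *model* rather than
of the stimuli.  It provides four instruments:

1. **ERF-controlled architectures.**  A family of bottleneck residual
   networks (4 blocks of 2/3/3/2 units, widths 128–1024, strides 2/2/2/1)
   whose middle kernel sizes set the theoretical effective receptive field
   (ERF) of the last convolutional layer to 11, 23, 47, 95 or 227 pixels.
   The ERF is computed analytically by receptive-field arithmetic
   (`erf += (k−1)·jump`, `jump *= stride` in forward order) and verified
   against an empirical input-gradient-support oracle.
2. **Feature scrambling.**  A trained base network is frozen and its last
   convolutional feature grid is fed — optionally through a spatial
   permutation, global or confined to local windows — into a trainable
   follow-up network.  Comparing accuracy with and without scrambling, at
   training or test time, isolates the contribution of the spatial
   arrangement of features.  Per-class sensitivity is the **scrambling
   ratio** f1_after / f1_before.
3. **RSA.**  Representational dissimilarity matrices (1 − Pearson over
   stimuli), a second-order RDM across all layers of all models
   (5 models × 12 layers = 60×60), R² between RDMs, and metric MDS
   embeddings.
4. **MIRC search.**  Recursive 75% corner-crop search for *minimal
   recognizable configurations* — the smallest patches a model still
   classifies correctly — with level histograms and k-means clustering of
   MIRC representations.

Because the dependency stack contains no deep-learning framework, the
networks run on a compact, tested numpy backend (`erfscope.nn`) sized for
desk-scale experiments.  A seeded synthetic-data module generates the two
cue regimes the scrambling analyses contrast (texture-defined vs.
arrangement-defined classes, plus a contour-only sketch rendering), so the
whole pipeline is exercisable on a laptop CPU without downloads.

## Worked example

Analytic architecture properties (instant):

```bash
$ erfscope arch build --variant erf227 --report erf,params
erf: 227
params: 7986088
```

The five canonical variants give exactly the printed ERFs, and composing
the smallest base with the aggregating follow-up extends its field to
cover a 224-px input:

```python
>>> from erfscope import (make_erf_variant, compute_erf,
...                       FollowUpSpec, compute_composed_erf)
>>> [compute_erf(make_erf_variant(v)).network_erf
...  for v in ("erf11", "erf23", "erf47", "erf95", "erf227")]
[11, 23, 47, 95, 227]
>>> compute_composed_erf(make_erf_variant("erf11"), FollowUpSpec("aggregating"))
235
```

A desk-scale experiment end to end — generate texture-defined classes,
train a scaled smallest-ERF variant, and evaluate:

```bash
$ erfscope synth --cue texture --classes 4 --per-class 50 --size 64 \
    --seed 1 --out /tmp/tex
200 images written to /tmp/tex
$ erfscope train --variant erf11 --width-mult 0.125 --data /tmp/tex \
    --seed 1 --out /tmp/erf11.npz
final train accuracy 0.956; checkpoint at /tmp/erf11.npz
$ erfscope eval --ckpt /tmp/erf11.npz --data /tmp/tex
top-1 accuracy: 0.9750
```

Oriented gratings are separable from local statistics alone, so even the
ERF-11 model nearly solves them after ten epochs — and keeps solving them when its
feature grid is spatially scrambled.  Arrangement-defined classes (same
parts, different layout; `--cue arrangement`) are the opposite regime:
only the composed base+follow-up model can learn them, and test-time
global scrambling sends it back to chance.  The full contrast is run by
`erfscope scrambling-study --config <yaml>` (see
`erfscope.pipeline.ExperimentConfig`) and asserted as directional
properties in `tests/test_acceptance.py`.

## Layout

| Module | Contents |
| --- | --- |
| `erfscope.architectures` | variant specs, ERF arithmetic, parameter counts, network builder |
| `erfscope.nn` | numpy conv/BN/ReLU/GAP/dense with backprop, SGD+momentum |
| `erfscope.scrambling` | permutation maps, base/follow-up composition, test-time scrambling |
| `erfscope.training` | schedule, preprocessing, per-class metrics, scrambling ratios |
| `erfscope.rsa` | RDMs, second-order RDM, R², MDS, sensitivity contrast |
| `erfscope.mirc` | patch recursion, MIRC trees, level histograms, clustering |
| `erfscope.synthetic` | texture/arrangement/sketch generators + certification baselines |
| `erfscope.pipeline` | config-driven ERF survey and scrambling study |
| `erfscope.cli` | `erfscope` command-line entry points |

See `docs/methods.md` for the model conventions, the synthetic-data design
and its limitations, and every numerical choice.
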