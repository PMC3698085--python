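# retscreen

Evolutionary screening of retinal fundus images: a trainable pipeline that
separates **normal** from **abnormal** fundus photographs by detecting the
basic signs of diabetic retinopathy — microaneurysms (MA), haemorrhages,
and bright (exudate-like) lesions — and referring any image with evidence
of disease. It is aimed at people studying automated DR screening and
population-level image triage, where two-thirds of images are normal and
filtering them out automatically saves most of the human grading effort.

## What it implements

* **Synthetic fundus generator** (`retscreen.synth`) — simulated retinas
  with optic disc, macula, branching vessel tree, MAs, haemorrhages,
  exudate clusters, pigment noise and an illumination gradient, with exact
  per-pixel ground truth recorded before illumination. Everything
  downstream trains and evaluates on these; no external data needed.
* **Segmentation** (`retscreen.image_ops`) — optic disc (Hough-refined
  bright disc) and macula localisation, median + dynamic-threshold
  background estimation, permissive vessel masking, and candidate-region
  extraction per sign (dark candidates split by watershed and partitioned
  by area into MA vs haemorrhage; bright candidates exclude the disc).
* **Features** (`retscreen.features`) — a detector×feature matrix shipped
  as data: region photometry/shape features for the global detectors,
  histogram/Fourier/PCA/phase-symmetry/texture features for the 32×32
  local detectors, and 9-symbol vector-quantized observation sequences
  from 15×15 patches for the MA context model.
* **Ensembles** (`retscreen.ensembles`) — per detector, 3 training
  algorithms × 10 hidden sizes × 3 initialisations = 90 neural networks
  per feature set, combined by best / average / sum / majority-vote rules.
* **Discrete HMMs** (`retscreen.hmm`) — Baum-Welch training and Viterbi
  scoring with topology masks; a three-model (MA / blood-vessel /
  background) context classifier scored by Viterbi path likelihood

  V(1,k) = π_k·b_k(o₁),  V(t,k) = max_x V(t−1,x)·a_{xk}·b_k(o_t)

* **Evolutionary optimizers** (`retscreen.evolution`) —
  * GA ensemble pruning with strict-majority fitness
    Acc = N_correct / N_total, roulette-wheel selection
    p_i = f_i / Σ_j f_j, variable-length 1-point crossover, and
    parents-vs-children elitist replacement;
  * GA-HMM structure/parameter evolution with Baum-Welch as local learner;
  * M-HMM, the memetic variant adding particle swarm optimization over
    the transition matrices of the selected top 20%;
  * C-HMM, synchronized co-evolution of an ensemble and the context HMM
    under a joint "ensemble-correct AND HMM-agrees" fitness.
* **Screening** (`retscreen.screening`) — per-image fusion: the MA verdict
  requires ensemble–HMM *agreement*, global detections are confirmed or
  down-weighted by local tile classifiers, and an image is abnormal iff
  any sign's weighted count reaches its threshold. Metrics are
  sensitivity tp/(tp+fn), specificity tn/(tn+fp), and the true-normal
  fraction among images called normal, tn/(tn+fn).

Most components are sklearn-style estimators (`fit` / `predict`,
`get_params`, trailing-underscore fitted attributes): `DiscreteHMM`,
`HmmContextClassifier`, `EnsemblePool`, `BlockCodebook`, `FundusScreener`.

## Worked example

```python
import numpy as np
from retscreen import SynthConfig, generate_image, FundusScreener, score_screen

size = (256, 256)
train = [generate_image(SynthConfig(image_size=size, n_ma=5, n_haem=3,
                                    n_bright=2, rng_seed=1000 + i))
         for i in range(10)] + \
        [generate_image(SynthConfig(image_size=size, rng_seed=2000 + i))
         for i in range(6)]

screener = FundusScreener(random_state=0).fit(train)

verdicts, truth = [], []
for seed in range(20):
    abnormal = seed < 10
    cfg = SynthConfig(image_size=size, rng_seed=seed,
                      **(dict(n_ma=5, n_haem=3, n_bright=2) if abnormal else {}))
    v = screener.screen_image(generate_image(cfg))
    print(seed, v.decision, v.counts())
    verdicts.append(v)
    truth.append(abnormal)

m = score_screen(verdicts, truth)
print(m.to_json())
```

Typical output (abbreviated):

```
0 abnormal {'MA': 0.0, 'HAEM': 1.5, 'BRIGHT': 2.0}
1 abnormal {'MA': 1.0, 'HAEM': 1.0, 'BRIGHT': 2.0}
...
10 normal {'MA': 0.0, 'HAEM': 0.0, 'BRIGHT': 0.0}
...
{'tp': 10, 'fp': 0, 'tn': 10, 'fn': 0,
 'sensitivity': 1.0, 'specificity': 1.0, 'npv_normal': 1.0}
```

Each count is the weighted number of accepted detections for that sign
(an unconfirmed detection counts 0.5); any count ≥ 1 refers the image as
abnormal. `v.evidence['MA'].detections` records, per candidate, whether
the ensemble and the HMM context model agreed (`source='agreed'`) or the
HMM rejected it (`source='hmm'`).

There is also a CLI: `retscreen synth | train | evolve | screen |
evaluate` (see `retscreen --help`).

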