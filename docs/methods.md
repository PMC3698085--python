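# Methods

`retscreen` implements a screening pipeline that separates normal from
abnormal digital fundus photographs by detecting the basic clinical signs
of diabetic retinopathy — microaneurysms (MA), haemorrhages, and bright
(exudate-like) lesions — with classifier ensembles and an HMM context
model, both optimized by evolutionary search, and fusing their evidence
into a per-image verdict. This note records the model assumptions, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not show.

## Synthetic study conditions

No clinical images ship with the package; every trainable stage is
exercised on simulated retinas with exact ground truth
(`retscreen.synth`). A simulated retina contains:

* a bright optic disc (OD; default radius 8% of the short image side), the
  brightest structure in the image;
* a darker macula placed two OD diameters from the disc centre;
* a vessel tree grown by recursive midpoint-displaced branching from the
  OD rim, segment width decaying by 0.75 per branch level — vessels thin
  with distance from the disc without any hemodynamic modelling;
* dark circular MAs (radius 1–3 px), kept ≥ 2 px clear of vessels by
  default; the clearance is configurable down to 0 to produce the hard
  near-vessel cases;
* larger irregular dark haemorrhages (radius 6–12 px, unions of displaced
  discs) and bright exudate clusters (closed unions of small bright dots);
* smooth pigment variation (Gaussian-filtered noise, sd 6 intensity units),
  sensor noise (sd 1.5), and a multiplicative linear illumination gradient
  (relative amplitude 0.25 at a random orientation).

Green-channel class contrasts are fixed so that, before illumination,
BRIGHT (+62) > background (120) > vessels = MAs = haemorrhages (−38), with
the OD at +95 and the macula at −26: dark lesions share the intensity range
of vessels, which is exactly the confusion the context model exists to
resolve. The label mask and region list are recorded *before* the
illumination gradient so detectors are scored against physical, not
photometric, truth. All randomness flows from one seeded generator; a
config is bit-reproducible.

What the generator does **not** emulate: camera colour response (RGB is an
affine map of the green channel), drusen and other non-DR bright deposits,
retinitis pigmentosa, vessel tortuosity/beading, image-quality artefacts,
or a circular camera aperture. Passing the synthetic screen therefore
demonstrates that the pipeline's machinery is correct and well calibrated
on images matching its assumptions — not clinical performance.

The sequence-level experiments use a second generator
(`synthetic_context_models`): three hidden Markov models (MA/BV/BG) whose
emission rows are biased toward class-specific bands of codebook symbols.
The `separation` knob sets class overlap; 0.35 gives the "well separated"
regime (per-class accuracy ≥ 0.99 for a plainly trained classifier), 0.1
gives a harder regime (~0.95) that leaves the evolutionary optimizers room
to differ. Scaled-down experiment sizes — 200 training sub-images per
category and 300 evaluation items for the context classifier, 150/240 for
the optimizer comparisons — keep every experiment inside desk-scale
runtimes while preserving the design of the originals.

## Preprocessing and segmentation (`image_ops`)

All contrast operations use the green channel; coordinates are 0-based
(row, col); bounding boxes are half-open.

* **Optic disc**: Gaussian smoothing, intensity gating at
  median + 0.6·(99.7th percentile − median), then a circular Hough
  refinement over the largest bright blob's boundary. We use this
  Hough-style refinement instead of an active deformable contour because
  centre and radius are all downstream stages consume. If the bright-peak
  contrast is below 25 intensity units the image is declared ungradable
  ("OD not found") rather than raising.
* **Macula**: dark-disc template match (disc-mean of the smoothed green
  channel, illumination-flattened by dividing out a coarse Gaussian
  surface) minimised over an annulus of radius 2·(2·od_radius) ± 50%
  around the disc; empty annulus ⇒ whole-image fallback flagged
  low-confidence.
* **Background**: a histogram-based rank median (kernel radius 24 px
  ≥ 2× the largest expected lesion diameter) followed by iterated dynamic
  thresholding: pixels deviating > 14 units from the surface (vessels,
  lesions, OD) are excluded and the surface re-estimated by normalized
  convolution, three passes. The iteration is what removes the OD's
  imprint from the estimate; on synthetic truth the estimate correlates
  > 0.9 with the true illumination × pigment surface.
* **Vessels**: shade-corrected green below an adaptive threshold
  (max(8, 2·1.4826·MAD of the negative residuals)), cleaned to elongated
  components (eccentricity ≥ 0.9). The mask is deliberately permissive —
  recall before precision — because the classifiers refine it.
* **Candidates**: dark components beyond a 10-unit margin under the
  background are watershed-split and partitioned by area at the area of a
  disc of radius 1.5% of image width (MA ≤ cutoff < haemorrhage); bright
  components beyond an 18-unit margin exclude the OD disc (×1.3 radius).
  Candidates are *never* filtered by vessel proximity: deleting everything
  near a vessel would delete the true MAs sitting next to vessels. The
  margins and kernel sizes above are package defaults, exposed in the
  function signatures; no external anchor fixes them.

## Features (`features`)

Each detector consumes a fixed subset of a common catalogue; the
detector×feature map ships as data (`FEATURE_TABLE`) and can be flipped
per detector without code changes. Global detectors (GBV, GH, GMA) score
candidate regions: green means inside/outside, HSI means and ratios
(I=(R+G+B)/3, S=1−min/I, H by the arccos form), area, boundary-pixel
perimeter, bounding-box statistics (height, width, fill ratio), major/minor
axis ratio, and circularity 4πA/P². Circularity uses the Crofton-style
perimeter estimate, which is unbiased on rasterized discs; the raw
boundary-pixel count (reported as the "perimeter" feature) is not. Ratios
with vanishing denominators return a large sentinel (1e6), never NaN.

Local detectors (LBV, LB, LDL, LBL) score 32×32 tiles: 8-bin per-channel
colour histograms, the 3×3 low-frequency Fourier magnitude corner, colour
PCA (eigenvalues + leading loadings; defined as zero on constant tiles),
a multi-scale even-symmetry ridge operator for phase symmetry (mean and
max), and GLCM texture at distance 1 averaged over 4 orientations
(contrast, energy, homogeneity).

The MA context model consumes 15×15 patches split into a 3×3 block grid in
row-major order. Each block yields (mean shade-corrected intensity,
intensity sd, gradient energy) and is vector-quantized by a seeded k-means
codebook (16 symbols by default) into one discrete symbol, giving 9-symbol
observation sequences. Discrete emissions were chosen over Gaussian ones
because the emission-table formulation is exactly testable against hand
computation and brute-force enumeration; the block-feature triple itself is
a design choice, not externally anchored.

## Discrete HMMs (`hmm`)

`DiscreteHMM` keeps π, a transition matrix A (optionally constrained by a
boolean topology mask that survives re-estimation exactly), and an
emission table B. All probability arithmetic is in log space with −∞
sentinels. Classification scores are **Viterbi path likelihoods** — the
probability of the single best state path — not forward likelihoods; the
forward recursion exists only inside Baum-Welch (as the EM E-step and its
monotone objective) and as an independent oracle in the tests.

Baum-Welch is vectorized over equal-length sequences with per-step
scaling. Zero-count emission cells are floored at 1e-6 and renormalized;
unvisited states fall back to uniform rows over the allowed topology. EM
is monotone but multimodal: `n_init` random restarts (4 for the recovery
experiment) keep the best final likelihood. With 500 length-9 sequences
from a 3-state generator with distinct emission peaks, the transition
matrix is recovered within 0.1 per entry up to state permutation.

The context classifier trains one model per category (MA/BV/BG) and
assigns a patch to the highest path likelihood; exact ties resolve MA
before BV before BG, because screening favours sensitivity.

## Ensembles (`ensembles`)

Each detector's pool spans 3 training algorithms × 10 hidden-layer sizes ×
3 weight initialisations = 90 feed-forward networks per feature set (180
or 270 for two- or three-set detectors). The three algorithms default to
plain SGD, SGD with momentum 0.9, and L-BFGS; the ten hidden sizes to
{2, 4, …, 20} — any three distinct optimizers and ten sizes satisfy the
design, and both are configurable. Members that fail to converge within
their iteration budget are retained (the GA may still select them) but
flagged. Combination rules: best single member (by recorded holdout
accuracy), average of posteriors, sum of posteriors, and majority vote;
average and sum share their argmax identically, and all ties resolve to
the positive (lesion) class. The deployed rule is averaging with a 0.5
posterior threshold.

## Evolutionary optimizers (`evolution`)

* **Fitness (ensemble pruning)**: strict-majority accuracy — a sample is
  correct iff *more than half* of the chromosome's members predict its
  true label; an exact half counts as incorrect. The prose around the
  published fitness calls this the "average rule" while describing
  majority counting; we implement the counting as described and keep the
  averaging combiner for deployment only.
* **Selection**: roulette wheel, p_i = f_i/Σf, drawn with replacement;
  all-zero fitness falls back to uniform. 80% of the population is
  selected for crossover each generation.
* **Crossover**: 1-point with cut points drawn *independently per parent*
  (chromosome lengths differ); duplicate genes are deduplicated keeping
  the first occurrence, and an empty child inherits one random parent
  gene.
* **Replacement**: a parent re-enters iff its fitness strictly exceeds
  both of its children's; the population is restored to constant size by
  stable truncation of the lowest-fitness entrants (ties keep the earlier
  entrant), topped up with fresh random chromosomes, with the best-ever
  individual always retained — so the best-fitness trajectory is
  non-decreasing by construction.
* **HMM chromosomes** carry state genes (emission rows travel with their
  genes), a transition matrix, and a topology kind (full, or a sparse
  self-loop + forward-neighbour band). Baum-Welch (8 sweeps per
  evaluation) is the local learner and its parameters are written back to
  the chromosome (Lamarckian). After crossover, genes that moved or
  arrived from the other parent are marked; mutation redraws exactly the
  marked transition rows from a uniform Dirichlet over the topology.
  State counts are randomized in 3–8.
* **Per-class evolution**: one run evolves the model of a single target
  category while fixed "rival" models (plain Baum-Welch fits) stand in
  for the other two; fitness is the 3-way held-out classification
  accuracy. This mirrors reporting accuracy per category and keeps the
  search space small; rival likelihoods are cached once per run.
* **M-HMM**: immediately after selection, PSO refines the transition
  matrices of the top 20% of selected individuals. Particles live on the
  row-stochastic simplex: after each velocity update
  (w=0.7, c1=c2=1.5, swarm 10, 20 iterations — defaults chosen in the
  common PSO range, nothing external fixes them) rows are clipped at 0,
  masked, and renormalized. PSO fitness is held-out accuracy with the
  particle's matrix; the best particle is written back. A 1-state model
  is a no-op.
* **C-HMM**: ensemble and HMM populations evolve in lock-step, pair i
  with pair i. Joint fitness = fraction of evaluation items where the
  ensemble decision is correct AND the HMM decision agrees with it;
  agreement on a wrong decision scores nothing — rewarding agreement
  alone would favour jointly-wrong pairs.

All optimizers are bit-reproducible under a fixed seed and resolve fitness
ties by lowest index.

## Screening (`screening`)

For a new image: build the retina map (OD failure ⇒ ungradable, referred
by default); run the MA agreement rule (evolved ensemble accepts ⇒ HMM
context classifier must also say MA; rejected candidates stay in the
evidence trail as black-box entries); run the haemorrhage and
bright-lesion ensembles on their candidates (the global bright detector
reuses the GH region schema, since the catalogue defines bright-lesion
features only at tile scale); classify every 32×32 tile with the four
local ensembles. A global detection whose centre tile the matching local
detector also flags (dark-lesion tile for MA/haemorrhage, bright-lesion
tile for exudates) is confirmed at weight 1; otherwise it is down-weighted
to 0.5. The image is abnormal iff any sign's weighted count reaches its
threshold (default 1.0 per sign: one confirmed lesion — or two
unconfirmed — refers the image). This confirm/down-weight rule is the
package's concrete instantiation of a global–local "reasoning mechanism"
that is otherwise unspecified; both the weight and the thresholds are
configuration.

Metrics: sensitivity tp/(tp+fn), specificity tn/(tn+fp), and the
true-normal fraction among system-normal images tn/(tn+fn). Ratios with
empty denominators are reported as undefined (None), never 0 or NaN.

## Experiment scales

The end-to-end screen experiment trains on 16 images (10 abnormal with
5 MA + 3 haemorrhages + 2 bright lesions each, 6 normal) at 256×256 — the
generator's default stays 512×512; resolution is a free parameter of the
synthetic conditions — and screens 100 unseen images (50/50). The
evolutionary comparisons run at population 30 × 30 generations (pruning
and HMM evolution) and 20 × 10 (synchronized co-evolution, which is by far
the most expensive optimizer). These sizes are the package's chosen
desk-scale analogues of the original experiment shapes.

## Known limitations

* Synthetic lesions are high-contrast and morphologically clean; nothing
  here measures performance on subtle, low-contrast clinical lesions.
* The context model covers MAs only; haemorrhage/bright-lesion decisions
  rely on ensembles plus tile confirmation alone.
* Patient-level aggregation, image-quality grading beyond OD-found, and
  drusen/RP discrimination are out of scope.
* The GA-HMM/M-HMM comparison is a paired-seed ordering property, not an
  effect-size claim; at high class separation both optimizers saturate
  and tie.
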