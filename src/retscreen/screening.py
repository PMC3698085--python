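"""Normal/abnormal screening decisions.

The screener runs every detector on a new image and fuses their evidence:

* microaneurysms use the *agreement rule* — a candidate counts only if the
  evolved MA ensemble and the three-model HMM context classifier agree it
  is an MA (candidates the ensemble accepts but the HMM rejects are kept in
  the evidence list, marked, and excluded from the count);
* haemorrhage and bright-lesion candidates are scored by their global
  ensembles;
* local 32x32 tile classifiers cross-check each global detection: a
  detection whose tile the matching local detector also flags is confirmed
  (weight 1), otherwise down-weighted (default 0.5);
* an image is abnormal iff any sign's weighted count reaches its threshold
  (default 1.0: a single confirmed lesion refers the image), and
  ungradable iff the optic disc cannot be found (by default ungradable
  images are referred, i.e. counted abnormal — screening favours safety).

Scores are sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), and the
normal-predictive fraction tn/(tn+fn) ("of the images called normal, how
many truly are").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import image_ops
from .ensembles import EnsemblePool
from .evolution import GAConfig, evolve_ensemble
from .features import (BlockCodebook, block_features, feature_names,
                       hmm_observation_sequence, region_features, tile_features)
from .hmm import HmmContextClassifier
from .image_ops import CandidateRegion, RetinaMap, build_retina_map
from .synth import LABELS, LabeledFundus, sample_subimages

__all__ = [
    "SignEvidence",
    "ImageVerdict",
    "ScreenMetrics",
    "FundusScreener",
    "detect_ma",
    "screen_image",
    "score_screen",
    "annotate_ma",
]

_SIGNS = ("MA", "HAEM", "BRIGHT")
#: local detector that confirms each global sign
_CONFIRMER = {"MA": "LDL", "HAEM": "LDL", "BRIGHT": "LBL"}


@dataclass
class Detection:
    region: CandidateRegion
    score: float
    source: str          # ensemble | hmm | agreed
    confirmed: bool = True
    weight: float = 1.0


@dataclass
class SignEvidence:
    sign: str
    detections: list[Detection] = field(default_factory=list)

    @property
    def count(self) -> float:
        """Weighted number of accepted detections."""
        accepted = "agreed" if self.sign == "MA" else "ensemble"
        return float(sum(d.weight for d in self.detections if d.source == accepted))


@dataclass
class ImageVerdict:
    decision: str                      # normal | abnormal | ungradable
    evidence: dict = field(default_factory=dict)
    retina_map: RetinaMap | None = None

    def counts(self) -> dict:
        return {s: (self.evidence[s].count if s in self.evidence else 0.0)
                for s in _SIGNS}


@dataclass
class ScreenMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    def _ratio(self, num: int, den: int):
        return num / den if den > 0 else None   # undefined, never NaN

    @property
    def sensitivity(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def npv_normal(self):
        """Fraction of system-normal images that are truly normal."""
        return self._ratio(self.tn, self.tn + self.fn)

    def to_json(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "npv_normal": self.npv_normal}


class UnloadedModelError(RuntimeError):
    pass


def score_screen(verdicts, truth_labels, ungradable_policy: str = "refer") -> ScreenMetrics:
    """Confusion counts with abnormal = positive.

    ``truth_labels``: True/"abnormal" for abnormal images.  Ungradable
    verdicts count as abnormal under the default "refer" policy, or as
    normal under "pass".
    """
    verdicts = list(verdicts)
    truths = [t if isinstance(t, bool) else str(t).lower() == "abnormal"
              for t in truth_labels]
    if len(verdicts) == 0 or len(verdicts) != len(truths):
        raise ValueError("need equal-length, nonempty verdict and truth lists")
    tp = fp = tn = fn = 0
    for v, truth_abnormal in zip(verdicts, truths):
        d = v.decision if isinstance(v, ImageVerdict) else str(v)
        if d == "ungradable":
            d = "abnormal" if ungradable_policy == "refer" else "normal"
        pred_abnormal = d == "abnormal"
        if pred_abnormal and truth_abnormal:
            tp += 1
        elif pred_abnormal:
            fp += 1
        elif truth_abnormal:
            fn += 1
        else:
            tn += 1
    return ScreenMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------

class FundusScreener:
    """End-to-end trainable screener (sklearn-style estimator).

    ``fit`` consumes labeled images and trains, in order: the global
    candidate ensembles (MA, haemorrhage, bright lesion), the four local
    tile ensembles, the block codebook + MA/BV/BG context HMMs, and the GA
    pruning of the MA pool.  ``predict`` maps images to
    :class:`ImageVerdict` objects.

    The per-sign abnormality thresholds default to 1.0 — any single
    confirmed lesion refers the image.
    """

    def __init__(self,
                 hidden_sizes: tuple = tuple(range(2, 21, 2)),
                 ma_patch_size: int = 15,
                 tile_size: int = 32,
                 n_symbols: int = 16,
                 hmm_states: int = 3,
                 posterior_threshold: float = 0.5,
                 down_weight: float = 0.5,
                 thresholds: dict | None = None,
                 ga_config: GAConfig | None = None,
                 evolve_ma: bool = True,
                 random_state: int = 0):
        self.hidden_sizes = hidden_sizes
        self.ma_patch_size = ma_patch_size
        self.tile_size = tile_size
        self.n_symbols = n_symbols
        self.hmm_states = hmm_states
        self.posterior_threshold = posterior_threshold
        self.down_weight = down_weight
        self.thresholds = thresholds
        self.ga_config = ga_config
        self.evolve_ma = evolve_ma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "hidden_sizes", "ma_patch_size", "tile_size", "n_symbols",
            "hmm_states", "posterior_threshold", "down_weight", "thresholds",
            "ga_config", "evolve_ma", "random_state")}

    def set_params(self, **params) -> "FundusScreener":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- training helpers -------------------------------------------------
    @staticmethod
    def _match(cand: CandidateRegion, truth_regions, cls: str, iou: float = 0.3) -> bool:
        for r in truth_regions:
            if r.cls != cls:
                continue
            inter = int((cand.mask & r.mask).sum())
            if inter == 0:
                continue
            union = int((cand.mask | r.mask).sum())
            if inter / union > iou or inter / r.mask.sum() > 0.5:
                return True
        return False

    _SCHEMA_FOR = {"MA": "GMA", "HAEM": "GH", "BRIGHT": "GH"}

    def _candidate_features(self, img: LabeledFundus, rm: RetinaMap, hyp: str):
        cands = image_ops.extract_candidates(img, rm, hyp)
        schema = self._SCHEMA_FOR[hyp]
        if not cands:
            return cands, np.empty((0, len(feature_names(schema))))
        X = np.stack([region_features(c, img, rm.background_estimate, schema).values
                      for c in cands])
        return cands, X

    def _tile_label(self, img: LabeledFundus, r0: int, c0: int) -> str:
        size = self.tile_size
        block = img.label_mask[r0:r0 + size, c0:c0 + size]
        if ((block == LABELS["MA"]) | (block == LABELS["HAEM"])).sum() >= 4:
            return "LDL"
        if (block == LABELS["BRIGHT"]).sum() >= 4:
            return "LBL"
        if (block == LABELS["BV"]).mean() > 0.05:
            return "LBV"
        return "LB"

    def fit(self, images: list[LabeledFundus], eval_fraction: float = 0.3
            ) -> "FundusScreener":
        rng = np.random.default_rng(self.random_state)
        n_eval = max(1, int(round(eval_fraction * len(images))))
        eval_imgs, train_imgs = images[:n_eval], images[n_eval:]
        if not train_imgs:
            raise ValueError("need at least 2 images to fit")

        # ---- global candidate samples ----
        glob = {s: {"X": [], "y": []} for s in _SIGNS}
        glob_eval = {s: {"X": [], "y": []} for s in _SIGNS}
        maps = {}
        for img_set, store in ((train_imgs, glob), (eval_imgs, glob_eval)):
            for img in img_set:
                rm = build_retina_map(img)
                maps[id(img)] = rm
                for hyp in _SIGNS:
                    cands, X = self._candidate_features(img, rm, hyp)
                    ylab = [self._match(c, img.regions, hyp) for c in cands]
                    store[hyp]["X"].append(X)
                    store[hyp]["y"].extend(ylab)

        self.pools_ = {}
        for hyp in _SIGNS:
            X = np.concatenate(glob[hyp]["X"])
            y = np.asarray(glob[hyp]["y"], dtype=int)
            pool = EnsemblePool(detector=self._SCHEMA_FOR[hyp],
                                hidden_sizes=self.hidden_sizes,
                                positive_threshold=self.posterior_threshold,
                                random_state=self.random_state)
            pool.fit(X, y)
            self.pools_[hyp] = pool

        # ---- GA pruning of the MA pool on held-out candidates ----
        Xe = np.concatenate(glob_eval["MA"]["X"])
        ye = np.asarray(glob_eval["MA"]["y"], dtype=int)
        if self.evolve_ma and len(np.unique(ye)) == 2:
            cfg = self.ga_config or GAConfig(population_size=20, generations=12,
                                             rng_seed=self.random_state)
            self.ma_subset_ = evolve_ensemble(self.pools_["MA"], (Xe, ye),
                                              cfg=cfg).member_indices
        else:
            self.ma_subset_ = list(range(len(self.pools_["MA"])))

        # ---- local tile ensembles ----
        tiles_X = {s: [] for s in ("LB", "LBV", "LDL", "LBL")}
        tiles_y = {s: [] for s in ("LB", "LBV", "LDL", "LBL")}
        for img in train_imgs:
            rm = maps[id(img)]
            for tile in image_ops.tile_local(img, self.tile_size):
                r0, c0 = tile.position
                lab = self._tile_label(img, r0, c0)
                bg_tile = rm.background_estimate[r0:r0 + self.tile_size,
                                                 c0:c0 + self.tile_size]
                if bg_tile.shape != tile.pixels.shape[:2]:
                    bg_tile = None
                for schema in tiles_X:
                    fv = tile_features(tile.pixels, schema, background_tile=bg_tile)
                    tiles_X[schema].append(fv.values)
                    tiles_y[schema].append(int(lab == schema))
        self.local_pools_ = {}
        for schema in tiles_X:
            X = np.stack(tiles_X[schema])
            y = np.asarray(tiles_y[schema])
            if len(np.unique(y)) < 2:   # degenerate: class absent in training
                self.local_pools_[schema] = None
                continue
            pool = EnsemblePool(detector=schema, hidden_sizes=self.hidden_sizes,
                                positive_threshold=self.posterior_threshold,
                                random_state=self.random_state + 17)
            pool.fit(X, y)
            self.local_pools_[schema] = pool

        # ---- context models ----
        patches, labels, bgs = [], [], []
        for img in train_imgs:
            rm = maps[id(img)]
            half = self.ma_patch_size // 2
            for cls, n in (("MA", 30), ("BV", 30), ("BG", 30)):
                for p in sample_subimages(img, cls, self.ma_patch_size, n,
                                          seed=int(rng.integers(2 ** 31))):
                    cy, cx = p.center
                    patches.append(p.pixels)
                    labels.append(cls)
                    bgs.append(rm.background_estimate[cy - half:cy - half + self.ma_patch_size,
                                                      cx - half:cx - half + self.ma_patch_size])
        self.codebook_ = BlockCodebook(self.n_symbols,
                                       random_state=self.random_state)
        self.codebook_.fit(np.concatenate([
            block_features(p, b) for p, b in zip(patches, bgs)]))
        seqs = np.stack([hmm_observation_sequence(p, self.codebook_, b)
                         for p, b in zip(patches, bgs)])
        self.context_ = HmmContextClassifier(
            n_states=self.hmm_states, n_symbols=self.n_symbols,
            random_state=self.random_state).fit(seqs, np.asarray(labels))
        self.thresholds_ = dict(self.thresholds or {s: 1.0 for s in _SIGNS})
        return self

    # -- inference --------------------------------------------------------
    def _require_fitted(self) -> None:
        if not hasattr(self, "pools_"):
            raise UnloadedModelError("screener has no trained model bundle")

    def detect_ma(self, img, rm: RetinaMap) -> SignEvidence:
        """Agreement-rule MA detection (white box = agreed MA, black box =
        HMM-rejected candidate, recorded via the detection source)."""
        self._require_fitted()
        cands, X = self._candidate_features(img, rm, "MA")
        ev = SignEvidence(sign="MA")
        if not cands:
            return ev
        dec, score = self.pools_["MA"].combine(X, subset=self.ma_subset_,
                                               rule="average")
        half = self.ma_patch_size // 2
        h, w = rm.background_estimate.shape
        rgb = img.rgb if hasattr(img, "rgb") else np.asarray(img)
        for c, d, s in zip(cands, dec, score):
            if not d:
                continue
            cy = int(np.clip(round(c.centroid[0]), half, h - half - 1))
            cx = int(np.clip(round(c.centroid[1]), half, w - half - 1))
            patch = rgb[cy - half:cy - half + self.ma_patch_size,
                        cx - half:cx - half + self.ma_patch_size]
            bg = rm.background_estimate[cy - half:cy - half + self.ma_patch_size,
                                        cx - half:cx - half + self.ma_patch_size]
            obs = hmm_observation_sequence(patch, self.codebook_, bg)
            hmm_cls = self.context_.predict(obs[None, :])[0]
            source = "agreed" if hmm_cls == "MA" else "hmm"
            ev.detections.append(Detection(region=c, score=float(s), source=source))
        return ev

    def _confirm(self, ev: SignEvidence, tile_scores: dict) -> None:
        """Cross-check detections against local tile classifications."""
        schema = _CONFIRMER[ev.sign]
        scores = tile_scores.get(schema)
        for d in ev.detections:
            if scores is None:
                d.confirmed, d.weight = True, 1.0
                continue
            tr = int(d.region.centroid[0]) // self.tile_size
            tc = int(d.region.centroid[1]) // self.tile_size
            ok = scores.get((tr, tc), 0.0) >= self.posterior_threshold
            d.confirmed = bool(ok)
            d.weight = 1.0 if ok else self.down_weight

    def screen_image(self, img) -> ImageVerdict:
        self._require_fitted()
        rm = build_retina_map(img)
        if not rm.od_found:
            return ImageVerdict(decision="ungradable", retina_map=rm)

        # local tile classification
        tile_scores: dict[str, dict] = {}
        tiles = image_ops.tile_local(img, self.tile_size)
        for schema, pool in self.local_pools_.items():
            if pool is None:
                continue
            X = np.stack([tile_features(t.pixels, schema).values for t in tiles])
            _, s = pool.combine(X, rule="average")
            tile_scores[schema] = {
                (t.position[0] // self.tile_size, t.position[1] // self.tile_size): float(v)
                for t, v in zip(tiles, s)}

        evidence = {"MA": self.detect_ma(img, rm)}
        for hyp in ("HAEM", "BRIGHT"):
            cands, X = self._candidate_features(img, rm, hyp)
            ev = SignEvidence(sign=hyp)
            if cands:
                dec, score = self.pools_[hyp].combine(X, rule="average")
                for c, d, s in zip(cands, dec, score):
                    if d:
                        ev.detections.append(Detection(region=c, score=float(s),
                                                       source="ensemble"))
            evidence[hyp] = ev
        for ev in evidence.values():
            self._confirm(ev, tile_scores)
        abnormal = any(evidence[s].count >= self.thresholds_.get(s, 1.0)
                       for s in _SIGNS)
        return ImageVerdict(decision="abnormal" if abnormal else "normal",
                            evidence=evidence, retina_map=rm)

    def predict(self, images) -> list[ImageVerdict]:
        return [self.screen_image(img) for img in images]

    # -- persistence ------------------------------------------------------
    def to_json(self) -> dict:
        self._require_fitted()
        return {
            "schema": "retscreen-bundle-1",
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()
                       if k not in ("ga_config", "thresholds")},
            "pools": {s: p.to_json() for s, p in self.pools_.items()},
            "local_pools": {s: (p.to_json() if p is not None else None)
                            for s, p in self.local_pools_.items()},
            "ma_subset": list(map(int, self.ma_subset_)),
            "codebook": self.codebook_.to_json(),
            "context_models": {c: m.to_json()
                               for c, m in self.context_.models_.items()},
            "thresholds": self.thresholds_,
        }

    @classmethod
    def from_json(cls, d: dict) -> "FundusScreener":
        from .hmm import DiscreteHMM

        params = dict(d["params"])
        params["hidden_sizes"] = tuple(params.get("hidden_sizes", ()))
        scr = cls(**params)
        scr.pools_ = {s: EnsemblePool.from_json(p) for s, p in d["pools"].items()}
        scr.local_pools_ = {s: (EnsemblePool.from_json(p) if p else None)
                            for s, p in d["local_pools"].items()}
        scr.ma_subset_ = d["ma_subset"]
        scr.codebook_ = BlockCodebook.from_json(d["codebook"])
        scr.context_ = HmmContextClassifier(
            n_states=scr.hmm_states, n_symbols=scr.n_symbols).set_models(
            {c: DiscreteHMM.from_json(m) for c, m in d["context_models"].items()})
        scr.thresholds_ = d["thresholds"]
        return scr

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path) -> "FundusScreener":
        import json
        from pathlib import Path

        return cls.from_json(json.loads(Path(path).read_text()))


def annotate_ma(img, evidence: SignEvidence) -> np.ndarray:
    """White boxes around agreed MAs, black boxes around rejected candidates."""
    rgb = (img.rgb if hasattr(img, "rgb") else np.asarray(img)).copy()
    h, w = rgb.shape[:2]
    for d in evidence.detections:
        r0, c0, r1, c1 = d.region.bbox
        r0, c0 = max(0, r0 - 2), max(0, c0 - 2)
        r1, c1 = min(h, r1 + 2), min(w, c1 + 2)
        colour = 255 if d.source == "agreed" else 0
        rgb[r0:r1, [c0, c1 - 1]] = colour
        rgb[[r0, r1 - 1], c0:c1] = colour
    return rgb


# ---------------------------------------------------------------------------
# functional wrappers

def detect_ma(img, retina_map: RetinaMap, screener: FundusScreener) -> SignEvidence:
    return screener.detect_ma(img, retina_map)


def screen_image(img, screener: FundusScreener,
                 thresholds: dict | None = None) -> ImageVerdict:
    if thresholds is not None:
        screener.thresholds_ = dict(thresholds)
    return screener.screen_image(img)
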