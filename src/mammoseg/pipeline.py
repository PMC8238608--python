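"""End-to-end orchestration: segmentation, benchmark and classification.

Two experiments are wired here, mirroring the package's evaluation design:

* a segmentation benchmark comparing seed-selection strategies (hand seeding
  at the truth centroid, a pessimistic random-seed hand baseline, FCM-GA
  automatic seeding, and GMM segmentation) by Jaccard, RMS and pixel-level
  confusion metrics over a phantom dataset;
* a classification experiment extracting GLCM features from each image's
  ROI and scoring a PNN by leave-one-out prediction with one-vs-rest
  confusion metrics and a ROC curve.

Every stochastic step consumes a child seed derived from one global seed, so
runs with equal configuration are bit-identical.
"""

from __future__ import annotations

import copy
import hashlib

import numpy as np
import pandas as pd
from scipy import ndimage

from . import evaluate, features, pnn
from .gmm_hmrf import HMRFConfig, gmm_em_fit, gmm_segment, hmrf_refine
from .phantom import CLASS_ORDER, PhantomSpec, make_dataset
from .preprocess import FilterConfig, adaptive_median_filter, to_uint8
from .region_grow import GrowConfig, grow_all, grow_region
from .seed_selection import (
    GAConfig,
    SeedPoint,
    fcm_memberships,
    ga_optimize,
    image_histogram_weights,
)

#: Default run configuration; sections mirror the module defaults.
DEFAULT_CONFIG = {
    "rng_seed": 0,
    "preprocess": {"initial_window": 3, "max_window": 7},
    "fcm_ga": {
        "clusters": 10,
        "population_size": 100,
        "mutation_rate": 0.2,
        "crossover_rate": 0.8,
        "generations": 50,
        "mutation_sigma": 10.0,
        "fuzzifier": 2.0,
        "n_seed_candidates": 5,
        "candidate_spacing": 5,
    },
    "grow": {
        "criterion": "std_band",
        "X": 3.0,
        "connectivity": 8,
        "bootstrap_min": 9,
        "sigma_floor": 1.0,
    },
    "gmm": {"components": 2, "iters": 100, "mode": "full", "hmrf": False,
            "beta": 1.0},
    # fixed-threshold regrow used when every std-band growth collapses
    # below the minimum area (X = half the expected mass contrast)
    "grow_fallback": {"enabled": True, "X": 30.0},
    "features": {"levels": 16},
    "pnn": {"sigma": 0.5, "positive_class": "malignant"},
    "mask_area": {"min_pixels": 32, "max_fraction": 0.15},
}


class UsageError(ValueError):
    """Invalid pipeline invocation (e.g. hand mode without a seed)."""


def merge_config(overrides: dict | None) -> dict:
    """DEFAULT_CONFIG with a nested override dict applied; unknown keys rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def apply(base, over, path=""):
        for key, val in (over or {}).items():
            if key not in base:
                raise KeyError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict):
                if not isinstance(val, dict):
                    raise KeyError(f"config section {path + key!r} must be a mapping")
                apply(base[key], val, path + key + ".")
            else:
                base[key] = val

    apply(cfg, overrides)
    return cfg


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _grow_config(cfg: dict) -> GrowConfig:
    return GrowConfig(**cfg["grow"])


def _area_bounds(cfg: dict, shape) -> tuple[int, int]:
    lo = int(cfg["mask_area"]["min_pixels"])
    hi = int(cfg["mask_area"]["max_fraction"] * shape[0] * shape[1])
    return lo, hi


def _bounded_mask(mask: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Apply the no-tumor rule: masks outside [lo, hi] pixels become empty."""
    area = int(mask.sum())
    if area < lo or area > hi:
        return np.zeros_like(mask)
    return mask


def fcm_ga_seed_candidates(image: np.ndarray, cfg: dict, rng_seed: int):
    """Spaced high-membership pixels of the brightest FCM-GA cluster."""
    sec = cfg["fcm_ga"]
    ga_cfg = GAConfig(
        population_size=sec["population_size"],
        mutation_rate=sec["mutation_rate"],
        crossover_rate=sec["crossover_rate"],
        generations=sec["generations"],
        mutation_sigma=sec["mutation_sigma"],
        rng_seed=rng_seed,
    )
    values, counts = image_histogram_weights(image)
    best, _ = ga_optimize(values, sec["clusters"], config=ga_cfg, weights=counts)
    centers = np.asarray(best.genes, dtype=float)
    target = int(np.argmax(centers))
    u = fcm_memberships(image.astype(float).ravel(), centers, sec["fuzzifier"])
    member = u[target].reshape(image.shape)
    order = np.argsort(member.ravel(), kind="stable")[::-1]
    spacing = sec["candidate_spacing"]
    picked = []
    for flat in order[:512]:
        r, c = divmod(int(flat), image.shape[1])
        if all(max(abs(r - pr), abs(c - pc)) >= spacing for pr, pc in picked):
            picked.append((r, c))
        if len(picked) >= sec["n_seed_candidates"]:
            break
    seeds = [SeedPoint(row=r, col=c, cluster_id=target) for r, c in picked]
    return seeds, best


def _grow_mask_with_bounds(image, seeds, cfg):
    """Grow from candidate seeds; keep the largest mask inside area bounds.

    If every growth stalls below the minimum area (the std band can collapse
    when the bootstrap phase traps a tiny, too-homogeneous neighborhood),
    the seeds are regrown once with the fixed-threshold similarity
    criterion; oversized growths (leaks) never trigger the fallback.
    """
    gc = _grow_config(cfg)
    lo, hi = _area_bounds(cfg, image.shape)
    best_mask = np.zeros(image.shape, dtype=np.uint8)
    best_area = -1
    max_seen = 0
    for seed in seeds:
        mask, _state = grow_region(image, seed, gc)
        area = int(mask.sum())
        max_seen = max(max_seen, area)
        if lo <= area <= hi and area > best_area:
            best_mask, best_area = mask, area
    fb = cfg["grow_fallback"]
    if best_area < 0 and max_seen < lo and fb["enabled"]:
        fallback = GrowConfig(criterion="threshold", X=fb["X"],
                              connectivity=gc.connectivity,
                              bootstrap_min=gc.bootstrap_min,
                              sigma_floor=gc.sigma_floor)
        for seed in seeds:
            mask, _state = grow_region(image, seed, fallback)
            area = int(mask.sum())
            if lo <= area <= hi and area > best_area:
                best_mask, best_area = mask, area
    return best_mask


def pipeline_segment(image: np.ndarray, method: str, config: dict | None = None,
                     seed_point=None, rng_seed: int | None = None):
    """Filter then segment one image; returns (mask, provenance record).

    Methods: ``hand`` (explicit seed), ``fcm-ga`` (automatic seeding),
    ``gmm`` / ``gmm-hmrf`` (mixture segmentation, brightest component).
    A detection whose area falls outside the configured bounds is treated as
    "no tumor" and reported as an empty mask.
    """
    cfg = config if isinstance(config, dict) and "rng_seed" in config else merge_config(config)
    seed = cfg["rng_seed"] if rng_seed is None else rng_seed
    img = to_uint8(np.asarray(image))
    filtered = adaptive_median_filter(img, FilterConfig(**cfg["preprocess"]))
    prov = {
        "method": method,
        "rng_seed": int(seed),
        "config": copy.deepcopy(cfg),
        "input_sha1": _digest(img),
        "filtered_sha1": _digest(filtered),
    }
    lo, hi = _area_bounds(cfg, img.shape)

    if method == "hand":
        if seed_point is None:
            raise UsageError("hand method requires explicit seed coordinates")
        mask, _ = grow_region(filtered, seed_point, _grow_config(cfg))
        mask = _bounded_mask(mask, lo, hi)
        prov["seed"] = tuple(
            (seed_point.row, seed_point.col)
            if hasattr(seed_point, "row") else seed_point
        )
    elif method == "fcm-ga":
        seeds, best = fcm_ga_seed_candidates(filtered, cfg, seed)
        mask = _grow_mask_with_bounds(filtered, seeds, cfg)
        prov["seed_candidates"] = [(s.row, s.col) for s in seeds]
        prov["ga_best_fitness"] = float(best.fitness)
        prov["ga_centers"] = np.asarray(best.genes).round(3).tolist()
    elif method in ("gmm", "gmm-hmrf"):
        sec = cfg["gmm"]
        params, _hist = gmm_em_fit(
            filtered.ravel(), k=sec["components"], iters=sec["iters"],
            mode=sec["mode"], rng_seed=seed,
        )
        labels = gmm_segment(filtered, params)
        if method == "gmm-hmrf" or sec["hmrf"]:
            labels = hmrf_refine(filtered, labels, params,
                                 HMRFConfig(beta=sec["beta"]))
        bright = int(np.argmax(params.means))
        comp, n_comp = ndimage.label(labels == bright,
                                     structure=np.ones((3, 3), dtype=int))
        if n_comp == 0:
            mask = np.zeros(img.shape, dtype=np.uint8)
        else:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       index=np.arange(1, n_comp + 1))
            mask = (comp == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        mask = _bounded_mask(mask, lo, hi)
        prov["gmm_means"] = params.means.round(3).tolist()
    else:
        raise UsageError(f"unknown segmentation method {method!r}")

    prov["mask_area"] = int(mask.sum())
    prov["mask_sha1"] = _digest(mask)
    return mask, prov


BENCHMARK_METHODS = ("hand", "fcm-ga", "gmm")
BENCHMARK_COLUMNS = ("jaccard", "jaccard_distance", "rms", "sensitivity",
                     "specificity", "precision", "fall_out")


def _truth_centroid(mask: np.ndarray):
    rr, cc = np.nonzero(mask)
    return SeedPoint(row=int(round(rr.mean())), col=int(round(cc.mean())))


def pipeline_benchmark(items, config: dict | None = None,
                       hand_mode: str = "centroid"):
    """Per-method segmentation metrics over a dataset.

    ``items`` is a list of (image, truth_mask, class_label).  The hand
    baseline seeds at the truth centroid (``hand_mode="centroid"``) or at a
    uniformly random pixel (``hand_mode="random"``, the pessimistic variant);
    normal images (empty truth) skip hand seeding and score the empty mask.
    Returns a 3-row DataFrame indexed by method with 7 metric columns.
    """
    cfg = merge_config(config)
    master = np.random.default_rng(cfg["rng_seed"])
    rows = {}
    child_seeds = {
        m: [int(master.integers(0, 2**31 - 1)) for _ in items]
        for m in BENCHMARK_METHODS
    }
    for method in BENCHMARK_METHODS:
        jac, rms = [], []
        tp = tn = fp = fn = 0
        for idx, (image, truth, _label) in enumerate(items):
            seed = child_seeds[method][idx]
            if method == "hand":
                if truth.sum() == 0:
                    mask = np.zeros_like(truth)
                else:
                    if hand_mode == "centroid":
                        sp = _truth_centroid(truth)
                    else:
                        rng = np.random.default_rng(seed)
                        sp = SeedPoint(
                            row=int(rng.integers(0, image.shape[0])),
                            col=int(rng.integers(0, image.shape[1])),
                        )
                    mask, _ = pipeline_segment(image, "hand", cfg,
                                               seed_point=sp, rng_seed=seed)
            else:
                mask, _ = pipeline_segment(image, method, cfg, rng_seed=seed)
            j, _d = evaluate.jaccard(mask, truth)
            jac.append(j)
            rms.append(evaluate.rms_error(mask, truth))
            c = evaluate.pixel_confusion(mask, truth)
            tp += c.TP
            tn += c.TN
            fp += c.FP
            fn += c.FN
        counts = evaluate.ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
        m = evaluate.metrics(counts)
        rows[method] = {
            "jaccard": float(np.mean(jac)),
            "jaccard_distance": float(1.0 - np.mean(jac)),
            "rms": float(np.mean(rms)),
            "sensitivity": m["sensitivity"],
            "specificity": m["specificity"],
            "precision": m["precision"],
            "fall_out": m["fall_out"],
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(BENCHMARK_COLUMNS))


def roi_for_features(image: np.ndarray, mask: np.ndarray,
                     config: dict | None = None) -> np.ndarray:
    """ROI used for texture features.

    A non-empty tumor mask is used directly; for tumor-free images the image
    is partitioned by region growing and the brightest region of at least
    ``mask_area.min_pixels`` pixels serves as the reference tissue ROI.
    """
    cfg = merge_config(config) if not (isinstance(config, dict) and "rng_seed" in config) else config
    if mask is not None and np.asarray(mask).sum() > 0:
        return np.asarray(mask).astype(np.uint8)
    img = to_uint8(np.asarray(image))
    filtered = adaptive_median_filter(img, FilterConfig(**cfg["preprocess"]))
    labels, k = grow_all(filtered, seeds=None, config=_grow_config(cfg))
    min_px = cfg["mask_area"]["min_pixels"]
    best_label, best_mean = None, -np.inf
    for l in range(k):
        sel = labels == l
        n = int(sel.sum())
        if n >= min_px:
            mean = float(filtered[sel].mean())
            if mean > best_mean:
                best_label, best_mean = l, mean
    if best_label is None:  # degenerate: everything tiny, take largest region
        sizes = np.bincount(labels.ravel(), minlength=k)
        best_label = int(np.argmax(sizes))
    return (labels == best_label).astype(np.uint8)


def dataset_features(items, config: dict | None = None) -> pd.DataFrame:
    """Feature table (imgio schema) for a list of (image, mask, label) items."""
    cfg = merge_config(config) if not (isinstance(config, dict) and "rng_seed" in config) else config
    records = []
    for idx, (image, mask, label) in enumerate(items):
        roi = roi_for_features(image, mask, cfg)
        fv = features.extract_features(to_uint8(image), roi,
                                       levels=cfg["features"]["levels"])
        records.append({"id": idx, "class_label": label, **fv.as_dict()})
    return pd.DataFrame.from_records(records)


def pipeline_classify(table: pd.DataFrame, config: dict | None = None):
    """Leave-one-out PNN classification of a feature table.

    Returns (predictions DataFrame, report dict).  The report carries
    accuracy, the one-vs-rest confusion metrics for the configured positive
    class, and the ROC curve of its posterior scores.
    """
    cfg = merge_config(config) if not (isinstance(config, dict) and "rng_seed" in config) else config
    feat_cols = list(features.FEATURE_NAMES)
    X = table[feat_cols]
    y = table["class_label"].to_numpy()
    model = pnn.pnn_train(X, y, sigma=cfg["pnn"]["sigma"])
    preds, posteriors = pnn.loo_predictions(model)
    positive = cfg["pnn"]["positive_class"]
    pred_df = table[["id", "class_label"]].copy()
    pred_df["predicted"] = preds
    for cls in model.classes:
        pred_df[f"posterior_{cls}"] = [p[cls] for p in posteriors]
    counts = evaluate.confusion(np.asarray(preds), y, positive)
    report = evaluate.metrics(counts)
    report["accuracy_overall"] = float(np.mean(np.asarray(preds) == y))
    curve = evaluate.roc(pred_df[f"posterior_{positive}"].to_numpy(), y, positive)
    report["auc"] = curve.auc
    return pred_df, report, curve


def default_dataset(n_per_class: int = 20, rng_seed: int = 0,
                    spec: PhantomSpec | None = None):
    """The standard 3 x n_per_class phantom suite (normal, benign, malignant)."""
    return make_dataset(n_per_class, spec_template=spec, rng_seed=rng_seed)


__all__ = [
    "DEFAULT_CONFIG", "UsageError", "merge_config",
    "pipeline_segment", "pipeline_benchmark",
    "roi_for_features", "dataset_features", "pipeline_classify",
    "fcm_ga_seed_candidates", "default_dataset",
    "BENCHMARK_METHODS", "BENCHMARK_COLUMNS", "CLASS_ORDER",
]
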