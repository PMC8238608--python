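"""Gaussian-mixture intensity segmentation with optional HMRF refinement.

Pixel intensities are modeled as a k-component Gaussian mixture

    f(x) = sum_i p_i N(x | mu_i, sigma_i),  sum_i p_i = 1,

fitted by EM from a k-means initialization.  Two E-step variants exist:

* ``full`` (default) — standard EM: responsibilities weighted by the mixture
  weights and the full normal density (with the 1/sigma normalizer); the
  M-step re-estimates means, variances and weights, and the log-likelihood
  is monotonically non-decreasing;
* ``unweighted`` — a simplified variant whose responsibilities use only the
  Gaussian exponent (no mixture weights, no 1/sigma normalizer) and whose
  M-step updates the means only.

Hard segmentation assigns each pixel to its maximum-posterior component.
Optionally, the labeling is refined under a hidden Markov random field with
a Potts spatial prior: iterated conditional modes (ICM) sweeps minimize the
per-pixel energy

    (y - mu_x)^2 / (2 sigma_x^2) + log sigma_x + beta * #{neighbors != x}

alternating with per-label parameter re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

SIGMA_FLOOR = 1e-3  # minimal component STD on the [0, 255] intensity scale


@dataclass
class GMMParams:
    weights: np.ndarray  # p_i, sum to 1
    means: np.ndarray    # mu_i
    stds: np.ndarray     # sigma_i >= SIGMA_FLOOR

    @property
    def k(self) -> int:
        return int(np.asarray(self.means).size)


@dataclass(frozen=True)
class HMRFConfig:
    beta: float = 1.0
    icm_sweeps: int = 5
    em_rounds: int = 3
    neighborhood: int = 4

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")


def kmeans_init(pixels, k: int, rng_seed=None, iters: int = 20):
    """Lloyd's algorithm on intensities from k distinct random initial values.

    Empty clusters are reseeded to the pixel farthest from its assigned
    center.  Returns (labels, means).
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x)
    if k > distinct.size:
        raise ValueError(f"k={k} exceeds {distinct.size} distinct values")
    rng = np.random.default_rng(rng_seed)
    means = np.sort(rng.choice(distinct, size=k, replace=False))
    labels = np.zeros(x.size, dtype=np.int32)
    for _ in range(iters):
        d = np.abs(x[None, :] - means[:, None])
        labels = np.argmin(d, axis=0)
        new_means = means.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new_means[j] = x[sel].mean()
            else:
                far = int(np.argmax(np.abs(x - means[labels])))
                new_means[j] = x[far]
        if np.allclose(new_means, means):
            means = new_means
            break
        means = new_means
    labels = np.argmin(np.abs(x[None, :] - means[:, None]), axis=0)
    return labels, means


def gmm_pdf(x, params: GMMParams):
    """Mixture density f(x) = sum_i p_i N(x | mu_i, sigma_i)."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(params.weights, dtype=float)
    mu = np.asarray(params.means, dtype=float)
    sd = np.asarray(params.stds, dtype=float)
    comp = (
        p[:, None]
        / (sd[:, None] * np.sqrt(2 * np.pi))
        * np.exp(-0.5 * ((x.ravel()[None, :] - mu[:, None]) / sd[:, None]) ** 2)
    )
    return comp.sum(axis=0).reshape(x.shape) if x.shape else float(comp.sum())


def _log_resp(x, params: GMMParams, mode: str):
    mu = np.asarray(params.means, dtype=float)[:, None]
    sd = np.asarray(params.stds, dtype=float)[:, None]
    quad = -0.5 * ((x[None, :] - mu) / sd) ** 2
    if mode == "unweighted":
        logw = quad
    elif mode == "full":
        p = np.asarray(params.weights, dtype=float)[:, None]
        logw = np.log(p) - np.log(sd) - 0.5 * np.log(2 * np.pi) + quad
    else:
        raise ValueError(f"unknown E-step mode {mode!r}")
    return logw  # k x n, unnormalized


def em_e_step(pixels, params: GMMParams, mode: str = "full") -> np.ndarray:
    """Responsibilities (n x k), rows summing to 1; log-sum-exp stabilized."""
    x = np.asarray(pixels, dtype=float).ravel()
    logw = _log_resp(x, params, mode)
    logz = logsumexp(logw, axis=0, keepdims=True)
    return np.exp(logw - logz).T


def em_m_step(pixels, resp, mode: str = "full",
              params: GMMParams | None = None, rng_seed=None) -> GMMParams:
    """M-step: weighted means (both modes); stds and weights in full mode only.

    A component whose total responsibility falls below 1e-12 is reseeded to
    a random pixel with the global STD.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    g = np.asarray(resp, dtype=float)  # n x k
    k = g.shape[1]
    tot = g.sum(axis=0)
    rng = np.random.default_rng(rng_seed)
    means = np.empty(k)
    stds = np.empty(k)
    weights = np.empty(k)
    global_sd = max(float(x.std()), SIGMA_FLOOR)
    for j in range(k):
        if tot[j] < 1e-12:
            means[j] = float(rng.choice(x))
            stds[j] = global_sd
            weights[j] = 1.0 / k
            continue
        means[j] = float((g[:, j] * x).sum() / tot[j])
        if mode == "full":
            var = float((g[:, j] * (x - means[j]) ** 2).sum() / tot[j])
            stds[j] = max(np.sqrt(var), SIGMA_FLOOR)
            weights[j] = tot[j] / x.size
        else:
            stds[j] = params.stds[j] if params is not None else global_sd
            weights[j] = params.weights[j] if params is not None else 1.0 / k
    weights = weights / weights.sum()
    return GMMParams(weights=weights, means=means, stds=stds)


def log_likelihood(pixels, params: GMMParams) -> float:
    x = np.asarray(pixels, dtype=float).ravel()
    logw = _log_resp(x, params, "full")
    return float(logsumexp(logw, axis=0).sum())


def gmm_em_fit(pixels, k: int = 2, iters: int = 100, mode: str = "full",
               rng_seed=None, tol: float = 1e-8):
    """Fit the mixture by EM from a k-means initialization.

    Returns ``(GMMParams, loglik_history)``; in full mode the history is
    non-decreasing (up to float slack).
    """
    x = np.asarray(pixels, dtype=float).ravel()
    labels, means = kmeans_init(x, k, rng_seed=rng_seed)
    stds = np.empty(k)
    weights = np.empty(k)
    for j in range(k):
        sel = labels == j
        stds[j] = max(float(x[sel].std()), SIGMA_FLOOR) if sel.any() else SIGMA_FLOOR
        weights[j] = max(float(sel.mean()), 1e-6)
    weights = weights / weights.sum()
    params = GMMParams(weights=weights, means=means.astype(float), stds=stds)
    history = []
    for _ in range(iters):
        resp = em_e_step(x, params, mode)
        params = em_m_step(x, resp, mode, params=params, rng_seed=rng_seed)
        ll = log_likelihood(x, params)
        if history and abs(ll - history[-1]) < tol:
            history.append(ll)
            break
        history.append(ll)
    return params, history


def gmm_segment(image: np.ndarray, params: GMMParams) -> np.ndarray:
    """Per-pixel argmax of full-mode posteriors (ties -> lower index)."""
    img = np.asarray(image, dtype=float)
    resp = em_e_step(img.ravel(), params, "full")
    return np.argmax(resp, axis=1).astype(np.int32).reshape(img.shape)


def hmrf_energy(image, labels, params: GMMParams,
                config: HMRFConfig | None = None) -> float:
    """Total HMRF energy: data term plus beta * (# unlike neighbor pairs)."""
    config = config or HMRFConfig()
    img = np.asarray(image, dtype=float)
    lab = np.asarray(labels)
    mu = np.asarray(params.means, dtype=float)
    sd = np.maximum(np.asarray(params.stds, dtype=float), SIGMA_FLOOR)
    data = ((img - mu[lab]) ** 2) / (2.0 * sd[lab] ** 2) + np.log(sd[lab])
    pairs = (("h", lab[:, :-1], lab[:, 1:]), ("v", lab[:-1, :], lab[1:, :]))
    if config.neighborhood == 8:
        pairs += (("d1", lab[:-1, :-1], lab[1:, 1:]),
                  ("d2", lab[:-1, 1:], lab[1:, :-1]))
    # unordered unlike pairs counted once: the single-site ICM update is the
    # exact conditional minimizer of this total
    unlike = sum(float((a != b).sum()) for _, a, b in pairs)
    return float(data.sum()) + config.beta * unlike


def hmrf_refine(image: np.ndarray, labels: np.ndarray, params: GMMParams,
                config: HMRFConfig | None = None) -> np.ndarray:
    """ICM refinement under a Potts prior, alternating with parameter updates.

    Each round runs ``icm_sweeps`` raster-order sweeps (each single-site
    update can only decrease the configured energy) then re-estimates the
    per-label mean/STD from the current assignment; a label that loses all
    pixels keeps its previous parameters.
    """
    config = config or HMRFConfig()
    img = np.asarray(image, dtype=float)
    lab = np.asarray(labels, dtype=np.int32).copy()
    h, w = img.shape
    k = params.k
    mu = np.asarray(params.means, dtype=float).copy()
    sd = np.maximum(np.asarray(params.stds, dtype=float).copy(), SIGMA_FLOOR)
    if config.neighborhood == 4:
        offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        offsets = ((-1, 0), (1, 0), (0, -1), (0, 1),
                   (-1, -1), (-1, 1), (1, -1), (1, 1))

    beta = config.beta
    img_list = img.tolist()
    for _ in range(config.em_rounds):
        lab_list = lab.tolist()
        log_sd = np.log(sd)
        inv_two_var = 1.0 / (2.0 * sd**2)
        for _ in range(config.icm_sweeps):
            changed = False
            for r in range(h):
                row = lab_list[r]
                img_row = img_list[r]
                for c in range(w):
                    y = img_row[c]
                    best_l, best_e = row[c], np.inf
                    for l in range(k):
                        e = (y - mu[l]) ** 2 * inv_two_var[l] + log_sd[l]
                        diff = 0
                        for dr, dc in offsets:
                            nr, nc = r + dr, c + dc
                            if 0 <= nr < h and 0 <= nc < w:
                                if lab_list[nr][nc] != l:
                                    diff += 1
                        e += beta * diff
                        if e < best_e - 1e-12:
                            best_e, best_l = e, l
                    if best_l != row[c]:
                        row[c] = best_l
                        changed = True
            if not changed:
                break
        lab = np.asarray(lab_list, dtype=np.int32)
        for l in range(k):
            sel = lab == l
            if sel.any():
                mu[l] = float(img[sel].mean())
                sd[l] = max(float(img[sel].std()), SIGMA_FLOOR)
    return lab


__all__ = [
    "GMMParams", "HMRFConfig", "SIGMA_FLOOR",
    "kmeans_init", "gmm_pdf", "em_e_step", "em_m_step",
    "log_likelihood", "gmm_em_fit", "gmm_segment", "hmrf_refine",
    "hmrf_energy",
]
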