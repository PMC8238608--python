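"""Automatic region-growing seed selection via FCM clustering tuned by a GA.

Fuzzy c-means (FCM) partitions the intensity histogram into K soft clusters
by minimizing the fuzzified within-cluster squared distance

    J_q = sum_i sum_j u_ij^q (x_j - c_i)^2,   sum_i u_ij = 1,

where q > 1 is the fuzzifier.  A real-coded genetic algorithm searches over
cluster-center vectors (the memberships are implied by the centers, which
halves the search space), using either J_q itself or a tri-level
segmentation-disagreement cost as fitness.  The tumor seed is the pixel with
maximal membership in the cluster whose center intensity is highest — masses
are hyperintense relative to surrounding tissue.

All clustering entry points accept an optional ``weights`` vector so images
can be clustered through their 256-bin intensity histogram at no loss of
exactness (intensity-only FCM depends on the data only through value counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateClusterError(RuntimeError):
    """A cluster received (numerically) zero total membership weight."""


@dataclass
class FCMState:
    """Converged fuzzy c-means state."""

    memberships: np.ndarray  # K x n
    centers: np.ndarray      # K
    fuzzifier: float
    objective: float
    n: int
    K: int
    history: list = field(default_factory=list)  # per-iteration objective


@dataclass
class Chromosome:
    """GA individual: K real cluster centers in [0, 255] plus its fitness."""

    genes: np.ndarray
    fitness: float = np.inf


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    mutation_rate: float = 0.2
    crossover_rate: float = 0.8
    generations: int = 50
    elitism_count: int = 1
    tournament_size: int = 2
    mutation_sigma: float = 10.0
    fitness_kind: str = "fcm_objective"  # or "segmentation_cost"
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.elitism_count < self.population_size):
            raise ValueError("elitism_count must be < population_size")
        if self.fitness_kind not in ("fcm_objective", "segmentation_cost"):
            raise ValueError(f"unknown fitness_kind {self.fitness_kind!r}")


@dataclass(frozen=True)
class SeedPoint:
    row: int
    col: int
    cluster_id: int = 0


def fcm_memberships(pixels, centers, q: float = 2.0) -> np.ndarray:
    """Membership update: u_ij = 1 / sum_k (d_ij/d_kj)^(2/(q-1)).

    ``d`` is the absolute intensity difference.  Pixels at zero distance from
    one or more centers split membership 1 equally among those centers.
    Columns sum to 1.
    """
    if q <= 1:
        raise ValueError("fuzzifier q must be > 1")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    x = np.asarray(pixels, dtype=float).ravel()
    d = np.abs(x[None, :] - centers[:, None])  # K x n
    zero = d == 0.0
    u = np.empty_like(d)
    col_zero = zero.any(axis=0)
    safe = ~col_zero
    if safe.any():
        # scale by the per-column minimum distance so the ratios stay in
        # (0, 1] and the power never overflows for nearly-coincident centers
        ds = d[:, safe]
        ratio = (ds.min(axis=0, keepdims=True) / ds) ** (2.0 / (q - 1.0))
        u[:, safe] = ratio / ratio.sum(axis=0, keepdims=True)
    if col_zero.any():
        zc = zero[:, col_zero]
        u[:, col_zero] = zc / zc.sum(axis=0, keepdims=True)
    return u


def fcm_update_centers(pixels, memberships, q: float = 2.0,
                       weights=None) -> np.ndarray:
    """Center update: c_i = sum_j w_j u_ij^q x_j / sum_j w_j u_ij^q."""
    x = np.asarray(pixels, dtype=float).ravel()
    u = np.asarray(memberships, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    uw = (u**q) * w[None, :]
    denom = uw.sum(axis=1)
    if np.any(denom <= 0):
        raise DegenerateClusterError(
            f"cluster(s) {np.flatnonzero(denom <= 0).tolist()} have zero weight"
        )
    return uw @ x / denom


def fcm_objective(pixels, memberships, centers, q: float = 2.0,
                  weights=None) -> float:
    """J_q = sum_ij w_j u_ij^q (x_j - c_i)^2 (squared Euclidean distance)."""
    x = np.asarray(pixels, dtype=float).ravel()
    u = np.asarray(memberships, dtype=float)
    c = np.asarray(centers, dtype=float).ravel()
    if u.shape != (c.size, x.size):
        raise ValueError("memberships shape does not match pixels/centers")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    d2 = (x[None, :] - c[:, None]) ** 2
    return float(((u**q) * d2 * w[None, :]).sum())


def fcm_fit(pixels, K: int, q: float = 2.0, max_iter: int = 100,
            tol: float = 1e-5, rng_seed=None, weights=None) -> FCMState:
    """Alternate membership/center updates from random distinct initial centers.

    The objective sequence is non-increasing (up to float slack); iteration
    stops when |ΔJ| < tol or after ``max_iter`` rounds.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x = np.asarray(pixels, dtype=float).ravel()
    rng = np.random.default_rng(rng_seed)
    distinct = np.unique(x)
    if K <= distinct.size:
        centers = rng.choice(distinct, size=K, replace=False)
    else:
        centers = rng.choice(x, size=K, replace=True)
    prev_obj = np.inf
    history = []
    u = fcm_memberships(x, centers, q)
    for _ in range(max_iter):
        try:
            centers = fcm_update_centers(x, u, q, weights=weights)
        except DegenerateClusterError:
            # reinitialize dead centers to random pixels and continue
            uw = (u**q).sum(axis=1)
            dead = uw <= 0
            centers = centers.copy()
            centers[dead] = rng.choice(x, size=int(dead.sum()))
        u = fcm_memberships(x, centers, q)
        obj = fcm_objective(x, u, centers, q, weights=weights)
        history.append(obj)
        if abs(prev_obj - obj) < tol:
            prev_obj = obj
            break
        prev_obj = obj
    return FCMState(
        memberships=u, centers=np.asarray(centers, dtype=float),
        fuzzifier=q, objective=float(prev_obj), n=x.size, K=K,
        history=history,
    )


def segmentation_cost(candidate_layers, reference_layers) -> float:
    """Tri-level disagreement cost: sum over layers of squared indicator gaps.

    Both arguments are sequences of three same-shape {0,1} masks, ordered
    (gray, white, black).  The cost equals the total per-layer disagreement
    pixel count and is 0 iff the layer stacks are identical.
    """
    if len(candidate_layers) != 3 or len(reference_layers) != 3:
        raise ValueError("expected exactly three layers on each side")
    cost = 0.0
    shape = np.asarray(reference_layers[0]).shape
    for cand, ref in zip(candidate_layers, reference_layers):
        cand = np.asarray(cand, dtype=float)
        ref = np.asarray(ref, dtype=float)
        if cand.shape != shape or ref.shape != shape:
            raise ValueError("layer shape mismatch")
        cost += float(((ref - cand) ** 2).sum())
    return cost


def label_layers(labels: np.ndarray, k: int = 3):
    """Per-label indicator masks of a LabelImage, label 0 first."""
    labels = np.asarray(labels)
    return [(labels == i).astype(np.uint8) for i in range(k)]


def trilevel_reference(image: np.ndarray):
    """Quantize an image into (gray, white, black) indicator layers.

    Thresholds sit at the terciles of the intensity range; "black" is the
    lowest band, "gray" the middle, "white" the highest.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    t1 = lo + (hi - lo) / 3.0
    t2 = lo + 2.0 * (hi - lo) / 3.0
    black = img <= t1
    white = img > t2
    gray = ~black & ~white
    return [gray.astype(np.uint8), white.astype(np.uint8), black.astype(np.uint8)]


def _fcm_fitness(genes, pixels, q, weights):
    u = fcm_memberships(pixels, genes, q)
    return fcm_objective(pixels, u, genes, q, weights=weights)


def make_segmentation_cost_fitness(image: np.ndarray, grow_config=None):
    """Fitness that grows regions from a chromosome's implied seeds and scores
    the resulting tri-level partition against a tri-level reference of the
    image (disagreement cost).  Intended for K=3 chromosomes; expensive —
    use small GA budgets."""
    from .region_grow import GrowConfig, grow_all

    reference = trilevel_reference(image)
    grow_config = grow_config or GrowConfig(criterion="threshold", X=20.0)

    def fitness(genes):
        seeds = [seed_for_cluster(image, np.asarray(genes, dtype=float), i)
                 for i in range(len(genes))]
        labels, k = grow_all(image, seeds=seeds, config=grow_config)
        # map grown labels to (gray, white, black) by mean intensity rank
        means = np.array([
            image[labels == i].mean() if (labels == i).any() else -np.inf
            for i in range(k)
        ])
        order = np.argsort(means)  # ascending: black ... white
        black = np.isin(labels, order[: max(1, k // 3)])
        white = np.isin(labels, order[-max(1, k // 3):])
        gray = ~black & ~white
        layers = [gray.astype(np.uint8), white.astype(np.uint8),
                  black.astype(np.uint8)]
        return segmentation_cost(layers, reference)

    return fitness


def ga_optimize(pixels, K: int, config: GAConfig | None = None, weights=None,
                fitness_fn=None):
    """Real-coded GA over center vectors.

    Tournament selection, arithmetic (blend) crossover, per-gene Gaussian
    mutation, elitism.  Returns the best chromosome ever evaluated and the
    per-generation best-so-far fitness history (non-increasing).
    """
    config = config or GAConfig()
    x = np.asarray(pixels, dtype=float).ravel()
    rng = np.random.default_rng(config.rng_seed)
    if fitness_fn is None:
        if config.fitness_kind != "fcm_objective":
            raise ValueError(
                "segmentation_cost fitness requires an explicit fitness_fn "
                "(see make_segmentation_cost_fitness)"
            )
        fitness_fn = lambda genes: _fcm_fitness(genes, x, 2.0, weights)

    lo = float(x.min()) if x.size else 0.0
    hi = float(x.max()) if x.size else 255.0
    pop = [
        Chromosome(genes=rng.uniform(lo, hi, size=K))
        for _ in range(config.population_size)
    ]
    for ind in pop:
        ind.fitness = float(fitness_fn(ind.genes))
    best = min(pop, key=lambda c: c.fitness)
    best = Chromosome(best.genes.copy(), best.fitness)
    history = []

    def tournament():
        idx = rng.integers(0, len(pop), size=config.tournament_size)
        return min((pop[i] for i in idx), key=lambda c: c.fitness)

    for _ in range(config.generations):
        ranked = sorted(pop, key=lambda c: c.fitness)
        nxt = [Chromosome(e.genes.copy(), e.fitness)
               for e in ranked[: config.elitism_count]]
        while len(nxt) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                lam = rng.random(K)
                g1 = lam * p1.genes + (1 - lam) * p2.genes
                g2 = lam * p2.genes + (1 - lam) * p1.genes
            else:
                g1, g2 = p1.genes.copy(), p2.genes.copy()
            for g in (g1, g2):
                if len(nxt) >= config.population_size:
                    break
                mut = rng.random(K) < config.mutation_rate
                g = g + mut * rng.normal(0.0, config.mutation_sigma, size=K)
                g = np.clip(g, 0.0, 255.0)
                child = Chromosome(genes=g, fitness=float(fitness_fn(g)))
                nxt.append(child)
        pop = nxt
        gen_best = min(pop, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = Chromosome(gen_best.genes.copy(), gen_best.fitness)
        history.append(best.fitness)
    return best, history


def _image_membership_for_cluster(image, centers, cluster_id, q=2.0):
    u = fcm_memberships(np.asarray(image, dtype=float).ravel(), centers, q)
    return u[cluster_id].reshape(np.asarray(image).shape)


def seed_for_cluster(image, centers, cluster_id, q: float = 2.0) -> SeedPoint:
    """Pixel with maximal membership in one cluster.

    Membership ties are broken by smaller intensity distance to the cluster
    center (so a K=1 chromosome seeds at the pixel nearest the mean), then
    by raster order (smallest (row, col) lexicographically).
    """
    image = np.asarray(image)
    m = _image_membership_for_cluster(image, centers, cluster_id, q)
    tied = np.flatnonzero(m.ravel() == m.max())
    dist = np.abs(image.ravel()[tied].astype(float)
                  - float(np.asarray(centers, dtype=float)[cluster_id]))
    flat = int(tied[np.flatnonzero(dist == dist.min())[0]])
    r, c = divmod(flat, m.shape[1])
    return SeedPoint(row=r, col=c, cluster_id=int(cluster_id))


def select_seed(image, best: Chromosome, q: float = 2.0,
                multi: bool = False):
    """Tumor seed: max-membership pixel of the highest-intensity cluster.

    Memberships are recomputed from ``best.genes``.  With ``multi=True`` a
    list with one seed per cluster is returned instead.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    centers = np.asarray(best.genes, dtype=float)
    if multi:
        return [seed_for_cluster(image, centers, i, q)
                for i in range(centers.size)]
    target = int(np.argmax(centers))
    return seed_for_cluster(image, centers, target, q)


def image_histogram_weights(image: np.ndarray):
    """(values, counts) of a uint8 image — the exact sufficient statistic for
    intensity-only FCM/GA."""
    values, counts = np.unique(np.asarray(image).ravel(), return_counts=True)
    return values.astype(float), counts.astype(float)


def fcm_ga_seed(image: np.ndarray, K: int = 10,
                config: GAConfig | None = None, q: float = 2.0,
                multi: bool = False):
    """End-to-end automatic seed selection on an image.

    Runs the GA over FCM centers on the image's intensity histogram and
    returns the selected seed(s) plus the best chromosome.
    """
    values, counts = image_histogram_weights(image)
    best, _history = ga_optimize(values, K, config=config, weights=counts)
    return select_seed(image, best, q=q, multi=multi), best


__all__ = [
    "FCMState", "Chromosome", "GAConfig", "SeedPoint",
    "DegenerateClusterError",
    "fcm_memberships", "fcm_update_centers", "fcm_objective", "fcm_fit",
    "segmentation_cost", "label_layers", "trilevel_reference",
    "make_segmentation_cost_fitness",
    "ga_optimize", "select_seed", "seed_for_cluster",
    "image_histogram_weights", "fcm_ga_seed",
]
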