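"""Descriptor selection: objective filtering, then GA-MLR subset search.

Objective feature selection (OFS) is activity-blind: constant columns,
near-constant columns (one value covering more than 95% of rows) and
the later member of any pair with |Pearson r| above the threshold
(default 0.90) are dropped, in a fixed deterministic scan order.

Subjective selection is a genetic algorithm over fixed-size descriptor
index sets, scored by Q²_LOO of the ordinary-least-squares fit —
tournament selection (size 2), one-point crossover on sorted index
lists with duplicate repair, point mutation, and elitism.  The model
size is chosen afterwards at the breaking point of the Q²_LOO-vs-k
curve: the smallest k whose marginal gain falls below epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AllFilteredError, UndefinedStatisticError
from .validation import fit_ols, q2_loo

# ---------------------------------------------------------------------------
# objective feature selection


@dataclass
class OFSResult:
    kept: list  # surviving column names, input order
    removal_log: list  # dicts: column, reason, partner (for correlated)


def objective_feature_selection(
    X: np.ndarray,
    names: list,
    near_constant_fraction: float = 0.95,
    corr_threshold: float = 0.90,
):
    """Drop constant, near-constant, then inter-correlated columns.

    Correlation pruning is greedy over column pairs in input order: for
    i < j, if both still alive and |r(i, j)| > threshold, column j is
    dropped and i recorded as its partner.  Returns the reduced matrix,
    surviving names, and an :class:`OFSResult` whose removal log covers
    every dropped column exactly once.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = list(names)
    alive = np.ones(p, dtype=bool)
    log = []

    for j in range(p):
        col = X[:, j]
        uniq, counts = np.unique(col, return_counts=True)
        if len(uniq) == 1:
            alive[j] = False
            log.append({"column": names[j], "reason": "constant", "partner": None})
        elif counts.max() / n > near_constant_fraction:
            alive[j] = False
            log.append(
                {"column": names[j], "reason": "near_constant", "partner": None}
            )

    live_idx = np.flatnonzero(alive)
    if len(live_idx) >= 2:
        sd = X[:, live_idx].std(axis=0)
        Z = (X[:, live_idx] - X[:, live_idx].mean(axis=0)) / sd
        R = np.abs(Z.T @ Z) / n
        live_alive = np.ones(len(live_idx), dtype=bool)
        for a in range(len(live_idx)):
            if not live_alive[a]:
                continue
            for b in range(a + 1, len(live_idx)):
                if live_alive[b] and R[a, b] > corr_threshold:
                    live_alive[b] = False
                    log.append(
                        {
                            "column": names[live_idx[b]],
                            "reason": "correlated",
                            "partner": names[live_idx[a]],
                        }
                    )
        alive[live_idx[~live_alive]] = False

    if not alive.any():
        raise AllFilteredError("objective feature selection removed every column")
    kept = [names[j] for j in np.flatnonzero(alive)]
    return X[:, alive], kept, OFSResult(kept=kept, removal_log=log)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    """GA hyperparameters; fitness is always Q²_LOO of the OLS fit."""

    subset_size: int = 5
    population_size: int = 50
    n_generations: int = 150
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    elitism: int = 2
    seed: int = 0
    local_refine: bool = True  # greedy 1-swap polish of the GA's best subset

    def __post_init__(self):
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("GA rates must lie in [0, 1]")
        if self.subset_size < 1:
            raise ValueError("subset size must be >= 1")
        if self.population_size < 1:
            raise ValueError("population must be >= 1")


@dataclass
class SelectionResult:
    subset: list  # descriptor column indices, sorted
    fitness: float
    history: list = field(default_factory=list)  # per-generation (best, mean)
    config: GAConfig | None = None


def _fitness(X, y, subset) -> float:
    """Q²_LOO of the candidate subset via a QR-based deletion identity.

    Numerically identical to ``validation.q2_loo`` but without the model
    object overhead — this is the GA's inner loop.  Rank-deficient or
    degenerate candidates score −inf.
    """
    sub = X[:, subset]
    n = len(y)
    D = np.column_stack([np.ones(n), sub])
    Q, R = np.linalg.qr(D)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        return -np.inf
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - D @ beta
    h = (Q**2).sum(axis=1)
    if np.any(h >= 1.0 - 1e-12):
        return -np.inf
    press = float(((resid / (1.0 - h)) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 1e-300:
        return -np.inf
    return 1.0 - press / tss


def _local_refine(X, y, subset: list) -> list:
    """Greedy 1-swap hill climb to a locally optimal subset.

    Deterministic: scans positions and replacement columns in index
    order and takes the best improving swap until none remains.
    """
    p = X.shape[1]
    current = list(subset)
    best_fit = _fitness(X, y, current)
    improved = True
    while improved:
        improved = False
        members = set(current)
        best_swap = None
        for pos in range(len(current)):
            for repl in range(p):
                if repl in members:
                    continue
                trial = current.copy()
                trial[pos] = repl
                f = _fitness(X, y, trial)
                if f > best_fit + 1e-12:
                    best_fit = f
                    best_swap = (pos, repl)
        if best_swap is not None:
            current[best_swap[0]] = best_swap[1]
            improved = True
    return sorted(current)


def ga_select(Xtr, ytr, cfg: GAConfig) -> SelectionResult:
    """GA search for the best fixed-size descriptor subset.

    Reproducible under ``cfg.seed``; the returned fitness equals
    ``q2_loo`` recomputed on the returned subset.  Elite fitness is
    monotone non-decreasing across generations.
    """
    X = np.asarray(Xtr, dtype=float)
    y = np.asarray(ytr, dtype=float)
    n, p = X.shape
    k = cfg.subset_size
    if n <= k + 2:
        raise UndefinedStatisticError(
            f"need n_train > k + 2 (n={n}, k={k})"
        )
    if p < k:
        raise UndefinedStatisticError(f"pool of {p} columns cannot yield k={k}")
    rng = np.random.default_rng(cfg.seed)

    pop = [
        np.sort(rng.choice(p, size=k, replace=False))
        for _ in range(cfg.population_size)
    ]
    fits = np.array([_fitness(X, y, ind) for ind in pop])
    history = []

    def tournament():
        i, j = rng.integers(cfg.population_size, size=2)
        return pop[i] if fits[i] >= fits[j] else pop[j]

    for _ in range(cfg.n_generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            a, b = tournament(), tournament()
            if k > 1 and rng.random() < cfg.crossover_rate:
                cut = int(rng.integers(1, k))
                child = np.concatenate([a[:cut], b[cut:]])
                # repair duplicated indices by random resample
                child = np.unique(child)
                while len(child) < k:
                    extra = rng.integers(p)
                    if extra not in child:
                        child = np.append(child, extra)
            else:
                child = a.copy()
            if p > k and rng.random() < cfg.mutation_rate:
                pos = int(rng.integers(k))
                repl = int(rng.integers(p))
                while repl in child:
                    repl = int(rng.integers(p))
                child[pos] = repl
            new_pop.append(np.sort(child))
        pop = new_pop
        fits = np.array([_fitness(X, y, ind) for ind in pop])
        history.append((float(fits.max()), float(np.mean(fits[np.isfinite(fits)]))))

    best = int(np.argmax(fits))
    subset = sorted(int(i) for i in pop[best])
    if cfg.local_refine:
        subset = _local_refine(X, y, subset)
    # report the fitness through the validation-module path so the
    # returned number is exactly what q2_loo gives for this subset
    fitness = q2_loo(X[:, subset], y)["q2_loo"]
    return SelectionResult(
        subset=subset,
        fitness=float(fitness),
        history=history,
        config=cfg,
    )


def exhaustive_select(Xtr, ytr, k: int) -> SelectionResult:
    """Enumerate every size-k subset — the oracle for small pools."""
    from itertools import combinations

    X = np.asarray(Xtr, dtype=float)
    y = np.asarray(ytr, dtype=float)
    best, best_fit = None, -np.inf
    for subset in combinations(range(X.shape[1]), k):
        f = _fitness(X, y, list(subset))
        if f > best_fit:
            best, best_fit = list(subset), f
    return SelectionResult(subset=best, fitness=float(best_fit))


# ---------------------------------------------------------------------------
# model-size choice


def breaking_point(q2_by_k: dict, epsilon: float = 0.02):
    """Choose the model size at the knee of the Q²_LOO-vs-k curve.

    ``q2_by_k`` maps k (1..k_max, contiguous) to the best Q²_LOO found
    at that size.  The chosen k is the smallest for which the marginal
    gain Q²(k+1) − Q²(k) drops below epsilon; if gains never plateau the
    largest k is returned with ``warning=True``.
    """
    ks = sorted(q2_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("breaking_point needs contiguous k values")
    for k in ks[:-1]:
        if q2_by_k[k + 1] - q2_by_k[k] < epsilon:
            return k, False
    return ks[-1], True


def select_model_size(
    Xtr,
    ytr,
    k_max: int = 8,
    epsilon: float = 0.02,
    cfg: GAConfig | None = None,
):
    """Run the GA at every k = 1..k_max and apply the breaking-point rule.

    Returns (chosen_k, warning, per-k SelectionResult dict, plot table of
    k vs R² and Q²_LOO).
    """
    base = cfg or GAConfig()
    results = {}
    curve = []
    for k in range(1, k_max + 1):
        cfg_k = GAConfig(
            subset_size=k,
            population_size=base.population_size,
            n_generations=base.n_generations,
            crossover_rate=base.crossover_rate,
            mutation_rate=base.mutation_rate,
            elitism=base.elitism,
            seed=base.seed + k,
        )
        res = ga_select(Xtr, ytr, cfg_k)
        results[k] = res
        r2_k = fit_ols(np.asarray(Xtr)[:, res.subset], ytr).r2
        curve.append({"k": k, "r2": r2_k, "q2_loo": res.fitness})
    chosen, warning = breaking_point(
        {k: results[k].fitness for k in results}, epsilon=epsilon
    )
    return chosen, warning, results, curve
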