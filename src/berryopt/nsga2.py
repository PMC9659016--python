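"""Elitist nondominated-sorting genetic algorithm (NSGA-II).

Real-coded NSGA-II over a box-bounded decision space with the classic
operator set: fast nondominated sorting, crowding-distance diversity,
binary tournament selection, intermediate crossover and uniform
within-bounds mutation.  Maximised objectives are handled by negation
internally; reported objective values are always on the caller's scale.

The default configuration mirrors the published optimization set-up for
the three-variable blanching/drying problem: population 30 x n_vars,
generation cap 500 x n_vars, 90% intermediate crossover, 10% uniform
mutation, tournament size 2, Pareto fraction 0.30.  A stall criterion on
the front's ideal/mean objective statistics stops runs that have
converged long before the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "OptimizationProblem",
    "NSGA2Config",
    "ParetoFrontRaw",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "tournament_select",
    "intermediate_crossover",
    "uniform_mutation",
    "run",
    "surrogate_problem",
]


@dataclass(frozen=True)
class OptimizationProblem:
    """A box-bounded multiobjective problem.

    objective : callable mapping a decision matrix (N, n_vars) to an
        objective matrix (N, n_obj).
    senses : per-objective "min" or "max".
    bounds : (n_vars, 2) array of [lo, hi].
    names : optional decision/objective names for reporting.
    """

    objective: callable
    senses: tuple
    bounds: np.ndarray
    var_names: tuple = ()
    obj_names: tuple = ()

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.shape[1] != 2 or np.any(~np.isfinite(b)) or np.any(b[:, 0] >= b[:, 1]):
            raise InvalidInputError("bounds must be finite (n_vars, 2) with lo < hi")
        if not all(s in ("min", "max") for s in self.senses):
            raise InvalidInputError("senses must be 'min' or 'max'")
        object.__setattr__(self, "bounds", b)

    @property
    def n_vars(self) -> int:
        return self.bounds.shape[0]

    @property
    def n_obj(self) -> int:
        return len(self.senses)

    def sign(self) -> np.ndarray:
        """+1 for minimised, -1 for maximised objectives."""
        return np.array([1.0 if s == "min" else -1.0 for s in self.senses])

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        F = np.asarray(self.objective(np.atleast_2d(X)), dtype=float)
        if not np.all(np.isfinite(F)):
            bad = np.atleast_2d(X)[~np.all(np.isfinite(F), axis=1)][0]
            raise InvalidInputError(
                f"objective returned non-finite values at decision vector {tuple(bad)}"
            )
        return F


@dataclass(frozen=True)
class NSGA2Config:
    """Algorithm parameters; defaults follow the published Table of settings."""

    population_per_var: int = 30
    generations_per_var: int = 500
    crossover_rate: float = 0.90
    crossover_ratio: float = 1.0
    mutation_rate: float = 0.10
    tournament_size: int = 2
    pareto_fraction: float = 0.30
    front_size: int | None = None  # override of round(fraction * popsize)
    stall_generations: int = 50
    stall_tol: float = 1e-6
    archive_max: int = 2000
    boundary_init_rate: float = 1.0 / 6.0
    polish_radii: tuple = (0.1, 0.05, 0.02, 0.01, 0.005, 0.002)
    polish_samples: int = 48
    polish_global_samples: int = 8192
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "pareto_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")

    def population_size(self, n_vars: int) -> int:
        pop = self.population_per_var * n_vars
        if pop < 4 or pop % 2:
            raise InvalidInputError("population must be even and >= 4")
        return pop


def dominates(a, b, senses=None) -> bool:
    """True iff ``a`` Pareto-dominates ``b``.

    ``a`` must be no worse than ``b`` in every objective (according to each
    objective's sense, all-"min" by default) and strictly better in at
    least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"length mismatch: {a.shape} vs {b.shape}")
    if senses is not None:
        sign = np.array([1.0 if s == "min" else -1.0 for s in senses])
        a, b = a * sign, b * sign
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(F: np.ndarray) -> list:
    """Partition points into ranked Pareto fronts (all objectives minimised).

    Returns a list of integer index arrays; front 0 is the maximal
    nondominated set, and every member of front r is dominated only by
    members of earlier fronts.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or len(F) == 0:
        raise InvalidInputError("need a nonempty (N, M) objective matrix")
    n = len(F)
    # pairwise dominance matrix: D[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    D = le & lt
    n_dominators = D.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dominators == 0))
        if current.size == 0:  # cannot happen with a valid dominance relation
            raise RuntimeError("cyclic dominance relation")
        fronts.append(current)
        remaining[current] = False
        n_dominators = n_dominators - D[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each point of a single front (minimised space).

    Boundary points per objective get infinite distance; interior points
    accumulate the normalized gap between their sorted neighbours.  An
    objective with zero range contributes nothing.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def tournament_select(rank: np.ndarray, crowd: np.ndarray, rng, size: int = 2) -> int:
    """Index of the winner of a size-``size`` tournament.

    Lower rank wins; rank ties go to the larger crowding distance;
    remaining ties are broken uniformly at random.
    """
    cand = rng.integers(0, len(rank), size=size)
    best = cand[0]
    for c in cand[1:]:
        if rank[c] < rank[best] or (
            rank[c] == rank[best] and crowd[c] > crowd[best]
        ):
            best = c
        elif rank[c] == rank[best] and crowd[c] == crowd[best] and rng.random() < 0.5:
            best = c
    return int(best)


def intermediate_crossover(p1, p2, rng, bounds, ratio: float = 1.0,
                           rate: float = 0.90):
    """Intermediate (arithmetic) crossover of two parents.

    With probability ``rate`` each child gene g is
    ``parent_g + u * ratio * (other_g - parent_g)`` with independent
    ``u ~ U(0, 1)`` per gene; otherwise the children are copies of the
    parents.  Children are clipped to the bounds.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if rng.random() < rate:
        u1 = rng.random(p1.size)
        u2 = rng.random(p1.size)
        c1 = p1 + u1 * ratio * (p2 - p1)
        c2 = p2 + u2 * ratio * (p1 - p2)
    else:
        c1, c2 = p1.copy(), p2.copy()
    b = np.asarray(bounds, dtype=float)
    return np.clip(c1, b[:, 0], b[:, 1]), np.clip(c2, b[:, 0], b[:, 1])


def uniform_mutation(x, rng, bounds, rate: float = 0.10):
    """Replace each gene independently with prob ``rate`` by a uniform draw."""
    x = np.asarray(x, dtype=float).copy()
    b = np.asarray(bounds, dtype=float)
    hit = rng.random(x.size) < rate
    if hit.any():
        x[hit] = rng.uniform(b[hit, 0], b[hit, 1])
    return x


@dataclass(frozen=True)
class ParetoFrontRaw:
    """Result of a run: decision matrix, objective matrix (caller's scale),
    per-generation history and the generation at which the run stopped."""

    X: np.ndarray
    F: np.ndarray
    generations: int
    history: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self, var_names, obj_names) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(var_names))
        for j, name in enumerate(obj_names):
            df[name] = self.F[:, j]
        df.insert(0, "pareto_id", np.arange(1, len(df) + 1))
        return df


def _polish(problem, X, F, rng, config):
    """Local dominance polish of selected front points (minimised space).

    At each of a sequence of shrinking radii (fractions of the decision
    ranges), every point is offered axis-aligned steps, projections onto
    the nearest bound, and random perturbations; a move is accepted only
    if it Pareto-dominates the current point, so a polished point is never
    worse in any objective.  This repairs the locally suboptimal points
    that crowding-based selection tends to pick from sparse regions of the
    search history.
    """
    b = problem.bounds
    span = b[:, 1] - b[:, 0]
    n_vars = problem.n_vars
    X = X.copy()
    F = F.copy()
    for _pass in range(2):
        # global repair: a point dominated by a distant region is replaced
        # by the dominating sample point before local refinement begins
        if config.polish_global_samples:
            S = rng.uniform(b[:, 0], b[:, 1],
                            (config.polish_global_samples, n_vars))
            on_bound = rng.random(S.shape) < 1.0 / (2 * n_vars)
            which = rng.integers(0, 2, size=S.shape)
            edges = np.where(which == 0, b[:, 0][None, :], b[:, 1][None, :])
            S[on_bound] = np.broadcast_to(edges, S.shape)[on_bound]
            FS = problem.evaluate(S) * problem.sign()
            for i in range(len(X)):
                le = np.all(FS <= F[i], axis=1)
                lt = np.any(FS < F[i], axis=1)
                dom = np.flatnonzero(le & lt)
                if dom.size:
                    gain = np.sum(F[i] - FS[dom], axis=1)
                    j = dom[np.argmax(gain)]
                    X[i], F[i] = S[j], FS[j]
        X, F = _polish_local(problem, X, F, rng, config)
    return X, F


def _polish_local(problem, X, F, rng, config):
    b = problem.bounds
    span = b[:, 1] - b[:, 0]
    n_vars = problem.n_vars
    for radius in config.polish_radii:
        improved = True
        sweeps = 0
        while improved and sweeps < 5:
            improved = False
            sweeps += 1
            for i in range(len(X)):
                steps = []
                for d in range(n_vars):
                    for s in (-1.0, 1.0):
                        e = np.zeros(n_vars)
                        e[d] = s * radius * span[d]
                        steps.append(X[i] + e)
                    # exact bound projections: boundary optima are common,
                    # and a projection may need a lateral adjustment too
                    for edge in (b[d, 0], b[d, 1]):
                        c = X[i].copy()
                        c[d] = edge
                        steps.append(c)
                        lateral = c + rng.normal(size=(4, n_vars)) * radius * span
                        lateral[:, d] = edge
                        steps.extend(lateral)
                k = config.polish_samples
                half = k // 2
                # isotropic draws at the current radius plus anisotropic
                # draws with an independent ladder radius per coordinate:
                # dominating regions are often thin in one axis only
                r_aniso = np.asarray(config.polish_radii)[
                    rng.integers(0, len(config.polish_radii), size=(k - half, n_vars))
                ]
                noise = np.vstack([
                    X[i] + rng.normal(size=(half, n_vars)) * radius * span,
                    X[i] + rng.normal(size=(k - half, n_vars)) * r_aniso * span,
                ])
                # for points sitting on a bound, search within the face with
                # extra draws: dominating regions there are 2-D patches that
                # full-dimensional sampling hits too rarely
                pinned = (X[i] <= b[:, 0] + 1e-12) | (X[i] >= b[:, 1] - 1e-12)
                if pinned.any() and not pinned.all():
                    r_face = np.asarray(config.polish_radii)[
                        rng.integers(0, len(config.polish_radii), size=(3 * k, n_vars))
                    ]
                    face = X[i] + rng.normal(size=(3 * k, n_vars)) * r_face * span
                    face[:, pinned] = X[i][pinned]
                    noise = np.vstack([noise, face])
                cand = np.clip(np.vstack([steps, noise]), b[:, 0], b[:, 1])
                FC = problem.evaluate(cand) * problem.sign()
                le = np.all(FC <= F[i], axis=1)
                lt = np.any(FC < F[i], axis=1)
                dom = np.flatnonzero(le & lt)
                if dom.size:
                    # steepest improvement among dominating candidates
                    gain = np.sum(F[i] - FC[dom], axis=1)
                    j = dom[np.argmax(gain)]
                    X[i], F[i] = cand[j], FC[j]
                    improved = True
    return X, F


def _nondominated_mask(F: np.ndarray) -> np.ndarray:
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    return ~np.any(le & lt, axis=0)


def run(problem: OptimizationProblem, config: NSGA2Config | None = None,
        seed: int | None = None) -> ParetoFrontRaw:
    """Standard elitist NSGA-II loop with an external nondominated archive.

    Parents and offspring are pooled each generation, sorted into fronts
    and truncated by crowding distance.  Alongside the population an
    archive of every nondominated point found so far is maintained (pruned
    by dominance, capped at ``archive_max`` by crowding), so the
    best-known front never degrades.  The returned front is the archive's
    nondominated set truncated (by crowding) to ``front_size`` or
    ``round(pareto_fraction * popsize)``.  Runs are deterministic under a
    fixed seed; a stall check on the front's per-objective ideal and mean
    values stops converged runs early.
    """
    config = config or NSGA2Config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_vars = problem.n_vars
    pop_size = config.population_size(n_vars)
    max_gen = config.generations_per_var * n_vars
    sign = problem.sign()
    b = problem.bounds

    X = rng.uniform(b[:, 0], b[:, 1], size=(pop_size, n_vars))
    # place a fraction of initial genes exactly on a bound: intermediate
    # crossover is contractive, so boundary optima are reachable only if
    # bound values already exist in the gene pool
    on_bound = rng.random(X.shape) < config.boundary_init_rate
    which = rng.integers(0, 2, size=X.shape)
    X[on_bound] = b[:, 0][None, :].repeat(pop_size, 0)[on_bound] * (1 - which[on_bound]) \
        + b[:, 1][None, :].repeat(pop_size, 0)[on_bound] * which[on_bound]
    F = problem.evaluate(X) * sign

    def rank_crowd(Fm):
        fronts = fast_nondominated_sort(Fm)
        rank = np.empty(len(Fm), dtype=int)
        crowd = np.empty(len(Fm))
        for r, front in enumerate(fronts, start=1):
            rank[front] = r
            crowd[front] = crowding_distance(Fm[front])
        return fronts, rank, crowd

    fronts, rank, crowd = rank_crowd(F)

    def update_archive(AX, AF, newX, newF):
        # prune the (small) new batch internally and against the archive,
        # which is mutually nondominated by construction: O(|new| * |A|)
        keep_new = _nondominated_mask(newF)
        newX, newF = newX[keep_new], newF[keep_new]
        _, uniq = np.unique(newF, axis=0, return_index=True)
        newX, newF = newX[np.sort(uniq)], newF[np.sort(uniq)]
        if AF is None:
            AX, AF = newX.copy(), newF.copy()
        else:
            # does any archive point dominate / duplicate each new point?
            le = np.all(AF[:, None, :] <= newF[None, :, :], axis=2)
            lt = np.any(AF[:, None, :] < newF[None, :, :], axis=2)
            eq = np.all(AF[:, None, :] == newF[None, :, :], axis=2)
            admit = ~np.any((le & lt) | eq, axis=0)
            if admit.any():
                newX, newF = newX[admit], newF[admit]
                # evict archive points dominated by an admitted newcomer
                le = np.all(newF[:, None, :] <= AF[None, :, :], axis=2)
                lt = np.any(newF[:, None, :] < AF[None, :, :], axis=2)
                survive = ~np.any(le & lt, axis=0)
                AX = np.vstack([AX[survive], newX])
                AF = np.vstack([AF[survive], newF])
        if len(AF) > config.archive_max:
            cd = crowding_distance(AF)
            order = np.argsort(-cd, kind="stable")[: config.archive_max]
            AX, AF = AX[np.sort(order)], AF[np.sort(order)]
        return AX, AF

    AX, AF = update_archive(None, None, X, F)
    history = []
    stall_stat = None
    stall_count = 0
    gen = 0
    for gen in range(1, max_gen + 1):
        # offspring
        children = []
        while len(children) < pop_size:
            i = tournament_select(rank, crowd, rng, config.tournament_size)
            j = tournament_select(rank, crowd, rng, config.tournament_size)
            c1, c2 = intermediate_crossover(
                X[i], X[j], rng, b, config.crossover_ratio, config.crossover_rate
            )
            children.append(uniform_mutation(c1, rng, b, config.mutation_rate))
            children.append(uniform_mutation(c2, rng, b, config.mutation_rate))
        Q = np.asarray(children[:pop_size])
        FQ = problem.evaluate(Q) * sign

        # elitist environmental selection on the pooled population
        Xall = np.vstack([X, Q])
        Fall = np.vstack([F, FQ])
        fronts_all = fast_nondominated_sort(Fall)
        keep = []
        for front in fronts_all:
            if len(keep) + len(front) <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(Fall[front])
                order = front[np.argsort(-cd, kind="stable")]
                keep.extend(order[: pop_size - len(keep)].tolist())
                break
        keep = np.asarray(keep)
        X, F = Xall[keep], Fall[keep]
        fronts, rank, crowd = rank_crowd(F)

        front1 = fronts[0]
        # every evaluated offspring feeds the archive, so the best-known
        # front can only improve
        AX, AF = update_archive(AX, AF, Q, FQ)
        stat = np.concatenate([AF.min(axis=0), AF.mean(axis=0)])
        history.append(
            {"generation": gen, "front_size": len(front1),
             **{f"ideal_{k}": F[front1].min(axis=0)[k] for k in range(F.shape[1])}}
        )
        if stall_stat is not None:
            denom = np.maximum(np.abs(stall_stat), 1e-12)
            change = np.max(np.abs(stat - stall_stat) / denom)
            stall_count = stall_count + 1 if change < config.stall_tol else 0
            if stall_count >= config.stall_generations:
                break
        stall_stat = stat

    target = config.front_size or int(round(config.pareto_fraction * pop_size))
    # over-select, polish locally, then keep the best-spread nondominated set
    idx = np.arange(len(AF))
    if len(idx) > 2 * target:
        cd = crowding_distance(AF)
        idx = idx[np.argsort(-cd, kind="stable")][: 2 * target]
    PX, PF = _polish(problem, AX[idx], AF[idx], rng, config)
    keep = np.flatnonzero(_nondominated_mask(PF))
    _, uniq = np.unique(PF[keep], axis=0, return_index=True)
    keep = keep[np.sort(uniq)]
    if len(keep) > target:
        cd = crowding_distance(PF[keep])
        keep = keep[np.argsort(-cd, kind="stable")][:target]
    # stable presentation: sort by the first objective
    keep = keep[np.argsort(PF[keep][:, 0], kind="stable")]
    return ParetoFrontRaw(
        X=PX[keep].copy(),
        F=(PF[keep] * sign).copy(),
        generations=gen,
        history=pd.DataFrame(history),
    )


def surrogate_problem(net=None) -> OptimizationProblem:
    """The four-objective blanching/drying problem over a surrogate network.

    Minimise drying time and specific energy consumption, maximise
    ascorbic-acid content and rehydration capacity over
    BT in [30, 120] s, T in [50, 90] degC, v in [0.01, 2.5] m/s.
    Uses the published reconstructed network when ``net`` is omitted.
    """
    from .network import INPUT_BOUNDS, RESPONSE_NAMES, forward, published_network

    net = net or published_network()

    def objective(X):
        out = forward(net, X[:, 0], X[:, 1], X[:, 2], check_domain=False)
        return np.column_stack([out[name] for name in RESPONSE_NAMES])

    return OptimizationProblem(
        objective=objective,
        senses=("min", "min", "max", "max"),
        bounds=INPUT_BOUNDS,
        var_names=("bt_s", "t_c", "v_ms"),
        obj_names=RESPONSE_NAMES,
    )
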