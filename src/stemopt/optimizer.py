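"""Taguchi two-level orthogonal-array search with probabilistic restarts.

Each restart picks the stored vertex farthest from the rest (a
variable-variance-weighted max-min criterion), builds two levels per design
variable (current value -/+ 0.2 x domain width for continuous variables,
-/+ 1 for the integer exponents, box-projected into bounds), runs the
smallest two-level orthogonal array that accommodates the factors, and
moves to the main-effects optimum; the array step is iterated until no
further improvement, and the local optimum is added to the vertex store so
later restarts are pushed toward unexplored regions.  Termination mirrors
the original flowchart: T1 — the suggested optimum is not better (factor
interactions), fall back to the best evaluated run; T2 — the optimum is
already stored, skip to the next restart; T3 — the restart budget is
exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (CapacityError, InfeasibleError, InsufficientVerticesError,
                     InvalidParameterError)

__all__ = ["VertexSpace", "TwoLevelDesign", "OptimizerConfig",
           "OptimizationResult", "orthogonal_array", "make_levels", "project",
           "vvp_select", "taguchi_step", "optimize", "random_vertex"]

_MAX_RUNS = 64


@dataclass(frozen=True)
class VertexSpace:
    """Box bounds plus an integer mask for the design variables."""

    lower: tuple
    upper: tuple
    integer_mask: tuple = None

    def __post_init__(self):
        lo = np.asarray(self.lower, float)
        up = np.asarray(self.upper, float)
        if lo.shape != up.shape or lo.ndim != 1:
            raise InvalidParameterError("lower/upper must be 1-D of equal length")
        if np.any(lo > up):
            raise InvalidParameterError("lower bound exceeds upper bound")
        mask = (np.zeros(lo.size, bool) if self.integer_mask is None
                else np.asarray(self.integer_mask, bool))
        object.__setattr__(self, "lower", tuple(lo))
        object.__setattr__(self, "upper", tuple(up))
        object.__setattr__(self, "integer_mask", tuple(mask))

    @property
    def n(self) -> int:
        return len(self.lower)

    @property
    def width(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    @classmethod
    def from_bounds(cls, bounds) -> "VertexSpace":
        """Build from a geometry.Bounds (20-variable stem design space)."""
        return cls(bounds.lower, bounds.upper, tuple(bounds.integer_mask))


def project(space: VertexSpace, x) -> np.ndarray:
    """Box projection: clip to bounds, round integer variables (idempotent)."""
    v = np.clip(np.asarray(x, float), space.lower, space.upper)
    mask = np.asarray(space.integer_mask)
    if mask.any():
        v = v.copy()
        v[mask] = np.clip(np.round(v[mask]),
                          np.asarray(space.lower)[mask],
                          np.asarray(space.upper)[mask])
    return v


def random_vertex(space: VertexSpace, rng: np.random.Generator) -> np.ndarray:
    lo, up = np.asarray(space.lower), np.asarray(space.upper)
    v = lo + rng.random(space.n) * (up - lo)
    mask = np.asarray(space.integer_mask)
    if mask.any():
        v[mask] = rng.integers(lo[mask].astype(int), up[mask].astype(int) + 1)
    return v


# --------------------------------------------------------------------------
# orthogonal arrays
# --------------------------------------------------------------------------

def orthogonal_array(n_factors: int) -> np.ndarray:
    """Smallest standard two-level orthogonal array holding ``n_factors``.

    Built from Sylvester-Hadamard matrices: 2^k runs support up to 2^k - 1
    factors (L4, L8, ..., L64); entries are levels {1, 2}, every column is
    balanced and every column pair contains each level combination equally
    often.  20 factors therefore get a 32-run array.
    """
    if n_factors < 1:
        raise InvalidParameterError("need at least one factor")
    runs = 2
    while runs - 1 < n_factors:
        runs *= 2
        if runs > _MAX_RUNS:
            raise CapacityError(
                f"{n_factors} factors exceed the supported {_MAX_RUNS}-run arrays")
    h = np.array([[1]])
    while h.shape[0] < runs:
        h = np.block([[h, h], [h, -h]])
    cols = h[:, 1:n_factors + 1]
    return np.where(cols > 0, 1, 2).astype(int)


@dataclass(frozen=True)
class TwoLevelDesign:
    """Per-factor level pairs plus the orthogonal run array."""

    levels: np.ndarray    # (n_factors, 2)
    array: np.ndarray     # (runs, n_factors), entries in {1, 2}

    def run_vector(self, run: int) -> np.ndarray:
        idx = self.array[run] - 1
        return self.levels[np.arange(self.levels.shape[0]), idx]

    @property
    def n_runs(self) -> int:
        return self.array.shape[0]


def make_levels(x, space: VertexSpace, offset: float = 0.2) -> TwoLevelDesign:
    """Two levels per variable: x -/+ offset*width (continuous), p -/+ 1
    (integer exponents), box-projected into the search intervals."""
    x = np.asarray(x, float)
    mask = np.asarray(space.integer_mask)
    delta = np.where(mask, 1.0, offset * space.width)
    lo = project(space, x - delta)
    hi = project(space, x + delta)
    return TwoLevelDesign(np.column_stack([lo, hi]), orthogonal_array(space.n))


# --------------------------------------------------------------------------
# restart selection
# --------------------------------------------------------------------------

def _normalize(store: np.ndarray, space: VertexSpace) -> np.ndarray:
    lo, w = np.asarray(space.lower), space.width
    w = np.where(w > 0, w, 1.0)
    return (np.asarray(store, float) - lo) / w


def vvp_select(store, space: VertexSpace, weighted: bool = True) -> int:
    """Index of the stored vertex farthest from the rest.

    Distances are Euclidean in the unit box, with each coordinate weighted by
    the store's per-coordinate variance (the variable-variance reading of the
    probabilistic restart density); the vertex maximizing its minimum
    weighted distance to all other vertices wins, ties broken by lowest
    index.  Set ``weighted=False`` for the plain max-min criterion.
    """
    store = np.asarray(store, float)
    if store.ndim != 2 or store.shape[0] < 2:
        raise InsufficientVerticesError("need at least two stored vertices")
    u = _normalize(store, space)
    if weighted:
        w = np.var(u, axis=0)
        if not np.any(w > 0):
            w = np.ones(u.shape[1])
    else:
        w = np.ones(u.shape[1])
    diff = u[:, None, :] - u[None, :, :]
    d2 = np.einsum("ijk,k->ij", diff ** 2, w)
    np.fill_diagonal(d2, np.inf)
    scores = d2.min(axis=1)
    return int(np.argmax(scores))


# --------------------------------------------------------------------------
# Taguchi step and the full search
# --------------------------------------------------------------------------

def taguchi_step(evaluator, x, space: VertexSpace, offset: float = 0.2,
                 fx: float | None = None, use_sn_ratio: bool = False):
    """One orthogonal-array step from vertex ``x``.

    Evaluates every run of the array, estimates per-factor main effects
    (mean response per level, or the smaller-the-better Taguchi S/N ratio
    -10 log10(mean y^2) when ``use_sn_ratio``), evaluates the predicted
    level combination, and returns the best of {current vertex, best run,
    predicted optimum} (preferring the current vertex on ties, so a constant
    objective returns its input) together with the evaluation log.
    """
    x = project(space, x)
    design = make_levels(x, space, offset)
    ys = np.empty(design.n_runs)
    log = []
    for r in range(design.n_runs):
        xr = design.run_vector(r)
        ys[r] = evaluator(xr)
        log.append((xr, float(ys[r])))
    if not np.all(np.isfinite(ys)):
        raise InfeasibleError("evaluator returned a non-finite objective")
    if fx is None:
        fx = float(evaluator(x))
        log.append((x.copy(), fx))

    pick = np.empty(space.n)
    for i in range(space.n):
        resp = []
        for level in (0, 1):
            sel = ys[design.array[:, i] == level + 1]
            if use_sn_ratio:
                # larger S/N is better; store its negation so min picks it
                resp.append(-(-10.0 * np.log10(np.mean(sel ** 2) + 1e-300)))
            else:
                resp.append(np.mean(sel))
        pick[i] = design.levels[i, int(np.argmin(resp))]
    x_pred = project(space, pick)
    y_pred = float(evaluator(x_pred))
    log.append((x_pred.copy(), y_pred))

    r_best = int(np.argmin(ys))
    candidates = [(fx, 0, x, fx), (float(ys[r_best]), 1, design.run_vector(r_best), float(ys[r_best])),
                  (y_pred, 2, x_pred, y_pred)]
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, x_out, y_out = candidates[0]
    return np.asarray(x_out, float), float(y_out), log


@dataclass(frozen=True)
class OptimizerConfig:
    n_init: int = 10
    max_restarts: int = 30
    seed: int = 0
    level_offset: float = 0.2
    inner_iterations: int = 50
    duplicate_tol: float = 1e-9
    vvp_weighted: bool = True
    use_sn_ratio: bool = False


@dataclass
class OptimizationResult:
    best_x: np.ndarray
    best_f: float
    optima: list               # [(x, f)] distinct local optima, ranked
    store: np.ndarray
    log: list                  # per-evaluation records
    n_evaluations: int
    restarts_used: int
    best_history: list = field(default_factory=list)


def _is_duplicate(x, store, space, tol) -> bool:
    u = _normalize(np.vstack([store, x[None, :]]), space)
    d = np.linalg.norm(u[:-1] - u[-1], axis=1)
    return bool(np.any(d <= tol * np.sqrt(space.n) + 1e-15))


def optimize(evaluator, space: VertexSpace,
             config: OptimizerConfig | None = None) -> OptimizationResult:
    """Full global search: random seeding, farthest-vertex restarts,
    iterated orthogonal-array local steps.  Deterministic for a fixed seed."""
    cfg = config or OptimizerConfig()
    rng = np.random.default_rng(cfg.seed)
    log, n_eval = [], 0

    def f(x, tag, restart):
        nonlocal n_eval
        y = float(evaluator(np.asarray(x, float)))
        n_eval += 1
        log.append({"restart": restart, "tag": tag,
                    "x": np.asarray(x, float).tolist(), "objective": y})
        return y

    store_list, store_f = [], []
    tries = 0
    while len(store_list) < cfg.n_init:
        v = random_vertex(space, rng)
        tries += 1
        if store_list and _is_duplicate(v, np.array(store_list), space, cfg.duplicate_tol):
            if tries > 100 * cfg.n_init:
                break
            continue
        store_list.append(v)
        store_f.append(f(v, "init", -1))
    if not store_list:
        raise InfeasibleError("could not seed any initial vertex")
    store = np.array(store_list)
    best_i = int(np.argmin(store_f))
    best_x, best_f = store[best_i].copy(), float(store_f[best_i])
    best_history = [best_f]
    optima = []

    restarts = 0
    while restarts < cfg.max_restarts:
        restarts += 1
        idx = vvp_select(store, space, weighted=cfg.vvp_weighted)
        x, fx = store[idx].copy(), float(store_f[idx])
        for _ in range(cfg.inner_iterations):
            def run_eval(xx, _r=restarts):
                return f(xx, "doe", _r)
            x_new, f_new, _ = taguchi_step(run_eval, x, space, cfg.level_offset,
                                           fx=fx, use_sn_ratio=cfg.use_sn_ratio)
            if f_new < fx - 1e-15:
                x, fx = x_new, f_new
            else:
                break
        if fx < best_f:
            best_x, best_f = x.copy(), float(fx)
        best_history.append(best_f)
        if _is_duplicate(x, store, space, cfg.duplicate_tol):
            continue  # T2: already a known optimum -> next restart
        store = np.vstack([store, x])
        store_f.append(float(fx))
        optima.append((x.copy(), float(fx)))

    optima.sort(key=lambda t: t[1])
    return OptimizationResult(best_x, best_f, optima, store, log,
                              n_eval, restarts, best_history)
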