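"""Sparse canonical correlation analysis with positivity constraints.

Penalized-matrix-decomposition SCCA (diagonal-covariance CCA with L1 and
optional nonnegativity constraints): alternating soft-threshold updates of
the two canonical weight vectors

    u <- P( soft(X^T Y v, lambda_x) ),   ||u||_2 = 1, ||u||_1 <= c_x
    v <- P( soft(Y^T X u, lambda_y) ),   ||v||_2 = 1, ||v||_1 <= c_y

where P projects onto the nonnegative orthant when positivity is on and
each lambda is found by bisection so the L1 budget is met.  The sparseness
is specified as the target active fraction of each block's vertex
dimension (default one half); the L1 budget realising that fraction is
calibrated by bisection on a pilot fit.

Significance uses the constrained permutation test: subject pairings of
the two blocks are re-drawn as uniform derangements (no subject may keep
its own pairing), the SCCA is refitted with identical configuration, and
p is the plain ratio (#permuted r >= observed r) / B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import ConfigError, DegeneracyError

__all__ = [
    "SccaConfig",
    "SccaResult",
    "PermutationResult",
    "scca_fit",
    "choose_sparseness",
    "permutation_test",
    "sample_derangement",
]


@dataclass
class SccaConfig:
    """Tuning knobs for the SCCA alternation.

    ``sparseness_x``/``sparseness_y`` are target active fractions in (0, 1]
    when ``sparseness_mode='fraction'`` (the default), or raw L1 budgets in
    [1, sqrt(V)] when ``sparseness_mode='budget'``.
    """

    sparseness_x: float = 0.5
    sparseness_y: float = 0.5
    sparseness_mode: str = "fraction"
    positive_x: bool = True
    positive_y: bool = True
    max_iter: int = 100
    tol: float = 1e-6
    standardize: bool = False
    whiten: bool = False
    n_components: int = 1

    def __post_init__(self):
        if self.sparseness_mode not in ("fraction", "budget"):
            raise ConfigError("sparseness_mode must be 'fraction' or 'budget'")
        if self.sparseness_mode == "fraction":
            for s in (self.sparseness_x, self.sparseness_y):
                if not 0 < s <= 1:
                    raise ConfigError("active fraction must lie in (0, 1]")
        if self.tol <= 0:
            raise ConfigError("tolerance must be positive")


@dataclass
class SccaResult:
    u: np.ndarray               # ventricle-block weights, ||u||_2 = 1
    v: np.ndarray               # thickness-block weights, ||v||_2 = 1
    r: float                    # canonical correlation of (Xu, Yv)
    iterations: int
    converged: bool
    budget_x: float = np.nan    # realised L1 budgets (c_x, c_y)
    budget_y: float = np.nan
    objective: float = np.nan   # u^T X^T Y v at the solution


@dataclass
class PermutationResult:
    observed_r: float
    permuted_r: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    convention: str = "ratio"


# ----------------------------------------------------------------------
# constrained unit-vector update
# ----------------------------------------------------------------------

def _soft(a: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def _l1l2_lambda(a_abs: np.ndarray, c: float) -> float:
    """Soft-threshold level lambda with ||S(a,l)||_1 / ||S(a,l)||_2 = c.

    The ratio is continuous and non-increasing in lambda with knots at the
    sorted magnitudes; within a knot interval (top-m support fixed) the
    constraint is a quadratic in lambda, solved in closed form.
    """
    d = np.sort(a_abs)[::-1]
    s1 = np.cumsum(d)
    s2 = np.cumsum(d * d)
    m = np.arange(1, len(d) + 1)
    # ratio evaluated just above each knot d_m (support = top m-1 ... use m)
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = s1 - m * d
        l2 = np.sqrt(np.maximum(s2 - 2 * d * s1 + m * d * d, 0.0))
        ratio = np.where(l2 > 0, l1 / l2, 0.0)
    # first knot index where the ratio (increasing along the sorted knots,
    # i.e. with decreasing lambda) reaches c; the crossing lambda lies in
    # (d[idx], d[idx-1]] where the support is the top idx magnitudes
    idx = int(np.searchsorted(ratio, c))
    idx = min(max(idx, 1), len(d) - 1)
    mm = idx
    s1m, s2m = s1[idx - 1], s2[idx - 1]
    lo, hi = d[idx], d[idx - 1]
    aa = mm * (mm - c * c)
    bb = -2.0 * s1m * (mm - c * c)
    cc = s1m * s1m - c * c * s2m
    if abs(aa) < 1e-300:
        lam = -cc / bb if abs(bb) > 1e-300 else 0.5 * (lo + hi)
    else:
        disc = max(bb * bb - 4 * aa * cc, 0.0)
        r1 = (-bb - np.sqrt(disc)) / (2 * aa)
        r2 = (-bb + np.sqrt(disc)) / (2 * aa)
        lam = r1 if lo - 1e-12 <= r1 <= hi + 1e-12 else r2
    return float(np.clip(lam, 0.0, d[0]))


def _update_weight(a: np.ndarray, c: float, positive: bool) -> np.ndarray:
    """argmax_u a.u  s.t. ||u||_2 <= 1, ||u||_1 <= c (and u >= 0 if positive)."""
    if positive:
        a = np.maximum(a, 0.0)
        if not a.any():
            return np.zeros_like(a)
    nrm = np.linalg.norm(a)
    if nrm == 0:
        return np.zeros_like(a)
    u = a / nrm
    if np.sum(np.abs(u)) <= c + 1e-12:
        return u
    lam = _l1l2_lambda(np.abs(a), c)
    s = _soft(a, lam)
    n2 = np.linalg.norm(s)
    if n2 == 0:
        # budget at its floor: keep only the largest coordinate
        out = np.zeros_like(a)
        j = int(np.argmax(np.abs(a)))
        out[j] = np.sign(a[j])
        return out
    return s / n2


def _center(m: np.ndarray, standardize: bool) -> np.ndarray:
    m = m - m.mean(axis=0)
    if standardize:
        sd = m.std(axis=0, ddof=1)
        m = m / np.where(sd > 0, sd, 1.0)
    return m


def _fit_budgets(z: np.ndarray, c_x: float, c_y: float, config: SccaConfig,
                 v0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Alternation at fixed L1 budgets on the cross-product matrix z = X^T Y."""
    if v0 is None:
        v = z.sum(axis=0)
        if config.positive_y:
            v = np.abs(v)
        n = np.linalg.norm(v)
        v = v / n if n > 0 else np.full(z.shape[1], 1.0 / np.sqrt(z.shape[1]))
    else:
        v = v0
    u = np.zeros(z.shape[0])
    it = 0
    converged = False
    for it in range(1, config.max_iter + 1):
        u_new = _update_weight(z @ v, c_x, config.positive_x)
        v_new = _update_weight(z.T @ u_new, c_y, config.positive_y)
        delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(v_new - v)))
        u, v = u_new, v_new
        if delta < config.tol:
            converged = True
            break
    return u, v, it, converged


def _dense_budget(nv: int) -> float:
    return float(np.sqrt(nv))


def choose_sparseness(
    n_vertices: int,
    fraction: float = 0.5,
    cross_product: np.ndarray | None = None,
    axis: int = 0,
    config: SccaConfig | None = None,
    seed: int = 0,
    rel_tol: float = 0.10,
    other_budget: float | None = None,
) -> float:
    """L1 budget whose pilot-fit active set is ~``fraction`` of the block.

    If ``cross_product`` (X^T Y) is given the calibration bisects on pilot
    fits of the actual data (``axis`` 0 calibrates the X block, 1 the Y
    block); otherwise a seeded standard-normal pilot of the same dimension
    is used.  The returned budget puts the active-set size within
    ``rel_tol`` of fraction * V whenever that size is attainable.
    """
    if n_vertices < 1:
        raise ConfigError("block dimension must be >= 1")
    if n_vertices == 1 or fraction >= 1.0:
        if fraction < 1.0 and n_vertices == 1:
            warnings.warn("a single weight cannot be sparsified; budget clamped to 1")
        return _dense_budget(n_vertices)
    config = config or SccaConfig()
    target = fraction * n_vertices
    if cross_product is None:
        rng = np.random.default_rng(seed)
        n_pilot = 50
        x = rng.normal(size=(n_pilot, n_vertices))
        y = rng.normal(size=(n_pilot, max(2, n_vertices // 2)))
        cross_product = _center(x, False).T @ _center(y, False)
        axis = 0

    def active(c: float) -> int:
        if axis == 0:
            cy = other_budget if other_budget is not None else _dense_budget(cross_product.shape[1])
            u, _, _, _ = _fit_budgets(cross_product, c, cy, config)
            return int(np.count_nonzero(u))
        cx = other_budget if other_budget is not None else _dense_budget(cross_product.shape[0])
        _, v, _, _ = _fit_budgets(cross_product, cx, c, config)
        return int(np.count_nonzero(v))

    lo, hi = 1.0, _dense_budget(n_vertices)
    best, best_err = 0.5 * (lo + hi), np.inf
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        k = active(mid)
        err = abs(k - target)
        if err < best_err:
            best, best_err = mid, err
        if err <= rel_tol * target:
            return mid
        if k < target:
            lo = mid
        else:
            hi = mid
    return best


def _inv_sqrt_cov(m: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    cov = m.T @ m / max(len(m) - 1, 1)
    w, q = np.linalg.eigh(cov)
    cut = rcond * w.max()
    inv = np.where(w > cut, 1.0 / np.sqrt(np.maximum(w, cut)), 0.0)
    return (q * inv) @ q.T


def _resolve_budgets(x, y, config: SccaConfig) -> tuple[float, float]:
    vx, vy = x.shape[1], y.shape[1]
    if config.sparseness_mode == "budget":
        return float(config.sparseness_x), float(config.sparseness_y)
    z = x.T @ y
    cx, cy = _dense_budget(vx), _dense_budget(vy)
    sparse_x = config.sparseness_x < 1.0 and vx > 1
    sparse_y = config.sparseness_y < 1.0 and vy > 1
    # the blocks' budgets interact through the alternation, so calibrate
    # them alternately, each against the other's current budget
    for _ in range(2 if (sparse_x and sparse_y) else 1):
        if sparse_x:
            cx = choose_sparseness(vx, config.sparseness_x, cross_product=z,
                                   axis=0, config=config, other_budget=cy)
        if sparse_y:
            cy = choose_sparseness(vy, config.sparseness_y, cross_product=z,
                                   axis=1, config=config, other_budget=cx)
    return cx, cy


def scca_fit(
    x: np.ndarray,
    y: np.ndarray,
    config: SccaConfig | None = None,
    budgets: tuple[float, float] | None = None,
) -> SccaResult:
    """Fit the leading sparse canonical pair of two subject x vertex blocks.

    Columns are mean-centered internally (standardized if configured).
    ``budgets`` overrides sparseness resolution with explicit L1 budgets,
    which the permutation test uses to keep the configuration identical
    across refits.
    """
    config = config or SccaConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ConfigError("X and Y must have the same number of subjects")
    if x.shape[0] < 3:
        raise ConfigError("need at least 3 subjects")
    xc = _center(x, config.standardize)
    yc = _center(y, config.standardize)
    if not xc.any() or not yc.any():
        raise DegeneracyError("a data block has zero variance after centering")
    if config.whiten:
        # whitening turns the covariance alternation into classical CCA:
        # unit-variance projections make covariance and correlation coincide
        xc = xc @ _inv_sqrt_cov(xc)
        yc = yc @ _inv_sqrt_cov(yc)
    if budgets is None:
        budgets = _resolve_budgets(xc, yc, config)
    c_x, c_y = budgets
    z = xc.T @ yc
    u, v, it, converged = _fit_budgets(z, c_x, c_y, config)
    if not converged:
        warnings.warn(f"SCCA alternation did not converge in {config.max_iter} iterations")
    xu = xc @ u
    yv = yc @ v
    if xu.std() == 0 or yv.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(xu, yv)[0, 1])
    return SccaResult(u=u, v=v, r=r, iterations=it, converged=converged,
                      budget_x=c_x, budget_y=c_y, objective=float(u @ z @ v))


# ----------------------------------------------------------------------
# permutation inference
# ----------------------------------------------------------------------

def sample_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random derangement by rejection from uniform permutations."""
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    config: SccaConfig | None = None,
    n_permutations: int = 2000,
    seed: int | None = 0,
    convention: str = "ratio",
) -> PermutationResult:
    """Derangement permutation test of the leading canonical correlation.

    Each iteration re-pairs every subject's ventricle block row with a
    uniformly drawn derangement of the thickness rows (no subject keeps
    its own pairing), refits the SCCA with the exact budgets of the
    observed fit, and records the permuted correlation.  ``convention``
    'ratio' gives p = k / B exactly; 'add_one' gives (k + 1) / (B + 1).
    """
    config = config or SccaConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = x.shape[0]
    if n < 4:
        raise ConfigError("permutation test requires n >= 4 subjects")
    if n_permutations < 100:
        warnings.warn(f"B = {n_permutations} gives p-value granularity {1 / n_permutations:.3f}")
    if convention not in ("ratio", "add_one"):
        raise ConfigError("convention must be 'ratio' or 'add_one'")
    observed = scca_fit(x, y, config)
    budgets = (observed.budget_x, observed.budget_y)
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_permutations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_permutations):
            perm = sample_derangement(rng, n)
            perm_r[b] = scca_fit(x, y[perm], config, budgets=budgets).r
    k = int(np.sum(perm_r >= observed.r))
    p = k / n_permutations if convention == "ratio" else (k + 1) / (n_permutations + 1)
    return PermutationResult(observed_r=observed.r, permuted_r=perm_r, p_value=p,
                             n_permutations=n_permutations, seed=seed,
                             convention=convention)
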