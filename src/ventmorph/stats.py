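"""Group-level statistics: demographic tests, ANCOVA, surface smoothing.

The group comparison layer mirrors standard morphometry practice:
chi-square / Fisher tests for categorical demographics, t or Mann-Whitney
tests for continuous ones, ANCOVA (OLS with group indicator + covariates)
for volumes and vertex-wise maps with Bonferroni familywise correction,
and heat-kernel smoothing of surface scalars specified by FWHM in mm.

Group is coded 1 = INPH, 0 = control throughout, so a positive group
effect means expansion (or thickening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps

from ._errors import ConfigError, DataError, DegeneracyError

__all__ = [
    "DemographicTestReport",
    "VertexStatResult",
    "demographic_tests",
    "two_sample_t_from_stats",
    "chi_square_2x2",
    "volume_ancova",
    "vertexwise_ancova",
    "smooth_surface_scalar",
]

DEFAULT_COVARIATES = ("age", "icv_mm3")


# ----------------------------------------------------------------------
# demographic tests
# ----------------------------------------------------------------------

@dataclass
class DemographicTestReport:
    """Per-variable test results with the group summaries they came from."""

    rows: list = field(default_factory=list)

    def add(self, variable, test, statistic, p_value, summary):
        if not (0 < p_value <= 1 or np.isnan(p_value)):
            raise DataError(f"p-value {p_value} outside (0, 1] for {variable}")
        self.rows.append({
            "variable": variable, "test": test, "statistic": statistic,
            "p_value": p_value, "summary": summary,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def p_value(self, variable: str) -> float:
        for r in self.rows:
            if r["variable"] == variable:
                return r["p_value"]
        raise KeyError(variable)


def chi_square_2x2(k1: int, n1: int, k2: int, n2: int,
                   correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table given per-group successes/totals."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.min() < 0 or n1 <= 0 or n2 <= 0:
        raise ConfigError("counts must be nonnegative with positive group sizes")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    odds, p = sps.fisher_exact(table)
    return float(odds), float(p)


def two_sample_t_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                            equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t test from printed group summaries (Welch by default)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


_CONTINUOUS_TESTS = ("t", "welch_t", "mannwhitney")
_CATEGORICAL_TESTS = ("chi2", "fisher")


def demographic_tests(
    cohort: pd.DataFrame,
    variables,
    test_map: dict | None = None,
    group_col: str = "group",
    groups: tuple = ("INPH", "control"),
) -> DemographicTestReport:
    """Compare demographic variables between the two groups.

    ``test_map`` assigns a test per variable: 'chi2' or 'fisher' for
    categorical variables, 't' (pooled), 'welch_t' or 'mannwhitney' for
    continuous ones; unlisted continuous variables default to 'welch_t'
    and unlisted categorical ones to 'chi2'.
    """
    test_map = dict(test_map or {})
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ConfigError("each group needs at least 2 subjects")
    report = DemographicTestReport()
    for var in variables:
        if var not in cohort.columns:
            raise DataError(f"variable {var!r} not in the cohort table")
        x1, x2 = g1[var], g2[var]
        categorical = not pd.api.types.is_numeric_dtype(cohort[var])
        test = test_map.get(var, "chi2" if categorical else "welch_t")
        if categorical:
            if test not in _CATEGORICAL_TESTS:
                raise ConfigError(f"test {test!r} invalid for categorical {var!r}")
            levels = sorted(cohort[var].dropna().unique())
            if len(levels) != 2:
                raise DataError(f"categorical variable {var!r} must have 2 levels")
            k1, k2 = int((x1 == levels[0]).sum()), int((x2 == levels[0]).sum())
            if test == "chi2":
                stat, p = chi_square_2x2(k1, len(x1), k2, len(x2))
            else:
                stat, p = fisher_exact_2x2(k1, len(x1), k2, len(x2))
            summary = f"{levels[0]}: {k1}/{len(x1)} vs {k2}/{len(x2)}"
        else:
            if test not in _CONTINUOUS_TESTS:
                raise ConfigError(f"test {test!r} invalid for continuous {var!r}")
            a, b = x1.to_numpy(dtype=float), x2.to_numpy(dtype=float)
            if test == "mannwhitney":
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                res = sps.ttest_ind(a, b, equal_var=(test == "t"))
                stat, p = float(res.statistic), float(res.pvalue)
            summary = (f"{a.mean():.2f} +- {a.std(ddof=1):.2f} (n={len(a)}) vs "
                       f"{b.mean():.2f} +- {b.std(ddof=1):.2f} (n={len(b)})")
        report.add(var, test, stat, p, summary)
    return report


# ----------------------------------------------------------------------
# ANCOVA
# ----------------------------------------------------------------------

def _ancova_design(cohort: pd.DataFrame, covariates, group_col="group",
                   case_label="INPH") -> tuple[np.ndarray, int]:
    n = len(cohort)
    cols = [np.ones(n), (cohort[group_col] == case_label).to_numpy(dtype=float)]
    for c in covariates:
        if c not in cohort.columns:
            raise DataError(f"covariate {c!r} missing from the cohort table")
        v = cohort[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise DataError(f"covariate {c!r} has missing values")
        cols.append(v)
    x = np.column_stack(cols)
    if np.linalg.cond(x) > 1e10:
        raise DegeneracyError("collinear ANCOVA design (condition number > 1e10)")
    return x, 1  # group column index


def volume_ancova(
    volumes: np.ndarray,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "group",
    case_label: str = "INPH",
) -> dict:
    """OLS of volume on group + covariates; reports the group effect.

    With ``covariates=()`` this reduces exactly to the pooled two-sample
    t test.  Returns a dict with the group-effect estimate, its t
    statistic, two-sided p-value and residual degrees of freedom.
    """
    y = np.asarray(volumes, dtype=float)
    if len(y) != len(cohort):
        raise DataError("volumes and cohort table have different lengths")
    x, gidx = _ancova_design(cohort, covariates, group_col, case_label)
    n, p = x.shape
    if n <= p:
        raise ConfigError(f"{n} subjects cannot fit {p} parameters")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[gidx, gidx])
    t = beta[gidx] / se
    pval = 2.0 * sps.t.sf(abs(t), dof)
    return {"effect": float(beta[gidx]), "se": float(se), "t": float(t),
            "p": float(pval), "dof": dof, "covariates": tuple(covariates)}


@dataclass
class VertexStatResult:
    """Vertex-wise ANCOVA group effects with a Bonferroni significance mask."""

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha_family: float
    n_tests: int
    correction: str
    covariates: tuple

    @property
    def n_vertices(self) -> int:
        return len(self.effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex": np.arange(self.n_vertices), "beta": self.effect,
            "t": self.t, "p": self.p, "significant": self.significant,
        })


def vertexwise_ancova(
    maps: np.ndarray,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    alpha_family: float = 0.01,
    correction: str = "bonferroni",
    n_tests: int | None = None,
    group_col: str = "group",
    case_label: str = "INPH",
) -> VertexStatResult:
    """Per-vertex ANCOVA of maps on group + covariates, Bonferroni-masked.

    ``maps`` is (n_subjects, V); rows match the cohort table.  The mask
    marks p <= alpha_family / n_tests where ``n_tests`` defaults to V but
    can be set larger when several surfaces (e.g. left + right) are tested
    as one family.  ``correction='per_vertex'`` applies the uncorrected
    alpha at each vertex instead.
    """
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    if len(m) != len(cohort):
        raise DataError("map stack and cohort table have different lengths")
    x, gidx = _ancova_design(cohort, covariates, group_col, case_label)
    n, p = x.shape
    if n <= p:
        raise ConfigError(f"{n} subjects cannot fit {p} parameters per vertex")
    nv = m.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ m            # (p, V)
    resid = m - x @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[gidx, gidx], 1e-300))
    t = beta[gidx] / se
    pv = np.clip(2.0 * sps.t.sf(np.abs(t), dof), np.finfo(float).tiny, 1.0)
    total = int(n_tests) if n_tests is not None else nv
    if correction == "bonferroni":
        thresh = alpha_family / total
    elif correction == "per_vertex":
        thresh = alpha_family
    else:
        raise ConfigError(f"unknown correction {correction!r}")
    return VertexStatResult(
        effect=beta[gidx], t=t, p=pv, significant=pv <= thresh,
        alpha_family=alpha_family, n_tests=total, correction=correction,
        covariates=tuple(covariates),
    )


# ----------------------------------------------------------------------
# surface smoothing
# ----------------------------------------------------------------------

def _cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray):
    """Symmetric cotangent edge weights and barycentric vertex areas."""
    v = vertices
    ii, jj, ww = [], [], []
    areas = np.zeros(len(v))
    for k in range(3):
        a = faces[:, k]
        b = faces[:, (k + 1) % 3]
        c = faces[:, (k + 2) % 3]
        # cotangent at vertex a weights edge (b, c)
        e1 = v[b] - v[a]
        e2 = v[c] - v[a]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-12)
        ii.extend([b, c])
        jj.extend([c, b])
        ww.extend([0.5 * cot, 0.5 * cot])
        if k == 0:
            fa = 0.5 * cross
            for col in range(3):
                np.add.at(areas, faces[:, col], fa / 3.0)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    w = sparse.coo_matrix((ww, (ii, jj)), shape=(len(v), len(v))).tocsr()
    lap = w - sparse.diags(np.asarray(w.sum(axis=1)).ravel())
    return lap, areas


def smooth_surface_scalar(values: np.ndarray, mesh, fwhm: float) -> np.ndarray:
    """Heat-kernel smoothing of a vertex scalar field on a surface.

    Explicit-Euler diffusion with the cotangent Laplacian, run to total
    diffusion time t = sigma^2 / 2 with sigma^2 = fwhm^2 / (8 ln 2), so the
    equivalent Gaussian kernel has the requested full-width at half-maximum
    in mm of geodesic distance.  The scheme conserves the area-weighted
    mean exactly and leaves constants unchanged; fwhm = 0 is the identity.
    """
    if fwhm < 0:
        raise ConfigError("fwhm must be nonnegative")
    f = np.asarray(values, dtype=float).copy()
    if fwhm == 0:
        return f
    vertices = mesh.vertices
    faces = mesh.faces
    if f.shape != (len(vertices),):
        raise DataError("scalar map length does not match the mesh")
    lap, areas = _cotangent_laplacian(vertices, faces)
    sigma2 = fwhm**2 / (8.0 * np.log(2.0))
    t_total = sigma2 / 2.0
    diag = -lap.diagonal()
    dt_stable = 0.5 * float(np.min(areas / np.maximum(diag, 1e-12)))
    n_steps = max(1, int(np.ceil(t_total / dt_stable)))
    dt = t_total / n_steps
    inv_a = 1.0 / areas
    for _ in range(n_steps):
        f = f + dt * inv_a * (lap @ f)
    return f
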