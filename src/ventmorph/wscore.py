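"""W-score normalization against a healthy-control covariate model.

W(v) = (raw(v) - expected(v | covariates)) / SD of control residuals(v),

fitted vertex-wise by ordinary least squares on the control group.  Like a
Z-score, W has mean 0 and SD 1 in controls, and +/-1.65 marks the 95th/5th
percentiles under normality.  Residual SD uses the degrees-of-freedom
corrected denominator n - p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError, DegeneracyError

__all__ = ["WScoreModel", "fit_control_model", "wscore"]

DEFAULT_COVARIATES = ("age", "icv_mm3")


@dataclass
class WScoreModel:
    """Per-vertex control regression: intercept + covariate slopes + residual SD."""

    coefficients: np.ndarray    # (1 + n_covariates, V)
    residual_sd: np.ndarray     # (V,)
    covariates: tuple
    n_controls: int

    @property
    def n_vertices(self) -> int:
        return self.coefficients.shape[1]

    def predict(self, subject_covariates) -> np.ndarray:
        x = _design_row(subject_covariates, self.covariates)
        return x @ self.coefficients

    def to_frame(self) -> pd.DataFrame:
        cols = {"intercept": self.coefficients[0]}
        for j, c in enumerate(self.covariates):
            cols[f"slope_{c}"] = self.coefficients[j + 1]
        cols["resid_sd"] = self.residual_sd
        df = pd.DataFrame(cols)
        df.insert(0, "vertex", np.arange(self.n_vertices))
        return df


def _design_row(subject_covariates, covariates) -> np.ndarray:
    row = [1.0]
    for c in covariates:
        if c not in subject_covariates or pd.isna(subject_covariates[c]):
            raise DataError(f"subject is missing covariate {c!r}")
        row.append(float(subject_covariates[c]))
    return np.asarray(row)


def fit_control_model(
    control_maps: np.ndarray,
    covariates: pd.DataFrame,
    covariate_names=DEFAULT_COVARIATES,
    sd_tol: float = 1e-10,
) -> WScoreModel:
    """Vertex-wise OLS of control map values on the configured covariates.

    Parameters
    ----------
    control_maps : (n_controls, V) array of per-vertex values.
    covariates : DataFrame with one row per control, containing
        ``covariate_names`` columns (row order matches ``control_maps``).
    """
    maps = np.atleast_2d(np.asarray(control_maps, dtype=float))
    n, nv = maps.shape
    names = tuple(covariate_names)
    p = 1 + len(names)
    if n < 4:
        raise ConfigError(f"need at least 4 controls, got {n}")
    if n <= p:
        raise ConfigError(f"{n} controls cannot identify {p} parameters plus a residual SD")
    for c in names:
        if c not in covariates.columns:
            raise DataError(f"covariate table is missing column {c!r}")
        if covariates[c].isna().any():
            raise DataError(f"covariate {c!r} has missing values")
    x = np.column_stack([np.ones(n)] + [covariates[c].to_numpy(dtype=float) for c in names])
    beta, *_ = np.linalg.lstsq(x, maps, rcond=None)
    resid = maps - x @ beta
    sd = np.sqrt(np.sum(resid**2, axis=0) / (n - p))
    scale = max(1.0, float(np.abs(maps).max()))
    bad = np.flatnonzero(sd <= sd_tol * scale)
    if bad.size:
        head = ", ".join(map(str, bad[:10]))
        raise DegeneracyError(
            f"control model is singular (zero residual SD) at {bad.size} "
            f"vertices: [{head}{'...' if bad.size > 10 else ''}]"
        )
    return WScoreModel(coefficients=beta, residual_sd=sd, covariates=names, n_controls=n)


def wscore(vertex_map: np.ndarray, subject_covariates, model: WScoreModel) -> np.ndarray:
    """Per-vertex W-score of one subject's map against the control model."""
    raw = np.asarray(vertex_map, dtype=float)
    if raw.shape != (model.n_vertices,):
        raise DataError(
            f"map has {raw.shape} values but the model was fitted on {model.n_vertices} vertices"
        )
    return (raw - model.predict(subject_covariates)) / model.residual_sd


def wscore_matrix(maps: np.ndarray, covariates: pd.DataFrame, model: WScoreModel) -> np.ndarray:
    """W-scores for a stack of subjects (rows match the covariate table)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    x = np.stack([_design_row(row, model.covariates) for _, row in covariates.iterrows()])
    return (maps - x @ model.coefficients) / model.residual_sd
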