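"""Sound-vs-silence activation: ordinary-least-squares block GLM.

One regressor of interest (the 18 s ON / 12 s OFF boxcar convolved with the
hemodynamic response), an intercept, optional linear drift, and pass-through
nuisance columns (e.g. motion parameters for real data).  No autocorrelation
whitening is applied, so t values are approximate under colored noise; the
synthetic path uses white noise where they are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import SweepDesign, on_block_regressor
from .simulate import hemodynamic_response
from .timeseries import SurfaceTimeSeries

__all__ = ["GlmResult", "build_design_matrix", "fit_glm"]


@dataclass
class GlmResult:
    beta: np.ndarray  # effect of the ON regressor, % signal
    t_stat: np.ndarray
    dof: int

    def p_two_sided(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t_stat), self.dof)


def build_design_matrix(
    design: SweepDesign,
    hemo_peak_s: float = 6.0,
    hemo_undershoot_s: float = 16.0,
    drift: bool = True,
    nuisance: np.ndarray | None = None,
    convolve: bool = True,
) -> np.ndarray:
    """Time × regressor matrix: [ON regressor, intercept, drift?, nuisance...].

    The ON column is the block boxcar convolved with the hemodynamic
    response sampled at TR (or the raw boxcar with ``convolve=False``).
    """
    box = on_block_regressor(design)
    if convolve:
        t = np.arange(0.0, 32.0, design.tr_s)
        kernel = hemodynamic_response(t, hemo_peak_s, hemo_undershoot_s)
        col = np.convolve(box, kernel)[: box.size]
        col /= col.max()
    else:
        col = box
    cols = [col, np.ones_like(col)]
    if drift:
        tt = np.arange(box.size, dtype=np.float64)
        cols.append(tt / tt[-1] - 0.5)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=np.float64))
        if nuisance.shape[0] != box.size:
            nuisance = nuisance.T
        cols.extend(nuisance.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def fit_glm(ts: SurfaceTimeSeries, X: np.ndarray) -> GlmResult:
    """Per-vertex OLS; t statistic for the ON-regressor contrast [1, 0, ...]."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != ts.n_timepoints:
        raise ValueError("design matrix rows must equal time points")
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    Y = ts.data.T  # time x vertices
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # regressors x vertices
    resid = Y - X @ B
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    c = np.zeros(X.shape[1])
    c[0] = 1.0
    var_c = c @ XtX_inv @ c
    beta = B[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 * var_c)
    return GlmResult(beta=beta, t_stat=t, dof=dof)
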