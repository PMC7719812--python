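"""First-level fMRI GLM with a canonical double-gamma HRF.

Regressors are condition boxcars convolved with the canonical
hemodynamic response function; the model is fit per voxel by ordinary
least squares, optionally with single-pass AR(1) prewhitening using the
pooled lag-1 residual autocorrelation (a documented approximation to a
full ReML fit with an autoregressive error model).  Second-level ROI
inference uses one-sample t within group (df = n - 1) and two-sample t
between groups (df = n1 + n2 - 2), signed control-minus-patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from closurenet.design import SessionDesign

__all__ = [
    "HrfParams",
    "Hrf",
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrast_t",
    "roi_contrast_table",
    "contrast_and_group",
]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma parameters (seconds).

    Defaults: response peak 6 s, undershoot peak 16 s, unit dispersions,
    undershoot ratio 1/6, 32 s support.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    ratio: float = 1.0 / 6.0
    length_s: float = 32.0


@dataclass(frozen=True)
class Hrf:
    kernel: np.ndarray   # sampled at TR resolution, starting at lag 0
    tr_s: float
    params: HrfParams

    def __len__(self) -> int:
        return len(self.kernel)


def hrf_continuous(t: np.ndarray, params: HrfParams) -> np.ndarray:
    """The double-gamma impulse response evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    a1 = params.peak_s / params.peak_disp_s
    a2 = params.undershoot_s / params.undershoot_disp_s
    if min(params.peak_disp_s, params.undershoot_disp_s) <= 0:
        raise ValueError("dispersions must be positive")
    h = (stats.gamma.pdf(t, a1, scale=params.peak_disp_s)
         - params.ratio * stats.gamma.pdf(t, a2, scale=params.undershoot_disp_s))
    return h


def canonical_hrf(params: HrfParams | None = None, tr_s: float = 2.0) -> Hrf:
    """Sample the double-gamma difference at TR resolution, unit-peak.

    The kernel starts at lag 0 (value 0, since both gamma shapes exceed
    one) and is normalized so its maximum is 1.
    """
    params = params or HrfParams()
    t = np.arange(0.0, params.length_s + 0.5 * tr_s, tr_s)
    h = hrf_continuous(t, params)
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF: all-zero kernel")
    return Hrf(kernel=h / np.max(h), tr_s=tr_s, params=params)


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # TRs x columns
    names: list[str]
    condition_names: list[str]  # subset of names that are condition regressors

    @property
    def n_tr(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        for name, w in weights.items():
            if name not in self.names:
                raise KeyError(f"no regressor named {name!r}")
            c[self.names.index(name)] = w
        return c


def build_design_matrix(
    design: SessionDesign,
    hrf: Hrf,
    drift_order: int = 2,
    conditions: list[str] | None = None,
) -> DesignMatrix:
    """Convolve condition boxcars with the HRF; add intercept and drifts.

    One column per non-rest condition (causal convolution, truncated to
    the session length), an intercept, and Legendre polynomial drift
    terms up to ``drift_order``.  Requesting a condition absent from the
    schedule is an error naming that condition.
    """
    sched = list(design.schedule)
    present = [c for c in dict.fromkeys(sched) if c != "rest"]
    if conditions is None:
        conditions = present
    for c in conditions:
        if c not in present:
            raise ValueError(f"condition {c!r} absent from schedule")
    T = len(sched)
    cols, names = [], []
    for c in conditions:
        box = np.asarray([1.0 if s == c else 0.0 for s in sched])
        cols.append(np.convolve(box, hrf.kernel)[:T])
        names.append(c)
    names.append("intercept")
    cols.append(np.ones(T))
    x = np.linspace(-1.0, 1.0, T)
    for d in range(1, drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(d)(x))
        names.append(f"drift{d}")
    return DesignMatrix(matrix=np.column_stack(cols), names=names,
                        condition_names=list(conditions))


@dataclass
class GlmFit:
    beta: np.ndarray        # columns x voxels (or columns, for one series)
    sigma2: np.ndarray      # residual variance per voxel
    df: int
    xtx_inv: np.ndarray
    design: DesignMatrix
    ar1_rho: float | None = None

    def stderr(self, c: np.ndarray) -> np.ndarray:
        return np.sqrt(self.sigma2 * float(c @ self.xtx_inv @ c))


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / df
    return beta, sigma2, df, xtx_inv


def fit_glm(y: np.ndarray, X: DesignMatrix | np.ndarray, whitening: str = "none") -> GlmFit:
    """Per-voxel least squares, optional AR(1) prewhitening.

    ``y`` is (T,) or (T, n_voxels).  With ``whitening='ar1'`` the lag-1
    autocorrelation pooled over voxels' OLS residuals defines a single
    prewhitening transform applied to both sides before refitting.
    """
    dm = X if isinstance(X, DesignMatrix) else DesignMatrix(np.asarray(X, float), [f"c{i}" for i in range(np.asarray(X).shape[1])], [])
    Xm = dm.matrix
    Y = np.asarray(y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError("len(y) must equal the design's row count")
    if whitening not in ("none", "ar1"):
        raise ValueError("whitening must be 'none' or 'ar1'")

    beta, sigma2, df, xtx_inv = _ols(Xm, Y)
    rho = None
    if whitening == "ar1":
        resid = Y - Xm @ beta
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid ** 2)
        rho = float(num / den) if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        W_first = np.sqrt(1.0 - rho ** 2)
        Yw = np.vstack([W_first * Y[:1], Y[1:] - rho * Y[:-1]])
        Xw = np.vstack([W_first * Xm[:1], Xm[1:] - rho * Xm[:-1]])
        beta, sigma2, df, xtx_inv = _ols(Xw, Yw)

    if squeeze:
        beta, sigma2 = beta[:, 0], sigma2[0]
    return GlmFit(beta=beta, sigma2=np.atleast_1d(sigma2), df=df, xtx_inv=xtx_inv,
                  design=dm, ar1_rho=rho)


def contrast_t(fit: GlmFit, weights: dict[str, float] | np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Contrast estimate, t statistic, and df for each voxel."""
    c = (fit.design.contrast_vector(weights) if isinstance(weights, dict)
         else np.asarray(weights, dtype=float))
    one_d = fit.beta.ndim == 1
    beta = fit.beta[:, None] if one_d else fit.beta
    est = c @ beta
    se = np.sqrt(fit.sigma2 * float(c @ fit.xtx_inv @ c))
    t = est / se
    if one_d:
        return float(est[0]), float(t[0]), fit.df
    return est, t, fit.df


def roi_contrast_table(
    fits: dict[str, GlmFit],
    weights: dict[str, float],
    roi_masks: dict[str, np.ndarray],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per subject x ROI mean contrast value over the mask voxels."""
    rows = []
    for subject, fit in fits.items():
        est, _t, _df = contrast_t(fit, weights)
        est = np.atleast_1d(est)
        for roi, mask in roi_masks.items():
            rows.append({"subject": subject, "group": groups[subject],
                         "roi": roi, "value": float(np.mean(est[np.asarray(mask)]))})
    return pd.DataFrame(rows)


def contrast_and_group(
    roi_values: pd.DataFrame,
    control_label: str = "control",
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Within- and between-group t-tests on ROI contrast values.

    Input rows: (subject, group, roi, value), optionally a ``condition``
    column for stacked contrasts.  Within each group: one-sample t
    against zero, df = n - 1.  Between groups: two-sample pooled t, df =
    n1 + n2 - 2, signed control-minus-patient.
    """
    keys = ["roi"] + (["condition"] if "condition" in roi_values.columns else [])
    rows = []
    for key, sub in roi_values.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        by_group = {}
        for grp, gsub in sub.groupby("group"):
            vals = gsub["value"].to_numpy(float)
            t, p = stats.ttest_1samp(vals, 0.0)
            rec[f"t_{grp}"] = float(t)
            rec[f"df_{grp}"] = len(vals) - 1
            rec[f"p_{grp}"] = float(p)
            by_group[grp] = vals
        if control_label in by_group and patient_label in by_group:
            a, b = by_group[control_label], by_group[patient_label]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rec["t_between"] = float(t)
            rec["df_between"] = len(a) + len(b) - 2
            rec["p_between"] = float(p)
        rows.append(rec)
    return pd.DataFrame(rows)
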