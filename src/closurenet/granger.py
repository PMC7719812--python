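"""VAR fitting, Geweke influence decomposition, Granger causality maps,
bootstrap+FDR thresholding, and nonparametric group inference.

For two zero-mean series ``x[n]`` and ``y[n]`` modeled jointly as a
VAR(p), the Geweke decomposition of their linear dependence is

* ``F_x->y = ln( var(y | own past) / var(y | both pasts) )`` — the past
  of ``x`` improves the prediction of ``y``;
* ``F_y->x`` — the symmetric counterpart;
* ``F_x.y  = ln( var(x|pasts) * var(y|pasts) / det Sigma_joint )`` — the
  undirected instantaneous influence;
* ``F_x,y  = F_x->y + F_y->x + F_x.y`` — total linear dependence, an
  exact identity when every term comes from the same fits.

Residual variances inside the decomposition use the maximum-likelihood
normalization (divide by the number of regression rows): restricted and
full models then share a denominator, so nested least squares makes each
directed term nonnegative by construction and the instantaneous term
nonnegative by the Cauchy–Schwarz inequality.

A Granger causality map (GCM) takes the mean time course of a reference
ROI as ``x`` and every voxel as ``y``; the difference map (dGCM) stores
``F_x->y - F_y->x`` per voxel, positive when influence flows from the
ROI to the voxel.  Map thresholds come from circularly time-shifted
surrogates of the reference series (autocorrelation preserved, cross-
dependence destroyed) pooled across voxels into one empirical null,
followed by Benjamini–Hochberg FDR.  Group-level GCIs are summarized by
median and IQR and tested with Wilcoxon signed-rank (within group,
median vs. zero) and rank-sum (between groups) statistics.

Coefficient matrices are stored in the minus-sign convention
``x[n] = -sum_i A[i] x[n-i] + u[n]``; ``VarModel.a_effective`` gives the
conventional regression form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from closurenet.design import SessionDesign

__all__ = [
    "VarModel",
    "GciResult",
    "DGcmMap",
    "fit_var",
    "select_var_order",
    "geweke_measures",
    "compute_dgcm",
    "threshold_map",
    "condition_segments",
    "signed_rank_test",
    "group_gci_stats",
    "pairwise_gci_table",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VAR fitting

@dataclass
class VarModel:
    """A fitted VAR(p) in the minus-sign storage convention."""

    order: int
    a_minus: list[np.ndarray]       # A[i], x[n] = -sum A[i] x[n-i] + u[n]
    sigma_u: np.ndarray             # innovation covariance (df-corrected)
    n_obs: int
    residuals: np.ndarray           # rows aligned with the regression targets
    mean: np.ndarray                # subtracted before fitting

    @property
    def a_effective(self) -> list[np.ndarray]:
        """Conventional regression matrices (``-A[i]``)."""
        return [-a for a in self.a_minus]

    def coef_se(self) -> list[np.ndarray]:
        """Asymptotic standard errors per coefficient matrix."""
        return self._se

    _se: list[np.ndarray] = field(default_factory=list, repr=False)


def _lag_rows(n: int, p: int, segments: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Target indices and their p lag indices, never crossing a segment
    boundary."""
    tgts, lags = [], []
    for start, stop in segments:
        for t in range(start + p, stop):
            tgts.append(t)
            lags.append([t - 1 - j for j in range(p)])
    if not tgts:
        raise ValueError("no usable rows: every segment shorter than p + 1")
    return np.asarray(tgts), np.asarray(lags)


def fit_var(series: np.ndarray, p: int, segments: list[tuple[int, int]] | None = None) -> VarModel:
    """Per-equation least-squares VAR(p) fit on a demeaned series.

    ``series`` is (n, k).  Requires ``n > p * k + 1`` rows; the
    innovation covariance uses the degrees-of-freedom correction
    ``n_rows - p * k``.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    needed = p * k + 2
    if n < needed:
        raise ValueError(f"series too short: need at least {needed} observations for p={p}, k={k}")
    mean = X.mean(axis=0)
    Xd = X - mean
    segments = segments or [(0, n)]
    tgt, lag = _lag_rows(n, p, segments)
    Y = Xd[tgt]                                   # (m, k)
    Z = Xd[lag].reshape(len(tgt), p * k)          # lag 1 block first
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)     # (p*k, k)
    resid = Y - Z @ B
    m = len(tgt)
    dof = m - p * k
    if dof < 1:
        raise ValueError("not enough rows for the df-corrected covariance")
    sigma_u = resid.T @ resid / dof
    a_eff = [B[i * k:(i + 1) * k].T for i in range(p)]
    # standard errors: sigma_jj * diag((Z'Z)^-1)
    ztz_inv = np.linalg.inv(Z.T @ Z)
    se_flat = np.sqrt(np.outer(np.diag(ztz_inv), np.diag(sigma_u)))  # (p*k, k)
    se = [se_flat[i * k:(i + 1) * k].T for i in range(p)]
    model = VarModel(order=p, a_minus=[-a for a in a_eff], sigma_u=sigma_u,
                     n_obs=n, residuals=resid, mean=mean)
    model._se = se
    return model


def select_var_order(series: np.ndarray, max_p: int = 8, criterion: str = "bic") -> int:
    """Information-criterion VAR order selection (logged)."""
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    best_p, best_ic = 1, np.inf
    for p in range(1, max_p + 1):
        if n <= p * k + 2:
            break
        model = fit_var(X, p)
        m = len(model.residuals)
        sigma_ml = model.residuals.T @ model.residuals / m
        sign, logdet = np.linalg.slogdet(sigma_ml)
        n_par = p * k * k
        if criterion == "bic":
            ic = logdet + n_par * np.log(m) / m
        elif criterion == "aic":
            ic = logdet + 2 * n_par / m
        else:
            raise ValueError("criterion must be 'bic' or 'aic'")
        if ic < best_ic:
            best_p, best_ic = p, ic
    logger.info("selected VAR order p=%d by %s", best_p, criterion)
    return best_p


# ---------------------------------------------------------------------------
# Geweke measures

@dataclass(frozen=True)
class GciResult:
    f_x_to_y: float
    f_y_to_x: float
    f_instantaneous: float
    f_total: float
    p: int
    n: int

    @property
    def dgci(self) -> float:
        """Influence difference F_x->y - F_y->x."""
        return self.f_x_to_y - self.f_y_to_x


def _normalize_segments(A: np.ndarray, segments: list[tuple[int, int]]) -> np.ndarray:
    """Demean and variance-normalize each segment of each series."""
    out = np.array(A, dtype=float, copy=True)
    for start, stop in segments:
        seg = out[start:stop]
        seg -= seg.mean(axis=0)
        sd = seg.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        seg /= sd
        out[start:stop] = seg
    return out


class _PairEngine:
    """Batched ROI-vs-voxel Geweke computation.

    Voxel-side lag moments are precomputed once, so recomputing the map
    for surrogate (time-shifted) reference series costs only the
    reference-side and cross moments.
    """

    def __init__(self, Y: np.ndarray, p: int, segments: list[tuple[int, int]]):
        T = Y.shape[0]
        self.p = p
        self.segments = segments
        self.T = T
        Yn = _normalize_segments(Y, segments)
        tgt, lag = _lag_rows(T, p, segments)
        self.tgt, self.lag = tgt, lag
        self.m = len(tgt)
        if self.m <= 2 * p + 1:
            raise ValueError(f"need more than {2 * p + 1} usable rows, got {self.m}")
        self.YT = Yn[tgt]                                # (m, V)
        self.YL = Yn[lag].transpose(0, 2, 1)             # (m, V, p)
        self.Syy_ll = np.einsum("nvp,nvq->vpq", self.YL, self.YL)
        self.Syt_l = np.einsum("nvp,nv->vp", self.YL, self.YT)
        self.Syy_tt = np.einsum("nv,nv->v", self.YT, self.YT)
        # restricted voxel model: y on its own past
        w = np.linalg.solve(self.Syy_ll, self.Syt_l[..., None])[..., 0]
        rss = self.Syy_tt - np.einsum("vp,vp->v", self.Syt_l, w)
        self.tau1 = rss / self.m

    def measures(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(F_x->y, F_y->x, F_x.y) per voxel for reference series ``x``."""
        p, m = self.p, self.m
        xn = _normalize_segments(x[:, None], self.segments)[:, 0]
        xt = xn[self.tgt]                                # (m,)
        XL = xn[self.lag]                                # (m, p)
        Sxx_ll = XL.T @ XL
        Sxt_l = XL.T @ xt
        Sxx_tt = float(xt @ xt)
        sigma1 = (Sxx_tt - Sxt_l @ np.linalg.solve(Sxx_ll, Sxt_l)) / m

        C_xl_yl = np.einsum("np,nvq->vpq", XL, self.YL)  # (V, p, p)
        C_xl_yt = (XL.T @ self.YT).T                     # (V, p)
        C_yl_xt = np.einsum("nvp,n->vp", self.YL, xt)    # (V, p)
        C_xt_yt = xt @ self.YT                           # (V,)

        V = self.YT.shape[1]
        G = np.empty((V, 2 * p, 2 * p))
        G[:, :p, :p] = Sxx_ll
        G[:, :p, p:] = C_xl_yl
        G[:, p:, :p] = C_xl_yl.transpose(0, 2, 1)
        G[:, p:, p:] = self.Syy_ll
        R = np.empty((V, 2 * p, 2))
        R[:, :p, 0] = Sxt_l
        R[:, p:, 0] = C_yl_xt
        R[:, :p, 1] = C_xl_yt
        R[:, p:, 1] = self.Syt_l
        W = np.linalg.solve(G, R)                        # (V, 2p, 2)
        Tm = np.empty((V, 2, 2))
        Tm[:, 0, 0] = Sxx_tt
        Tm[:, 0, 1] = Tm[:, 1, 0] = C_xt_yt
        Tm[:, 1, 1] = self.Syy_tt
        E = Tm - np.einsum("vpi,vpj->vij", R, W)
        Sig = E / m
        sigma2 = Sig[:, 0, 0]
        tau2 = Sig[:, 1, 1]
        det = sigma2 * tau2 - Sig[:, 0, 1] ** 2
        if np.any(sigma2 <= 0) or np.any(tau2 <= 0) or np.any(det <= 0) or sigma1 <= 0 or np.any(self.tau1 <= 0):
            raise np.linalg.LinAlgError(
                "singular residual covariance in Geweke computation; "
                "the series are (near-)deterministically related and no "
                "regularization is applied by design")
        f_x2y = np.log(self.tau1 / tau2)
        f_y2x = np.log(sigma1 / sigma2)
        f_inst = np.log(sigma2 * tau2 / det)
        return f_x2y, f_y2x, f_inst


def geweke_measures(
    x: np.ndarray,
    y: np.ndarray,
    p: int = 1,
    segments: list[tuple[int, int]] | None = None,
) -> GciResult:
    """Geweke influence decomposition for a pair of series.

    Returns directed terms, the instantaneous term, and their sum (the
    total linear dependence); the additivity identity is exact because
    every term comes from the same restricted/joint fits.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) <= 3 * p + 3:
        raise ValueError(f"need more than {3 * p + 3} samples for p={p}")
    segments = segments or [(0, len(x))]
    # canonicalize the internal pair order so that swapping the arguments
    # swaps the directed components bit-exactly
    if x.tobytes() > y.tobytes():
        engine = _PairEngine(x[:, None], p, segments)
        f_y2x, f_x2y, f_inst = engine.measures(y)
    else:
        engine = _PairEngine(y[:, None], p, segments)
        f_x2y, f_y2x, f_inst = engine.measures(x)
    return GciResult(
        f_x_to_y=float(f_x2y[0]),
        f_y_to_x=float(f_y2x[0]),
        f_instantaneous=float(f_inst[0]),
        f_total=float(f_x2y[0] + f_y2x[0] + f_inst[0]),
        p=p,
        n=engine.m,
    )


# ---------------------------------------------------------------------------
# maps

@dataclass
class DGcmMap:
    """Voxelwise influence-difference map referenced to one ROI."""

    dgci: np.ndarray                 # F_ref->vox - F_vox->ref, per voxel
    f_instantaneous: np.ndarray
    f_ref_to_vox: np.ndarray
    f_vox_to_ref: np.ndarray
    ref_flag: np.ndarray             # True where the voxel is inside the ROI
    p: int
    n_used: int
    spatial_shape: tuple[int, ...] | None = None
    pvals: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    threshold_meta: dict = field(default_factory=dict)
    _engine: "_PairEngine | None" = field(default=None, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)


def condition_segments(design: SessionDesign, condition: str, p: int) -> list[tuple[int, int]]:
    """TR intervals of one condition's runs, each with ``p`` lead-in TRs.

    Lagged pairs never cross a segment boundary, so restricting the map
    to these segments yields a condition-specific GCM.
    """
    runs = design.onsets()
    runs = runs[runs.condition == condition]
    if runs.empty:
        raise ValueError(f"condition {condition!r} absent from schedule")
    return [(max(0, int(r.onset_tr) - p), int(r.onset_tr) + int(r.duration_tr))
            for r in runs.itertuples()]


def _as_series(volume: np.ndarray) -> tuple[np.ndarray, tuple[int, ...] | None]:
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:
        X, Y, Z, T = vol.shape
        return vol.reshape(X * Y * Z, T).T, (X, Y, Z)
    if vol.ndim == 2:
        return vol, None
    raise ValueError("volume must be 4-D (x, y, z, t) or 2-D (t, voxels)")


def compute_dgcm(
    reference_roi: np.ndarray,
    volume: np.ndarray,
    p: int = 1,
    segments: list[tuple[int, int]] | None = None,
) -> DGcmMap:
    """Unthresholded difference-GCM for one reference ROI.

    ``x`` is the mean raw time course of the mask voxels; for every voxel
    ``y`` the three Geweke measures are computed on the (per-segment
    normalized) series, with lagged pairs spanning segment boundaries
    excluded.  Voxels inside the reference mask are flagged, not
    silently dropped.
    """
    series, shape = _as_series(volume)
    T, V = series.shape
    mask = np.asarray(reference_roi, dtype=int).ravel()
    if mask.size == 0:
        raise ValueError("reference mask is empty")
    segments = list(segments) if segments is not None else [(0, T)]
    kept = []
    for start, stop in sorted(segments):
        if kept and start < kept[-1][1]:
            raise ValueError("segments must be nonoverlapping")
        if stop - start < p + 2:
            warnings.warn(f"segment ({start}, {stop}) shorter than p + 2; skipped")
            continue
        kept.append((start, stop))
    if not kept:
        raise ValueError("no usable segments")
    x = series[:, mask].mean(axis=1)
    flag = np.zeros(V, dtype=bool)
    flag[mask] = True
    # reference-mask voxels are flagged and excluded from the pair fits:
    # a voxel (near-)identical to the ROI mean makes the joint residual
    # covariance singular
    outside = np.flatnonzero(~flag)
    engine = _PairEngine(series[:, outside], p, kept)
    f_x2y, f_y2x, f_inst = engine.measures(x)

    def _expand(vals: np.ndarray) -> np.ndarray:
        full = np.full(V, np.nan)
        full[outside] = vals
        return full

    return DGcmMap(
        dgci=_expand(f_x2y - f_y2x),
        f_instantaneous=_expand(f_inst),
        f_ref_to_vox=_expand(f_x2y),
        f_vox_to_ref=_expand(f_y2x),
        ref_flag=flag,
        p=p,
        n_used=engine.m,
        spatial_shape=shape,
        _engine=engine,
        _x=x,
    )


def threshold_map(dmap: DGcmMap, B: int, q: float = 0.05, seed: int = 0) -> DGcmMap:
    """Bootstrap+FDR significance mask for a difference-GCM.

    The null distribution is built by recomputing the map on ``B``
    circularly time-shifted surrogates of the reference series (shift
    drawn uniformly from ``p+1 .. T-p-1``), pooling the surrogate dGCI
    values across voxels into one empirical null.  Per-voxel two-sided
    p-values against that null are thresholded with Benjamini–Hochberg
    at level ``q``.  The input map is returned with ``pvals``,
    ``sig_mask`` and threshold metadata filled in.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if 1.0 / B > q:
        raise ValueError(f"B={B} too small to resolve q={q} (1/B > q)")
    if dmap._engine is None or dmap._x is None:
        raise ValueError("map does not carry its source series; recompute with compute_dgcm")
    engine, x = dmap._engine, dmap._x
    T = engine.T
    p = dmap.p
    rng = np.random.default_rng(seed)
    lo, hi = p + 1, T - p
    if hi <= lo:
        raise ValueError("series too short for circular-shift surrogates")
    outside = np.flatnonzero(~dmap.ref_flag)
    null = np.empty((B, len(outside)))
    for b in range(B):
        shift = int(rng.integers(lo, hi))
        f_x2y, f_y2x, _ = engine.measures(np.roll(x, shift))
        null[b] = f_x2y - f_y2x
    flat = np.sort(np.abs(null.ravel()))
    n_null = flat.size
    # two-sided p against the null pooled across voxels
    obs = dmap.dgci[outside]
    counts = n_null - np.searchsorted(flat, np.abs(obs), side="left")
    pv = (1.0 + counts) / (n_null + 1.0)
    reject = multipletests(pv, alpha=q, method="fdr_bh")[0]
    dmap.pvals = np.full(len(dmap.dgci), np.nan)
    dmap.pvals[outside] = pv
    dmap.sig_mask = np.zeros(len(dmap.dgci), dtype=bool)
    dmap.sig_mask[outside] = reject
    dmap.threshold_meta = {"B": B, "q": q, "seed": int(seed),
                           "null_size": int(n_null), "scheme": "circular-shift, pooled null"}
    return dmap


# ---------------------------------------------------------------------------
# group inference

def signed_rank_test(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for median vs. zero.

    Exact when n <= 25 with no zeros and no tied magnitudes; otherwise
    the normal approximation with Pratt zero handling and continuity
    correction.  All-zero input is undefined (NaN).
    """
    v = np.asarray(values, dtype=float)
    nz = v[v != 0]
    if nz.size == 0:
        return float("nan")
    mags = np.abs(v)
    exact_ok = (v.size <= 25 and nz.size == v.size
                and np.unique(mags).size == mags.size)
    if exact_ok:
        res = stats.wilcoxon(v, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(v, alternative="two-sided", zero_method="pratt",
                             method="approx", correction=True)
    return float(res.pvalue)


def group_gci_stats(gci_table: pd.DataFrame, min_per_group: int = 5) -> pd.DataFrame:
    """Median/IQR and Wilcoxon tests for subject-level GCIs.

    Input rows: (subject, group, connection, value).  Output: one row per
    connection x group with the group's median, IQR, and signed-rank p
    (median vs. zero), plus the connection's between-group rank-sum p
    repeated on each row.
    """
    rows = []
    for conn, sub in gci_table.groupby("connection"):
        by_group = {g: s["value"].to_numpy(float) for g, s in sub.groupby("group")}
        for g, vals in by_group.items():
            if len(vals) < min_per_group:
                raise ValueError(f"group {g!r} has fewer than {min_per_group} subjects")
        groups = sorted(by_group)
        p_rs = float("nan")
        if len(groups) == 2:
            p_rs = float(stats.ranksums(by_group[groups[0]], by_group[groups[1]]).pvalue)
        for g in groups:
            vals = by_group[g]
            rows.append({
                "connection": conn,
                "group": g,
                "n": len(vals),
                "median": float(np.median(vals)),
                "iqr": float(stats.iqr(vals)),
                "p_signed_rank": signed_rank_test(vals),
                "p_rank_sum": p_rs,
            })
    return pd.DataFrame(rows)


def pairwise_gci_table(
    roi_series: pd.DataFrame,
    p: int = 1,
    segments: list[tuple[int, int]] | None = None,
    subject: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Subject-level directed-influence table over all ROI pairs.

    One row per ordered pair (source -> target) with the dGCI value
    (``F_src->dst - F_dst->src``) and the raw directed measures.
    """
    cols = list(roi_series.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = geweke_measures(roi_series[a].to_numpy(), roi_series[b].to_numpy(),
                                  p=p, segments=segments)
            rows.append({"subject": subject, "group": group,
                         "connection": f"{a}->{b}", "value": res.dgci,
                         "f_forward": res.f_x_to_y, "f_backward": res.f_y_to_x,
                         "f_instantaneous": res.f_instantaneous})
            rows.append({"subject": subject, "group": group,
                         "connection": f"{b}->{a}", "value": -res.dgci,
                         "f_forward": res.f_y_to_x, "f_backward": res.f_x_to_y,
                         "f_instantaneous": res.f_instantaneous})
    return pd.DataFrame(rows)
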