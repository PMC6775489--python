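"""PCA and two-class OPLS-DA on layer-resolved spectra.

OPLS-DA separates between-class (predictive) from class-uncorrelated
(orthogonal) variation. The predictive weight comes from the X-y
covariance; each orthogonal component is the part of the corresponding
X-loading orthogonal to the predictive weight, deflated from X before the
final predictive fit. Diagnostics follow chemometrics convention: R2X(cum)
and R2Y(cum) are fractions of X and y sum of squares modeled, Q2(cum) is
the cross-validated R2Y from deterministic interleaved ("venetian blind")
folds. Spectra are mean-centered only; no unit-variance scaling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats


@dataclass
class PCAModel:
    n_components: int
    scores: np.ndarray  # (n, a)
    loadings: np.ndarray  # (m, a), orthonormal columns
    r2x: np.ndarray  # per component
    r2x_cum: float
    mean: np.ndarray


def pca_fit(x: np.ndarray, n_components: int = 2) -> PCAModel:
    """PCA by SVD of the column-centered matrix; R2X_a = sigma_a^2 / sum sigma^2."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    a = min(n_components, sv.size)
    total = np.sum(sv**2)
    r2x = (sv[:a] ** 2) / total if total > 0 else np.zeros(a)
    scores = u[:, :a] * sv[:a]
    return PCAModel(n_components=a, scores=scores, loadings=vt[:a].T,
                    r2x=r2x, r2x_cum=float(r2x.sum()), mean=mean)


@dataclass
class OPLSModel:
    t_pred: np.ndarray  # (n,) predictive score
    p_pred: np.ndarray  # (m,) predictive loading
    w_pred: np.ndarray  # (m,) predictive weight
    c_pred: float  # y-loading
    t_orth: np.ndarray  # (n, n_orth)
    p_orth: np.ndarray  # (m, n_orth)
    w_orth: np.ndarray  # (m, n_orth)
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    x_mean: np.ndarray
    y_mean: float
    classes: tuple = (0, 1)

    @property
    def n_orth(self) -> int:
        return self.t_orth.shape[1]


def _opls_core(xc: np.ndarray, yc: np.ndarray, n_orth: int):
    """Orthogonal-signal-correction decomposition on centered data."""
    w = xc.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y carries no covariance with X")
    w = w / nw
    t_orth_list, p_orth_list, w_orth_list = [], [], []
    x_work = xc
    for _ in range(n_orth):
        t = x_work @ w
        p = x_work.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o = w_o / n_o
        t_o = x_work @ w_o
        p_o = x_work.T @ t_o / (t_o @ t_o)
        x_work = x_work - np.outer(t_o, p_o)
        t_orth_list.append(t_o)
        p_orth_list.append(p_o)
        w_orth_list.append(w_o)
    t = x_work @ w
    p = x_work.T @ t / (t @ t)
    c = (yc @ t) / (t @ t)
    t_orth = np.column_stack(t_orth_list) if t_orth_list else np.empty((xc.shape[0], 0))
    p_orth = np.column_stack(p_orth_list) if p_orth_list else np.empty((xc.shape[1], 0))
    w_orth = np.column_stack(w_orth_list) if w_orth_list else np.empty((xc.shape[1], 0))
    return w, t, p, c, t_orth, p_orth, w_orth


def _opls_predict(x_new_c: np.ndarray, w, c, w_orth, p_orth) -> np.ndarray:
    """Predict centered y for centered new rows, removing orthogonal parts."""
    xw = x_new_c.copy()
    for j in range(w_orth.shape[1]):
        t_o = xw @ w_orth[:, j]
        xw = xw - np.outer(t_o, p_orth[:, j])
    return (xw @ w) * c


def opls_da_fit(x: np.ndarray, y: np.ndarray, n_orth: int = 2,
                cv_folds: int = 7) -> OPLSModel:
    """Fit a 1 + n_orth component OPLS-DA model on a two-class problem.

    ``y`` holds exactly two distinct class labels; they are coded 0/1 and
    centered. Q2 uses interleaved folds assigned by row index (row i goes
    to fold i mod cv_folds), refitting the full model on each training
    split.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(np.unique(y).tolist())))
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    if x.shape[0] < cv_folds:
        raise ValueError("need at least cv_folds observations")
    y01 = np.asarray([classes.index(v) for v in y], dtype=float)

    x_mean = x.mean(axis=0)
    y_mean = float(y01.mean())
    xc = x - x_mean
    yc = y01 - y_mean
    n, m = xc.shape
    if np.linalg.norm(xc.T @ yc) < 1e-12 * max(np.linalg.norm(xc), 1.0):
        # X carries no class-correlated variation: degenerate null model
        return OPLSModel(t_pred=np.zeros(n), p_pred=np.zeros(m),
                         w_pred=np.zeros(m), c_pred=0.0,
                         t_orth=np.empty((n, 0)), p_orth=np.empty((m, 0)),
                         w_orth=np.empty((m, 0)), r2x_cum=0.0, r2y_cum=0.0,
                         q2_cum=0.0, x_mean=x_mean, y_mean=y_mean,
                         classes=classes)
    w, t, p, c, t_orth, p_orth, w_orth = _opls_core(xc, yc, n_orth)

    ssy = float(yc @ yc)
    r2y = 1.0 - float(np.sum((yc - t * c) ** 2)) / ssy if ssy else 0.0
    ssx = float(np.sum(xc**2))
    modeled = float(np.sum(np.outer(t, p) ** 2))
    if t_orth.size:
        modeled += float(np.sum((t_orth @ p_orth.T) ** 2))
    r2x = modeled / ssx if ssx else 0.0

    press = 0.0
    for fold in range(cv_folds):
        test = np.arange(x.shape[0]) % cv_folds == fold
        train = ~test
        if len(set(y01[train])) < 2:
            raise ValueError("a CV fold lost one class; reduce cv_folds")
        xm = x[train].mean(axis=0)
        ym = y01[train].mean()
        wf, tf, pf, cf, tof, pof, wof = _opls_core(
            x[train] - xm, y01[train] - ym, n_orth)
        pred = _opls_predict(x[test] - xm, wf, cf, wof, pof) + ym
        press += float(np.sum((y01[test] - pred) ** 2))
    q2 = 1.0 - press / ssy if ssy else 0.0

    return OPLSModel(t_pred=t, p_pred=p, w_pred=w, c_pred=float(c),
                     t_orth=t_orth, p_orth=p_orth, w_orth=w_orth,
                     r2x_cum=float(r2x), r2y_cum=float(r2y), q2_cum=float(q2),
                     x_mean=x_mean, y_mean=y_mean, classes=classes)


def correlation_scaled_loadings(model: OPLSModel, x: np.ndarray) -> np.ndarray:
    """p(corr): Pearson correlation of each X column with the predictive score.

    Columns with zero variance get p(corr) = 0.
    """
    x = np.asarray(x, dtype=float)
    t = model.t_pred
    tc = t - t.mean()
    xc = x - x.mean(axis=0)
    num = xc.T @ tc
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(tc)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcorr = np.where(denom > 0, num / denom, 0.0)
    return np.clip(pcorr, -1.0, 1.0)


@dataclass
class HotellingEllipse:
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,)
    orientation_deg: float
    alpha: float
    stable: bool = True


def hotelling_ellipse(scores: np.ndarray, alpha: float = 0.05) -> HotellingEllipse:
    """Hotelling T^2 confidence ellipse on a two-column score matrix.

    T2_crit = 2 (n - 1) / (n - 2) * F(1 - alpha; 2, n - 2); semi-axes are
    sqrt(T2_crit * eigenvalue) along the covariance eigenvectors. Flagged
    unstable for n = 3 (a single denominator degree of freedom).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    n = scores.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    t2_crit = 2.0 * (n - 1) / (n - 2) * scipy.stats.f.ppf(1 - alpha, 2, n - 2)
    semi = np.sqrt(np.clip(evals, 0, None) * t2_crit)
    orient = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
    return HotellingEllipse(center=center, semi_axes=semi,
                            orientation_deg=orient, alpha=alpha,
                            stable=n > 3)


def hotelling_contains(ellipse: HotellingEllipse, scores: np.ndarray) -> np.ndarray:
    """Boolean mask of score rows inside the ellipse (T^2 <= critical)."""
    scores = np.asarray(scores, dtype=float)
    d = scores - ellipse.center
    th = math.radians(ellipse.orientation_deg)
    rot = np.array([[math.cos(th), math.sin(th)],
                    [-math.sin(th), math.cos(th)]])
    local = d @ rot.T
    return (local[:, 0] / ellipse.semi_axes[0]) ** 2 \
        + (local[:, 1] / ellipse.semi_axes[1]) ** 2 <= 1.0
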