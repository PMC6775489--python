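"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factorizes a preprocessed spectral map D (n voxels x m channels) into
non-negative concentrations C (n x k) and non-negative component spectra
S (k x m), D ~= C @ S, using exact non-negative least-squares subproblems
(active set) so the lack of fit is non-increasing across iterations. Only
non-negativity constraints are applied in both directions; resolved
spectra are re-normalized to unit area each cycle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

log = logging.getLogger(__name__)


@dataclass
class MCRModel:
    spectra: np.ndarray  # (k, m), rows area-normalized
    concentrations: np.ndarray  # (n, k)
    wavenumbers: np.ndarray
    lof_percent: float
    explained_variance_percent: float
    iterations: int
    converged: bool
    lof_trace: list[float] = field(default_factory=list)
    component_names: list[str] | None = None

    @property
    def k(self) -> int:
        return self.spectra.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.concentrations @ self.spectra


def svd_rank_screen(data: np.ndarray, max_k: int = 10,
                    var_threshold: float = 0.99,
                    gap_factor: float = 1.5) -> tuple[np.ndarray, int]:
    """Leading singular values and a suggested component count.

    k combines two criteria: the smallest count whose cumulative
    squared-singular-value fraction reaches ``var_threshold``, extended
    while consecutive singular values stay separated by more than
    ``gap_factor`` (components clearly above the flat noise floor carry
    structure even when their variance share is small).
    """
    data = np.asarray(data, dtype=float)
    if not np.any(data):
        raise ValueError("all-zero matrix has no meaningful rank")
    sv_all = np.linalg.svd(data, compute_uv=False)
    frac = np.cumsum(sv_all**2) / np.sum(sv_all**2)
    k_var = int(np.searchsorted(frac, var_threshold) + 1)
    k_gap = 1
    tiny = 1e-12 * sv_all[0]
    for i in range(min(max_k, sv_all.size - 1)):
        if sv_all[i + 1] <= tiny:  # numerically zero: exact rank reached
            if sv_all[i] > tiny:
                k_gap = i + 1
            break
        if sv_all[i] > gap_factor * sv_all[i + 1]:
            k_gap = i + 1
    k = min(max(k_var, k_gap), max_k)
    return sv_all[:max_k], k


def lack_of_fit(c: np.ndarray, s: np.ndarray, data: np.ndarray) -> float:
    """Percent lack of fit: 100 * sqrt(sum((D - C S)^2) / sum(D^2))."""
    resid = data - c @ s
    denom = np.sum(data**2)
    if denom == 0:
        return 0.0
    return 100.0 * float(np.sqrt(np.sum(resid**2) / denom))


def purest_spectra_init(data: np.ndarray, k: int) -> np.ndarray:
    """Pick k mutually most-independent voxel spectra as initial estimates.

    Successive-projection selection: start from the largest-norm spectrum,
    then repeatedly add the spectrum with the largest residual after
    projection onto the span of those already chosen. A simple stand-in for
    purest-variable (SIMPLISMA-type) selection that is exact on noiseless
    mixtures with pure voxels present.
    """
    x = np.asarray(data, dtype=float)
    chosen: list[int] = []
    resid = x.copy()
    for _ in range(k):
        norms = np.linalg.norm(resid, axis=1)
        idx = int(np.argmax(norms))
        if norms[idx] <= 1e-12:
            raise ValueError("data rank below requested k; cannot seed")
        chosen.append(idx)
        v = resid[idx] / norms[idx]
        resid = resid - np.outer(resid @ v, v)
    s0 = np.clip(x[chosen], 0.0, None)
    return s0


def _nnls_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve min ||a @ x_j - b[:, j]|| s.t. x_j >= 0 for every column j."""
    out = np.empty((a.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        out[:, j], _ = scipy.optimize.nnls(a, b[:, j])
    return out


def _normalize_rows(s: np.ndarray, grid: np.ndarray,
                    c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each spectrum to unit area, moving the scale into C (C@S fixed)."""
    s = s.copy()
    c = c.copy()
    for i in range(s.shape[0]):
        area = np.trapezoid(s[i], grid)
        if area > 1e-300:
            s[i] /= area
            c[:, i] *= area
    return s, c


def mcr_als_fit(data: np.ndarray, wavenumbers: np.ndarray, k: int = 4,
                init: np.ndarray | str = "purest", max_iter: int = 500,
                tol: float = 1e-8,
                component_names: list[str] | None = None) -> MCRModel:
    """Alternating non-negative least squares unmixing.

    ``init`` is either "purest" or a (k, m) non-negative matrix of initial
    spectral estimates (e.g. components resolved from another tissue).
    Iterates C-given-S / S-given-C exact NNLS updates until the relative
    lack-of-fit change drops below ``tol`` or ``max_iter`` is reached. On
    exit, components are ordered by match to the initial estimates when
    given, else by descending total concentration.
    """
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    if k > min(n, m):
        raise ValueError("k exceeds matrix rank bound")
    if isinstance(init, str):
        if init != "purest":
            raise ValueError("init must be 'purest' or an array")
        s = purest_spectra_init(data, k)
        match_to_init = False
        init_ref = None
    else:
        s = np.asarray(init, dtype=float).copy()
        if s.shape != (k, m):
            raise ValueError("init spectra must be (k, m)")
        if np.any(s < 0):
            raise ValueError("init spectra must be non-negative")
        match_to_init = True
        init_ref = s.copy()

    lof_trace: list[float] = []
    prev = np.inf
    converged = False
    c = np.zeros((n, k))
    it = 0
    for it in range(1, max_iter + 1):
        c = _nnls_rows(s.T, data.T).T  # rows of C
        s = _nnls_rows(c, data)  # rows of S
        cur = lack_of_fit(c, s, data)
        lof_trace.append(cur)
        if cur <= 1e-9 or (
                prev < np.inf and abs(prev - cur) <= tol * max(prev, 1e-12)):
            converged = True
            break
        prev = cur
    if not converged:
        log.warning("MCR-ALS did not converge in %d iterations (LOF %.3g%%)",
                    max_iter, lof_trace[-1] if lof_trace else float("nan"))

    s, c = _normalize_rows(s, wavenumbers, c)
    # resolve permutation ambiguity
    if match_to_init and init_ref is not None:
        order = match_components(s, init_ref)
    else:
        order = np.argsort(-c.sum(axis=0))
    s, c = s[order], c[:, order]
    names = None
    if component_names is not None:
        names = list(component_names)

    denom = np.sum(data**2)
    resid = data - c @ s
    ev = 100.0 * (1.0 - np.sum(resid**2) / denom) if denom else 100.0
    return MCRModel(spectra=s, concentrations=c, wavenumbers=np.asarray(wavenumbers),
                    lof_percent=lack_of_fit(c, s, data),
                    explained_variance_percent=float(ev), iterations=it,
                    converged=converged, lof_trace=lof_trace,
                    component_names=names)


def match_components(s: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Greedy cosine matching of resolved spectra to reference spectra."""
    k = s.shape[0]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ni, nj = np.linalg.norm(ref[i]), np.linalg.norm(s[j])
            sim[i, j] = (ref[i] @ s[j]) / (ni * nj) if ni and nj else 0.0
    order = np.full(k, -1)
    used = set()
    for i in np.argsort(-sim.max(axis=1)):
        j_best = max((j for j in range(k) if j not in used),
                     key=lambda j: sim[i, j])
        order[i] = j_best
        used.add(j_best)
    return order
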