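"""Lung texture pattern (LTP) learning.

Initial LTPs are chi-square k-means clusters of the texture histograms.
Spatial augmentation then iterates relabeling / centroid updates under the
mixed chi2-l2 cost

    chi2(FT_x, FT_k) + lambda * W * ||FS_x - FS_k||^2

with an infinite textural penalty barring assignment to any LTP whose 95th
percentile intra-cluster texture distance the ROI exceeds (texture-only
argmin as fallback when every LTP is barred).  W scales spatial against
textural scatter so lambda can be tuned on [0, 2]; lambda is set to the
largest grid value whose relative texture-homogeneity loss Delta-SSW_T
stays below the tolerance L_T (1% by default).

Centroids are arithmetic means of member histograms.  The mean is not the
exact chi-square minimizer, so the iteration stops at the best iterate once
the objective stalls; the recorded objective trace is then non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chi-square distances

def chi2_distance(p: np.ndarray, q: np.ndarray) -> float:
    """0.5 * sum_b (p_b - q_b)^2 / (p_b + q_b), empty bins contributing 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("histogram entries must be non-negative")
    s = p + q
    d = np.zeros_like(s)
    nz = s > 0
    d[nz] = (p[nz] - q[nz]) ** 2 / s[nz]
    return 0.5 * float(d.sum())


def chi2_cdist(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise chi-square distances between rows of P (n, B) and Q (m, B)."""
    P = np.asarray(P, dtype=float)[:, None, :]
    Q = np.asarray(Q, dtype=float)[None, :, :]
    s = P + Q
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(s > 0, (P - Q) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return 0.5 * d.sum(axis=2)


def _mean_centroids(F: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cent = np.zeros((k, F.shape[1]))
    for j in range(k):
        members = labels == j
        if members.any():
            cent[j] = F[members].mean(axis=0)
    return cent


# ---------------------------------------------------------------------------
# model container

@dataclass
class LtpModel:
    """Texture+spatial centroid pairs with assignments and tuning parameters."""

    ft_centroids: np.ndarray      # (K, B_T)
    fs_centroids: np.ndarray      # (K, B_S)
    labels: np.ndarray            # (n,) LTP index per training ROI
    lam: float = 0.0
    w: float = 1.0
    penalty: bool = True          # gamma = infinity textural penalty on/off
    p95: np.ndarray = field(default=None)       # (K,) admissibility thresholds
    max_intra: np.ndarray = field(default=None)  # (K,) max intra-cluster chi2
    ssw_t: float = 0.0
    objective_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.ft_centroids.shape[0]

    def member_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == j) for j in range(self.k)]


def _cluster_stats(FT: np.ndarray, labels: np.ndarray, cent: np.ndarray):
    """Per-cluster P95 and max intra-cluster chi2 texture distances and SSW_T."""
    k = cent.shape[0]
    p95 = np.zeros(k)
    max_intra = np.zeros(k)
    ssw = 0.0
    for j in range(k):
        members = np.flatnonzero(labels == j)
        if members.size == 0:
            continue
        d = chi2_cdist(FT[members], cent[j:j + 1])[:, 0]
        p95[j] = np.percentile(d, 95)
        max_intra[j] = d.max()
        ssw += d.sum()
    return p95, max_intra, ssw


def ssw_texture(FT: np.ndarray, labels: np.ndarray, cent: np.ndarray) -> float:
    """Intra-cluster chi-square texture homogeneity (sum over all ROIs)."""
    _, _, ssw = _cluster_stats(FT, labels, cent)
    return ssw


# ---------------------------------------------------------------------------
# initial texture-only clustering

def _chi2_kmeans_pp(FT: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under the chi-square distance; returns data rows."""
    n = FT.shape[0]
    centers = [int(rng.integers(n))]
    d = chi2_cdist(FT, FT[centers[-1]][None, :])[:, 0]
    for _ in range(1, k):
        probs = d**2
        tot = probs.sum()
        if tot <= 0:
            remaining = np.setdiff1d(np.arange(n), centers)
            centers.append(int(rng.choice(remaining)))
        else:
            centers.append(int(rng.choice(n, p=probs / tot)))
        d = np.minimum(d, chi2_cdist(FT, FT[centers[-1]][None, :])[:, 0])
    return FT[centers].copy()


def init_ltps(FT: np.ndarray, n_ltp: int, seed: int = 0,
              max_iter: int = 100) -> LtpModel:
    """Initial LTPs: chi-square Lloyd k-means on texture histograms.

    Relabeling uses the chi-square distance and centroid updates the
    arithmetic mean; empty clusters are dropped.  SSW_T of the converged
    state is stored as the lambda-tuning baseline.
    """
    FT = np.asarray(FT, dtype=float)
    n = FT.shape[0]
    if n < n_ltp:
        raise ValueError(f"need at least {n_ltp} ROIs, got {n}")
    rng = np.random.default_rng(seed)
    cent = _chi2_kmeans_pp(FT, n_ltp, rng)
    labels = None
    for _ in range(max_iter):
        d = chi2_cdist(FT, cent)
        new = np.argmin(d, axis=1)
        used = np.unique(new)            # drop empty clusters, re-indexing
        new = np.searchsorted(used, new)
        cent = _mean_centroids(FT, new, used.size)
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
    p95, max_intra, ssw = _cluster_stats(FT, labels, cent)
    return LtpModel(ft_centroids=cent, fs_centroids=np.empty((cent.shape[0], 0)),
                    labels=labels, lam=0.0, w=1.0, penalty=True,
                    p95=p95, max_intra=max_intra, ssw_t=ssw)


# ---------------------------------------------------------------------------
# W scaling

def compute_W(FT: np.ndarray, FS: np.ndarray) -> float:
    """Ratio of total chi-square texture scatter to total l2 spatial scatter."""
    FT = np.asarray(FT, dtype=float)
    FS = np.asarray(FS, dtype=float)
    if FT.shape[0] < 2:
        raise ValueError("need at least 2 ROIs")
    sst_t = chi2_cdist(FT, FT.mean(axis=0, keepdims=True))[:, 0].sum()
    sst_s = float(((FS - FS.mean(axis=0)) ** 2).sum())
    if sst_s == 0:
        raise ValueError("all ROIs share one sub-region (SST_S = 0); "
                         "disable the lambda*W spatial term")
    return float(sst_t) / sst_s


# ---------------------------------------------------------------------------
# spatial augmentation

def augment_ltps(FT: np.ndarray, FS: np.ndarray, init: LtpModel, lam: float,
                 w: float, penalty: bool = True, max_iter: int = 50,
                 change_tol: float = 1e-3) -> LtpModel:
    """Iterate {relabel, centroid update} under the mixed chi2-l2 cost.

    Each ROI moves to the admissible LTP (chi2 texture distance within the
    LTP's P95 threshold, from the previous iteration's assignments) with the
    smallest combined cost; ROIs barred from every LTP fall back to the
    texture-only argmin.  Empty LTPs are dropped.

    Termination: fewer than 0.1% of ROIs change label, ``max_iter``
    iterations, or an iteration fails to improve the objective by a relative
    1e-6 (the previous, better iterate is kept).  The last rule exists
    because the mean is not the exact chi-square centroid, so unbounded
    iteration can churn on a plateau; stopping at the best iterate keeps the
    recorded objective trace non-increasing.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    FT = np.asarray(FT, dtype=float)
    FS = np.asarray(FS, dtype=float)
    n = FT.shape[0]
    labels = init.labels.copy()
    ft_cent = init.ft_centroids.copy()
    fs_cent = _mean_centroids(FS, labels, ft_cent.shape[0])
    p95 = init.p95.copy()
    trace = []
    for _ in range(max_iter):
        d_t = chi2_cdist(FT, ft_cent)
        d_s = ((FS[:, None, :] - fs_cent[None, :, :]) ** 2).sum(axis=2)
        cost = d_t + lam * w * d_s
        if penalty:
            barred = d_t > p95[None, :]
            masked = np.where(barred, np.inf, cost)
            new = np.argmin(masked, axis=1)
            dead = ~np.isfinite(masked[np.arange(n), new])
            if dead.any():
                new[dead] = np.argmin(d_t[dead], axis=1)
        else:
            new = np.argmin(cost, axis=1)
        # Eq-3 objective at the previous centroids (penalty term zero by design)
        obj = float(cost[np.arange(n), new].sum())
        if trace and obj > trace[-1] - 1e-6 * abs(trace[-1]):
            break  # no real improvement: keep the previous, better iterate
        trace.append(obj)
        changed = int((new != labels).sum())
        used = np.unique(new)
        new = np.searchsorted(used, new)
        labels = new
        ft_cent = _mean_centroids(FT, labels, used.size)
        fs_cent = _mean_centroids(FS, labels, used.size)
        p95, max_intra, ssw = _cluster_stats(FT, labels, ft_cent)
        if changed <= change_tol * n:
            break
    return LtpModel(ft_centroids=ft_cent, fs_centroids=fs_cent, labels=labels,
                    lam=lam, w=w, penalty=penalty, p95=p95, max_intra=max_intra,
                    ssw_t=ssw, objective_trace=trace)


def tune_lambda(FT: np.ndarray, FS: np.ndarray, init: LtpModel, w: float,
                grid=None, l_t: float = 1.0, penalty: bool = True):
    """Largest grid lambda whose texture-homogeneity loss stays below L_T.

    Delta-SSW_T(lambda) = (SSW_T^lambda - SSW_T) / SSW_T * 100 is evaluated by
    re-augmenting from the same initial model for every grid value; returns
    ``(lambda_star, trace)`` where trace is a list of (lambda, delta) pairs.
    """
    if grid is None:
        grid = np.linspace(0.0, 2.0, 51)
    grid = sorted(float(g) for g in grid)
    if l_t <= 0:
        raise ValueError("L_T must be > 0")
    if init.ssw_t == 0:
        logger.warning("SSW_T = 0 at init (degenerate clustering); returning grid max")
        return grid[-1], [(g, 0.0) for g in grid]
    trace = []
    lam_star = 0.0
    for lam in grid:
        model = augment_ltps(FT, FS, init, lam, w, penalty=penalty)
        delta = (model.ssw_t - init.ssw_t) / init.ssw_t * 100.0
        trace.append((lam, float(delta)))
        if delta < l_t:
            lam_star = lam
    return lam_star, trace
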