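"""Reproducibility metrics and the signature-to-subtype constrained regression.

Cluster-label reproducibility R_ln averages, over retrained models and
patterns, the fraction of a reference pattern's ROIs recovered by the
Hungarian-matched pattern of a retrained model.  Label-map reproducibility
uses per-pattern Dice overlap and Spearman correlation of percent-pattern
values; cross-scanner agreement uses Cohen's kappa of pattern presence.

The constrained multivariate regression maps (N+1)-bin scan signatures X to
4-bin ground-truth subtype signatures Y by minimizing ||XA - Y||^2 subject
to 0 <= A <= 1 and unit row sums, so each coefficient reads as the
probability that a voxel of a given predictor belongs to a ground-truth
class.  Prediction quality is the intraclass correlation (two-way random,
absolute agreement, single measures) between cross-validated predictions
and ground truth; ICCs are compared with Fisher's r-to-z transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import optimize, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cluster matching and R_ln

def overlap_matrix(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Contingency counts between two labelings of the same items."""
    a_ids = np.unique(labels_a)
    b_ids = np.unique(labels_b)
    mat = np.zeros((a_ids.size, b_ids.size), dtype=int)
    for i, a in enumerate(a_ids):
        sel = labels_a == a
        for j, b in enumerate(b_ids):
            mat[i, j] = int(np.sum(sel & (labels_b == b)))
    return mat


def hungarian_match(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Optimal one-to-one cluster matching maximizing total overlap.

    Returns a mapping from cluster ids of ``labels_a`` to matched ids of
    ``labels_b``; surplus clusters of the larger set stay unmatched (the
    rectangular problem is zero-padded to square).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same items")
    a_ids = np.unique(labels_a)
    b_ids = np.unique(labels_b)
    mat = overlap_matrix(labels_a, labels_b)
    n = max(a_ids.size, b_ids.size)
    padded = np.zeros((n, n))
    padded[: mat.shape[0], : mat.shape[1]] = mat
    rows, cols = optimize.linear_sum_assignment(-padded)
    mapping = {}
    for r, c in zip(rows, cols):
        if r < a_ids.size and c < b_ids.size:
            mapping[a_ids[r]] = b_ids[c]
    return mapping


def reproducibility_ln(reference: np.ndarray, subsets: list[np.ndarray]) -> float:
    """Mean Hungarian-matched recovery fraction of reference clusters (R_ln).

    For each retrained labeling c and each reference cluster k, the matched
    cluster pi(k) contributes |ref_k intersect sub_pi(k)| / |ref_k|; empty
    reference clusters are skipped with an adjusted divisor.
    """
    reference = np.asarray(reference)
    total, terms = 0.0, 0
    for sub in subsets:
        sub = np.asarray(sub)
        mapping = hungarian_match(reference, sub)
        for k in np.unique(reference):
            ref_k = reference == k
            if not ref_k.any():
                logger.warning("empty reference cluster %s skipped", k)
                continue
            if k in mapping:
                total += np.sum(ref_k & (sub == mapping[k])) / ref_k.sum()
            terms += 1
    return total / terms if terms else float("nan")


def reproducibility_ln_pairwise(subsets: list[np.ndarray]) -> tuple[float, float]:
    """Mean and sd of R_ln over all ordered pairs of retrained labelings."""
    vals = [reproducibility_ln(a, [b])
            for i, a in enumerate(subsets) for j, b in enumerate(subsets) if i != j]
    return float(np.mean(vals)), float(np.std(vals))


def matched_ari(labels: np.ndarray, truth: np.ndarray) -> float:
    """Adjusted Rand index after majority-vote grouping of clusters to truth classes.

    Each cluster is mapped to the truth class holding most of its members
    (many-to-one), then the ARI of the grouped labeling against truth is
    returned; this scores recovery of K planted classes by a finer clustering.
    """
    from sklearn.metrics import adjusted_rand_score

    labels = np.asarray(labels)
    truth = np.asarray(truth)
    grouped = np.empty_like(truth)
    for c in np.unique(labels):
        sel = labels == c
        vals, counts = np.unique(truth[sel], return_counts=True)
        grouped[sel] = vals[np.argmax(counts)]
    return float(adjusted_rand_score(truth, grouped))


# ---------------------------------------------------------------------------
# label-map reproducibility

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * float((a & b).sum()) / float(denom)


def label_reproducibility(maps_a: list[np.ndarray], maps_b: list[np.ndarray],
                          n_sltp: int, lung_masks: list[np.ndarray]) -> pd.DataFrame:
    """Per-sLTP Dice and Spearman reproducibility across two ROI seedings.

    ``maps_a`` / ``maps_b`` are paired label maps of the same scans.  Dice is
    averaged over scans where the pattern occurs in at least one map; the
    Spearman correlation is over per-scan percent-pattern values.
    """
    rows = []
    for k in range(1, n_sltp + 1):
        dices, pa, pb = [], [], []
        for la, lb, lung in zip(maps_a, maps_b, lung_masks):
            ma, mb = la == k, lb == k
            if ma.any() or mb.any():
                dices.append(dice(ma, mb))
            lung = np.asarray(lung, dtype=bool)
            pa.append(100.0 * (ma & lung).sum() / lung.sum())
            pb.append(100.0 * (mb & lung).sum() / lung.sum())
        rho = stats.spearmanr(pa, pb).statistic if len(pa) > 1 else np.nan
        rows.append({"sltp": k,
                     "dice": float(np.mean(dices)) if dices else np.nan,
                     "spearman": float(rho)})
    return pd.DataFrame(rows)


def presence_kappa(sig_a: np.ndarray, sig_b: np.ndarray) -> np.ndarray:
    """Cohen's kappa of per-sLTP presence (%sLTP > 0) across paired scans.

    ``sig_a``/``sig_b`` are (n_scans, N+1) signature matrices of paired
    sessions; column 0 (no-emphysema) is ignored.  Degenerate 2x2 tables
    (all scans agreeing on one cell) yield NaN.
    """
    sig_a = np.atleast_2d(sig_a)
    sig_b = np.atleast_2d(sig_b)
    if sig_a.shape != sig_b.shape:
        raise ValueError("paired signature matrices must have equal shape")
    out = []
    for k in range(1, sig_a.shape[1]):
        pa = sig_a[:, k] > 0
        pb = sig_b[:, k] > 0
        n = pa.size
        po = np.mean(pa == pb)
        pe = pa.mean() * pb.mean() + (1 - pa.mean()) * (1 - pb.mean())
        out.append(np.nan if pe == 1.0 else (po - pe) / (1.0 - pe))
    return np.array(out)


# ---------------------------------------------------------------------------
# constrained regression and ICC

@dataclass
class RegressionModel:
    """Row-stochastic coefficient matrix with cross-validated ICC per class."""

    A: np.ndarray                 # (N_predictor, n_classes), rows sum to 1
    icc: pd.DataFrame             # per class: ICC, ci95_low, ci95_high
    folds: np.ndarray             # (n_scans,) fold assignment
    residual: float               # training objective ||XA - Y||^2


def _solve_row_stochastic(X: np.ndarray, Y: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """argmin ||XA - Y||^2 with 0 <= A <= 1 and unit row sums (SLSQP)."""
    n_pred, n_cls = X.shape[1], Y.shape[1]
    size = n_pred * n_cls

    def objective(a):
        A = a.reshape(n_pred, n_cls)
        R = X @ A - Y
        return float((R**2).sum()), (2.0 * X.T @ R).ravel()

    constraints = [{"type": "eq",
                    "fun": lambda a: a.reshape(n_pred, n_cls).sum(axis=1) - 1.0,
                    "jac": lambda a: np.repeat(np.eye(n_pred), n_cls, axis=1)}]
    a0 = np.full(size, 1.0 / n_cls)
    res = optimize.minimize(objective, a0, jac=True, method="SLSQP",
                            bounds=[(0.0, 1.0)] * size, constraints=constraints,
                            options={"maxiter": 500, "ftol": tol})
    if not res.success:
        logger.warning("SLSQP reported: %s", res.message)
    A = res.x.reshape(n_pred, n_cls)
    A = np.clip(A, 0.0, 1.0)
    A /= A.sum(axis=1, keepdims=True)
    return A


def icc_absolute_agreement(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """ICC(2,1): two-way random, absolute agreement, single measures, with 95% CI."""
    n = len(pred)
    data = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["pred", "truth"], n),
        "score": np.concatenate([pred, truth]),
    })
    if np.allclose(pred, truth):
        return 1.0, np.nan, np.nan
    res = pg.intraclass_corr(data=data, targets="target", raters="rater",
                             ratings="score", nan_policy="omit")
    sel = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]  # naming differs across versions
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), float(lo), float(hi)


def fit_constrained_regression(X: np.ndarray, Y: np.ndarray, n_folds: int = 4,
                               seed: int = 0,
                               class_names: list[str] | None = None) -> RegressionModel:
    """Fit the row-stochastic signature regression with K-fold validated ICC.

    ``X`` (n_scans, N_predictor) and ``Y`` (n_scans, n_classes) hold fractions
    in [0, 1].  The coefficient matrix is fit on all scans; per-class ICCs
    compare held-out-fold predictions against ground truth.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must cover the same scans")
    if np.linalg.matrix_rank(X) == 0:
        raise ValueError("degenerate predictor matrix (rank 0)")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    pred = np.zeros_like(Y)
    for f in range(n_folds):
        hold = folds == f
        if hold.all() or (~hold).sum() < 2:
            raise ValueError("not enough scans for cross-validation")
        A_f = _solve_row_stochastic(X[~hold], Y[~hold])
        pred[hold] = X[hold] @ A_f
    A = _solve_row_stochastic(X, Y)
    names = class_names or [f"class_{i}" for i in range(Y.shape[1])]
    rows = []
    for i, name in enumerate(names):
        icc, lo, hi = icc_absolute_agreement(pred[:, i], Y[:, i])
        rows.append({"class": name, "icc": icc, "ci95_low": lo, "ci95_high": hi})
    residual = float(((X @ A - Y) ** 2).sum())
    return RegressionModel(A=A, icc=pd.DataFrame(rows), folds=folds, residual=residual)


def compare_icc(icc1: float, n1: int, icc2: float, n2: int) -> dict:
    """Two-tailed p for a difference of two ICCs via Fisher's r-to-z transform."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    for icc in (icc1, icc2):
        if abs(icc) >= 1.0:
            raise ValueError("|ICC| = 1 has an infinite transform")
    z1, z2 = np.arctanh(icc1), np.arctanh(icc2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return {"z": float(z), "p": float(p)}
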