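"""Whole-scan sLTP labeling, scan signatures and scanner calibration.

At test time, ROI centers are SURS-sampled per lung; centers whose ROI has
percent emphysema <= 1% by either segmentation are labeled no-emphysema
(class 0), the rest get the sLTP minimizing the mixed chi2-l2 labeling cost
(ties to the lowest index).  Remaining lung voxels inherit the code of the
nearest sampled center within the same lung (a Voronoi fill in mm).  The
scan signature is the normalized histogram over codes 0..N per lung.

Scanner calibration equalizes outside-air mean attenuation by an additive
shift and then applies a monotone piecewise-linear quantile map estimated
on normal lung parenchyma.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig
from .exceptions import StageError
from .features import (roi_slices, roi_texture, spatial_feature, surs_sample,
                       TextonCodebook)
from .ltp import chi2_cdist
from .merge import SltpModel
from .pdcm import PdcmMap
from .volio import Volume

logger = logging.getLogger(__name__)

OUTSIDE_LUNG = -1
NO_EMPHYSEMA = 0


def assign_sltp(FT: np.ndarray, FS: np.ndarray, model: SltpModel) -> np.ndarray:
    """sLTP ids (1..N) minimizing chi2(FT, FT_k) + lam*W*||FS - FS_k||^2."""
    d_t = chi2_cdist(np.atleast_2d(FT), model.ft_centroids)
    d_s = ((np.atleast_2d(FS)[:, None, :] - model.fs_centroids[None, :, :]) ** 2).sum(axis=2)
    cost = d_t + model.lam * model.w * d_s
    return np.argmin(cost, axis=1) + 1


def label_scan(ct: np.ndarray, pdcms: dict[str, PdcmMap], emph_950: np.ndarray,
               emph_smooth: np.ndarray, model: SltpModel, codebook: TextonCodebook,
               config: RunConfig, rng: np.random.Generator,
               beta2: int | None = None) -> Volume:
    """Label a scan with sLTPs; codes -1 outside lung, 0 no-emphysema, 1..N sLTPs."""
    beta2 = config.beta2 if beta2 is None else beta2
    shape = ct.shape
    labels = np.full(shape, OUTSIDE_LUNG, dtype=np.int16)
    spacing = next(iter(pdcms.values())).spacing
    lungs = np.zeros_like(next(iter(pdcms.values())).mask)
    for p in pdcms.values():
        lungs |= p.mask
    for side, pdcm in pdcms.items():
        centers = surs_sample(pdcm.mask, pdcm.spacing, config.roi_edge_mm,
                              config.beta1, beta2, rng)
        if centers.shape[0] == 0:
            raise StageError(f"no SURS centers sampled in {side} lung; increase beta2")
        half = [max(1, int(round(config.roi_edge_mm / 2.0 / s))) for s in pdcm.spacing]
        codes = np.zeros(centers.shape[0], dtype=np.int16)
        ft_rows, fs_rows, emph_idx = [], [], []
        for n, c in enumerate(centers):
            sl = roi_slices(c, half)
            lung = lungs[sl]
            n_lung = int(lung.sum())
            if n_lung == 0:
                continue
            p950 = 100.0 * float((emph_950[sl] & lung).sum()) / n_lung
            psm = 100.0 * float((emph_smooth[sl] & lung).sum()) / n_lung
            if p950 <= config.gate_percent or psm <= config.gate_percent:
                codes[n] = NO_EMPHYSEMA
                continue
            ft_rows.append(roi_texture(ct[sl], lung, codebook))
            fs_rows.append(spatial_feature(c, pdcm, config.n_r_bins,
                                           config.n_theta_bins, config.n_phi_bins))
            emph_idx.append(n)
        if emph_idx:
            codes[np.array(emph_idx)] = assign_sltp(np.array(ft_rows),
                                                    np.array(fs_rows), model)
        # Voronoi fill: every lung voxel takes the code of its nearest center (mm)
        tree = cKDTree(centers * np.asarray(pdcm.spacing))
        lung_vox = np.argwhere(pdcm.mask)
        _, nearest = tree.query(lung_vox * np.asarray(pdcm.spacing), workers=1)
        labels[lung_vox[:, 0], lung_vox[:, 1], lung_vox[:, 2]] = codes[nearest]
    return Volume(labels, spacing)


def sltp_signature(labels: Volume | np.ndarray, lung_mask: np.ndarray,
                   n_sltp: int) -> np.ndarray:
    """(N+1)-bin percent signature [%no-emphysema, %sLTP_1, ..., %sLTP_N]."""
    lab = labels.voxels if isinstance(labels, Volume) else labels
    vals = lab[np.asarray(lung_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty lung mask")
    counts = np.bincount(np.clip(vals, 0, n_sltp), minlength=n_sltp + 1).astype(float)
    return counts / vals.size * 100.0


def outside_air_mask(ct: np.ndarray, lung_mask: np.ndarray,
                     air_threshold_hu: float = -600.0) -> np.ndarray:
    """Air voxels outside the lung (used for scanner mean equalization)."""
    return (~np.asarray(lung_mask, dtype=bool)) & (np.asarray(ct) < air_threshold_hu)


def calibrate_scanner(src: np.ndarray, ref: np.ndarray, src_lung: np.ndarray,
                      ref_lung: np.ndarray, src_normal: np.ndarray,
                      ref_normal: np.ndarray, n_quantiles: int = 256) -> np.ndarray:
    """Two-step cross-scanner intensity calibration of ``src`` toward ``ref``.

    1) additive shift equalizing the outside-air mean attenuation;
    2) monotone piecewise-linear quantile mapping estimated on normal lung
       parenchyma, applied inside the lung.  Rank order within the lung is
       preserved.  With an empty normal-parenchyma mask, step 2 is skipped.
    """
    src = np.asarray(src, dtype=float)
    ref = np.asarray(ref, dtype=float)
    src_air = outside_air_mask(src, src_lung)
    ref_air = outside_air_mask(ref, ref_lung)
    if not src_air.any() or not ref_air.any():
        raise ValueError("no outside-air voxels found for mean equalization")
    shifted = src + (ref[ref_air].mean() - src[src_air].mean())
    src_normal = np.asarray(src_normal, dtype=bool)
    ref_normal = np.asarray(ref_normal, dtype=bool)
    if not src_normal.any() or not ref_normal.any():
        logger.warning("empty normal-parenchyma mask; skipping histogram mapping")
        return shifted
    qs = np.linspace(0.0, 1.0, n_quantiles)
    xp = np.quantile(shifted[src_normal], qs)
    fp = np.quantile(ref[ref_normal], qs)
    # enforce strictly increasing knots for a well-defined monotone map
    xp = np.maximum.accumulate(xp)
    keep = np.concatenate([[True], np.diff(xp) > 0])
    xp, fp = xp[keep], fp[keep]
    out = shifted.copy()
    lung = np.asarray(src_lung, dtype=bool)
    inside = shifted[lung]
    lo, hi = xp[0], xp[-1]
    mapped = np.interp(inside, xp, fp)
    # linear extrapolation beyond the knot range keeps the map monotone
    if xp.size > 1:
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        below, above = inside < lo, inside > hi
        mapped[below] = fp[0] + slope_lo * (inside[below] - lo)
        mapped[above] = fp[-1] + slope_hi * (inside[above] - hi)
    out[lung] = mapped
    return out
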