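"""ROI sampling and texture / spatial feature extraction.

Training ROIs are 25 mm cubes drawn by systematic uniform random sampling
(SURS) over each lung, gated to emphysema-like regions (both percent-
emphysema measures > 1%).  Texture is summarized as the normalized histogram
of texton frequencies over all 3x3x3 patches of the ROI, against a 40-texton
codebook learned by k-means on raw patch intensities.  Space is summarized
as a one-hot vector over the 36 lung sub-regions obtained by discretizing
the PDCM coordinates: r in thirds (core / mid / peel), theta in quadrants
centered on the anatomical axes (anterior / lateral / posterior / medial)
and phi in thirds (superior / mid-level / inferior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

from .config import RunConfig
from .exceptions import DegenerateMaskError
from .pdcm import PdcmMap

logger = logging.getLogger(__name__)

R_BIN_NAMES = ("core", "mid", "peel")
THETA_BIN_NAMES = ("anterior", "lateral", "posterior", "medial")
PHI_BIN_NAMES = ("superior", "mid-level", "inferior")
N_SUBREGIONS = len(R_BIN_NAMES) * len(THETA_BIN_NAMES) * len(PHI_BIN_NAMES)


# ---------------------------------------------------------------------------
# emphysema segmentation

def segment_emphysema_threshold(ct: np.ndarray, mask: np.ndarray,
                                threshold_hu: float = -950.0) -> np.ndarray:
    """Voxels inside the lung with attenuation below the threshold (default -950 HU)."""
    return np.asarray(mask, dtype=bool) & (np.asarray(ct) < threshold_hu)


def segment_emphysema_smooth(ct: np.ndarray, mask: np.ndarray, beta: float = 1.0,
                             n_icm: int = 5, seed: int = 0) -> np.ndarray:
    """Spatially coherent emphysema segmentation (synthetic stand-in).

    A two-component Gaussian intensity mixture (emphysema vs. normal lung) is
    fit inside the lung by EM on the voxel histogram, and the posterior is
    smoothed by iterated conditional modes with a six-neighbor contiguity
    weight ``beta``.  This is a simple in-package construction that mimics the
    behavior of measure-field segmentations (coherent regions, fewer isolated
    voxels than thresholding); it is not the published HMMF method.
    Degenerate fits fall back to -950 HU thresholding.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(ct, dtype=float)[mask]
    if vals.size < 10:
        return segment_emphysema_threshold(ct, mask)
    # EM initialized from the -950 HU split
    low = vals < -950.0
    if low.sum() < 5 or (~low).sum() < 5:
        lo, hi = np.quantile(vals, [0.05, 0.95])
        mu = np.array([lo, hi])
        sigma = np.array([vals.std() or 1.0] * 2)
        pi = np.array([0.1, 0.9])
    else:
        mu = np.array([vals[low].mean(), vals[~low].mean()])
        sigma = np.array([max(vals[low].std(), 1.0), max(vals[~low].std(), 1.0)])
        pi = np.array([low.mean(), 1.0 - low.mean()])
    for _ in range(50):
        logp = (np.log(pi)[None, :]
                - np.log(sigma)[None, :]
                - 0.5 * ((vals[:, None] - mu[None, :]) / sigma[None, :]) ** 2)
        logp -= logp.max(axis=1, keepdims=True)
        resp = np.exp(logp)
        resp /= resp.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        if np.any(nk < 5):
            logger.warning("degenerate intensity mixture; falling back to thresholding")
            return segment_emphysema_threshold(ct, mask)
        mu_new = (resp * vals[:, None]).sum(axis=0) / nk
        sigma_new = np.sqrt((resp * (vals[:, None] - mu_new[None, :]) ** 2).sum(axis=0) / nk)
        sigma_new = np.maximum(sigma_new, 1.0)
        pi_new = nk / nk.sum()
        if np.allclose(mu_new, mu, atol=1e-3):
            mu, sigma, pi = mu_new, sigma_new, pi_new
            break
        mu, sigma, pi = mu_new, sigma_new, pi_new
    if mu[0] > mu[1]:  # component 0 is the emphysema (low HU) class
        mu, sigma, pi = mu[::-1], sigma[::-1], pi[::-1]
        resp = resp[:, ::-1]
    if mu[1] - mu[0] < 20.0:
        logger.warning("mixture components not separated; falling back to thresholding")
        return segment_emphysema_threshold(ct, mask)
    # log-posterior fields inside the lung
    log_post = np.zeros(mask.shape + (2,), dtype=float)
    for c in range(2):
        log_post[mask, c] = (np.log(pi[c]) - np.log(sigma[c])
                             - 0.5 * ((vals - mu[c]) / sigma[c]) ** 2)
    labels = np.zeros(mask.shape, dtype=bool)
    labels[mask] = resp[:, 0] > 0.5
    struct = ndi.generate_binary_structure(3, 1)
    for _ in range(n_icm):
        nb_emph = ndi.convolve(labels.astype(float), struct.astype(float), mode="constant")
        score_e = log_post[..., 0] + beta * nb_emph
        score_n = log_post[..., 1] + beta * (ndi.convolve(mask.astype(float),
                                                          struct.astype(float),
                                                          mode="constant") - nb_emph)
        new = mask & (score_e > score_n)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


# ---------------------------------------------------------------------------
# SURS sampling

def surs_sample(mask: np.ndarray, spacing, stack_edge_mm: float, beta1: float,
                beta2: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic uniform random sampling of voxel centers over a lung mask.

    The mask bounding box is tiled by non-overlapping cubic stacks of edge
    ``stack_edge_mm``.  In each stack, ``beta2`` candidate positions on a
    regular in-stack lattice are each displaced by a uniform random shift in
    [0, beta1] mm per axis and retained iff the resulting voxel center lies
    inside the mask.  Returns an (n, 3) integer array of voxel indices;
    deterministic given the generator state, and independent of it when
    beta1 = 0.
    """
    if beta2 < 1:
        raise ValueError("beta2 must be >= 1")
    if stack_edge_mm <= 0:
        raise ValueError("stack edge must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3), dtype=int)
    spacing = np.asarray(spacing, dtype=float)
    lo = np.array([idx.min() for idx in np.nonzero(mask)])
    hi = np.array([idx.max() for idx in np.nonzero(mask)])
    box_mm = (hi - lo + 1) * spacing
    n_stacks = np.maximum(1, np.ceil(box_mm / stack_edge_mm).astype(int))
    # regular in-stack lattice: smallest m with m^3 >= beta2, first beta2 nodes
    m = int(np.ceil(beta2 ** (1.0 / 3.0)))
    while m**3 < beta2:
        m += 1
    lat = (np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), axis=-1)
           .reshape(-1, 3)[:beta2])
    offsets = (lat + 0.5) / m * stack_edge_mm
    centers = []
    for sx in range(n_stacks[0]):
        for sy in range(n_stacks[1]):
            for sz in range(n_stacks[2]):
                origin = lo * spacing + np.array([sx, sy, sz]) * stack_edge_mm
                shift = rng.uniform(0.0, beta1, size=(beta2, 3)) if beta1 > 0 else 0.0
                pos_mm = origin[None, :] + offsets + shift
                vox = np.rint(pos_mm / spacing).astype(int)
                ok = np.all((vox >= 0) & (vox < mask.shape), axis=1)
                vox = vox[ok]
                ok = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
                centers.append(vox[ok])
    if not centers:
        return np.empty((0, 3), dtype=int)
    return np.concatenate(centers, axis=0)


def roi_slices(center, half_vox) -> tuple[slice, slice, slice]:
    """Clipped index slices of the ROI cube around a voxel center."""
    return tuple(slice(max(0, int(c) - h), int(c) + h + 1)
                 for c, h in zip(center, half_vox))


def percent_emphysema(center, edge_mm: float, emph_mask: np.ndarray,
                      lung_mask: np.ndarray, spacing) -> float:
    """Fraction (in %) of emphysematous voxels among lung voxels of the ROI cube."""
    half = [max(1, int(round(edge_mm / 2.0 / s))) for s in spacing]
    sl = roi_slices(center, half)
    lung = lung_mask[sl]
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise DegenerateMaskError("ROI contains no lung voxels")
    return 100.0 * float((emph_mask[sl] & lung).sum()) / n_lung


# ---------------------------------------------------------------------------
# texton codebook and texture features

@dataclass
class TextonCodebook:
    """K centroid vectors of raw patch intensities (patch_edge^3 values, HU)."""

    centroids: np.ndarray        # (K, patch_edge**3)
    patch_edge: int = 3
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def extract_patches(cube: np.ndarray, patch_edge: int = 3,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """All dense stride-1 patches of a ROI cube, flattened to rows.

    With a mask, only patches whose every voxel lies inside it are kept, so
    histograms describe lung tissue rather than chest wall or outside air.
    """
    cube = np.asarray(cube, dtype=float)
    if any(s < patch_edge for s in cube.shape):
        return np.empty((0, patch_edge**3))
    win = sliding_window_view(cube, (patch_edge,) * 3).reshape(-1, patch_edge**3)
    if mask is not None:
        ok = sliding_window_view(np.asarray(mask, dtype=bool),
                                 (patch_edge,) * 3).reshape(-1, patch_edge**3).all(axis=1)
        win = win[ok]
    return win


def build_texton_codebook(patches: np.ndarray, k: int = 40,
                          seed: int = 0, patch_edge: int = 3) -> TextonCodebook:
    """k-means texton codebook from raw training patches (k-means++ init)."""
    patches = np.asarray(patches, dtype=float)
    if patches.shape[0] < k:
        raise ValueError(f"need at least {k} patches, got {patches.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                tol=1e-6, random_state=seed, algorithm="lloyd")
    km.fit(patches)
    return TextonCodebook(centroids=km.cluster_centers_.copy(),
                          patch_edge=patch_edge, seed=seed)


def texture_feature(cube: np.ndarray, codebook: TextonCodebook,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized texton-frequency histogram of a ROI cube.

    Every stride-1 patch (restricted to all-lung patches when a mask is
    given) is assigned to the nearest centroid (Euclidean, ties to the
    lowest index); the histogram sums to 1.
    """
    patches = extract_patches(cube, codebook.patch_edge, mask=mask)
    if patches.shape[0] == 0:
        raise ValueError("ROI holds no admissible patch")
    c = codebook.centroids
    d2 = (np.einsum("ij,ij->i", patches, patches)[:, None]
          - 2.0 * patches @ c.T + np.einsum("ij,ij->i", c, c)[None, :])
    hist = np.bincount(np.argmin(d2, axis=1), minlength=codebook.k).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# spatial features

def roi_texture(cube: np.ndarray, lung: np.ndarray,
                codebook: TextonCodebook) -> np.ndarray:
    """Lung-restricted texture histogram, falling back to all patches when the
    ROI is too thin to hold a single all-lung patch."""
    try:
        return texture_feature(cube, codebook, mask=lung)
    except ValueError:
        return texture_feature(cube, codebook)


def spatial_bin_index(r: float, theta: float, phi: float,
                      n_r: int = 3, n_theta: int = 4, n_phi: int = 3) -> int:
    """Flat sub-region index of a PDCM coordinate triple.

    r is split into right-open thirds (core / mid / peel, r = 1 to the last
    bin); theta into quadrants centered on the anatomical axes (edges at
    pi/4 + k*pi/2 from the anterior axis); phi into thirds indexed from the
    superior bin (phi = +pi/2) downward.  The flat index rasters as
    ``r_bin * (n_theta * n_phi) + theta_bin * n_phi + phi_bin``.
    """
    r_bin = min(int(np.floor(np.clip(r, 0.0, 1.0) * n_r)), n_r - 1)
    sector = 2.0 * np.pi / n_theta
    theta_bin = int(np.floor(np.mod(theta + sector / 2.0, 2.0 * np.pi) / sector)) % n_theta
    phi_asc = min(int(np.floor((phi + np.pi / 2.0) / (np.pi / n_phi))), n_phi - 1)
    phi_bin = (n_phi - 1) - phi_asc
    return r_bin * (n_theta * n_phi) + theta_bin * n_phi + phi_bin


def spatial_bin_volume(pdcm: PdcmMap, n_r: int = 3, n_theta: int = 4,
                       n_phi: int = 3) -> np.ndarray:
    """Sub-region index of every voxel (int array, -1 outside the lung)."""
    out = np.full(pdcm.mask.shape, -1, dtype=np.int16)
    m = pdcm.mask
    r = np.clip(pdcm.r[m], 0.0, 1.0)
    r_bin = np.minimum((r * n_r).astype(int), n_r - 1)
    sector = 2.0 * np.pi / n_theta
    theta_bin = (np.mod(pdcm.theta[m] + sector / 2.0, 2.0 * np.pi) / sector).astype(int) % n_theta
    phi_asc = np.minimum(((pdcm.phi[m] + np.pi / 2.0) / (np.pi / n_phi)).astype(int), n_phi - 1)
    phi_bin = (n_phi - 1) - phi_asc
    out[m] = r_bin * (n_theta * n_phi) + theta_bin * n_phi + phi_bin
    return out


def spatial_feature(center, pdcm: PdcmMap, n_r: int = 3, n_theta: int = 4,
                    n_phi: int = 3) -> np.ndarray:
    """One-hot sub-region vector of a ROI center."""
    c = tuple(int(v) for v in center)
    if not pdcm.mask[c]:
        raise ValueError(f"center {c} is outside the lung mask")
    idx = spatial_bin_index(pdcm.r[c], pdcm.theta[c], pdcm.phi[c], n_r, n_theta, n_phi)
    vec = np.zeros(n_r * n_theta * n_phi)
    vec[idx] = 1.0
    return vec


def subregion_name(index: int) -> str:
    r_bin, rem = divmod(index, len(THETA_BIN_NAMES) * len(PHI_BIN_NAMES))
    t_bin, p_bin = divmod(rem, len(PHI_BIN_NAMES))
    return f"{R_BIN_NAMES[r_bin]}/{THETA_BIN_NAMES[t_bin]}/{PHI_BIN_NAMES[p_bin]}"


# ---------------------------------------------------------------------------
# ROI tables

@dataclass
class RoiTable:
    """Columnar container of sampled ROIs and their features."""

    centers: np.ndarray           # (n, 3) voxel indices
    side: np.ndarray              # (n,) str: 'right' / 'left'
    pem_950: np.ndarray           # (n,) percent emphysema, thresholding
    pem_smooth: np.ndarray        # (n,) percent emphysema, coherent segmentation
    ft: np.ndarray                # (n, K) texture histograms
    fs: np.ndarray                # (n, 36) one-hot spatial vectors
    bin_index: np.ndarray         # (n,) flat sub-region index
    mean_hu: np.ndarray           # (n,) mean ROI attenuation
    scan_id: np.ndarray           # (n,) str

    def __len__(self) -> int:
        return self.centers.shape[0]

    def subset(self, sel) -> "RoiTable":
        return RoiTable(self.centers[sel], self.side[sel], self.pem_950[sel],
                        self.pem_smooth[sel], self.ft[sel], self.fs[sel],
                        self.bin_index[sel], self.mean_hu[sel], self.scan_id[sel])

    @property
    def gated(self) -> np.ndarray:
        """Training gate: both percent-emphysema measures strictly above 1%."""
        return (self.pem_950 > 1.0) & (self.pem_smooth > 1.0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2],
            "side": self.side, "pem_950": self.pem_950, "pem_smooth": self.pem_smooth,
            "bin_index": self.bin_index, "mean_hu": self.mean_hu, "scan_id": self.scan_id,
        })
        return df


def sample_roi_table(ct: np.ndarray, pdcms: dict[str, PdcmMap], emph_950: np.ndarray,
                     emph_smooth: np.ndarray, config: RunConfig,
                     rng: np.random.Generator, codebook: TextonCodebook | None = None,
                     scan_id: str = "scan", beta2: int | None = None) -> RoiTable:
    """SURS-sample both lungs and extract per-ROI features.

    Texture histograms are only computed when a codebook is given (they are
    filled with zeros otherwise, e.g. while collecting codebook patches).
    """
    beta2 = config.beta2 if beta2 is None else beta2
    rows = {k: [] for k in ("centers", "side", "p950", "psm", "ft", "fs", "bin", "hu")}
    nbins = config.n_subregions
    lungs = np.zeros_like(next(iter(pdcms.values())).mask)
    for p in pdcms.values():
        lungs |= p.mask
    for side in ("right", "left"):
        pdcm = pdcms[side]
        centers = surs_sample(pdcm.mask, pdcm.spacing, config.roi_edge_mm,
                              config.beta1, beta2, rng)
        half = [max(1, int(round(config.roi_edge_mm / 2.0 / s))) for s in pdcm.spacing]
        for c in centers:
            sl = roi_slices(c, half)
            lung = lungs[sl]
            n_lung = int(lung.sum())
            if n_lung == 0:
                continue
            p950 = 100.0 * float((emph_950[sl] & lung).sum()) / n_lung
            psm = 100.0 * float((emph_smooth[sl] & lung).sum()) / n_lung
            cube = ct[sl]
            if codebook is not None:
                ft = roi_texture(cube, lung, codebook)
            else:
                ft = np.zeros(config.n_textons)
            fs = spatial_feature(c, pdcm, config.n_r_bins, config.n_theta_bins,
                                 config.n_phi_bins)
            rows["centers"].append(c)
            rows["side"].append(side)
            rows["p950"].append(p950)
            rows["psm"].append(psm)
            rows["ft"].append(ft)
            rows["fs"].append(fs)
            rows["bin"].append(int(np.argmax(fs)))
            rows["hu"].append(float(cube.mean()))
    n = len(rows["centers"])
    return RoiTable(
        centers=np.array(rows["centers"], dtype=int).reshape(n, 3),
        side=np.array(rows["side"], dtype=object),
        pem_950=np.array(rows["p950"], dtype=float),
        pem_smooth=np.array(rows["psm"], dtype=float),
        ft=np.array(rows["ft"], dtype=float).reshape(n, config.n_textons),
        fs=np.array(rows["fs"], dtype=float).reshape(n, nbins),
        bin_index=np.array(rows["bin"], dtype=int),
        mean_hu=np.array(rows["hu"], dtype=float),
        scan_id=np.array([scan_id] * n, dtype=object),
    )


def collect_codebook_patches(ct: np.ndarray, table: RoiTable, config: RunConfig,
                             rng: np.random.Generator, spacing,
                             lung_mask: np.ndarray | None = None) -> np.ndarray:
    """Raw 3x3x3 lung patches from emphysema-gated ROIs for codebook training."""
    half = [max(1, int(round(config.roi_edge_mm / 2.0 / s))) for s in spacing]
    chunks = []
    for c in table.centers[table.gated]:
        sl = roi_slices(c, half)
        m = lung_mask[sl] if lung_mask is not None else None
        p = extract_patches(ct[sl], config.texton_size, mask=m)
        if p.shape[0] == 0 and m is not None:
            p = extract_patches(ct[sl], config.texton_size)
        chunks.append(p)
    if not chunks:
        raise ValueError("no emphysema-gated ROIs to draw codebook patches from")
    patches = np.concatenate(chunks, axis=0)
    if patches.shape[0] > config.max_codebook_patches:
        sel = rng.choice(patches.shape[0], config.max_codebook_patches, replace=False)
        patches = patches[sel]
    return patches
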