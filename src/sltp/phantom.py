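"""Synthetic full-lung CT phantoms with planted texture classes.

Two mirrored superellipsoid lungs with apical tapering are embedded in a
soft-tissue body surrounded by air.  Parenchyma is spatially correlated
Gaussian noise around a normal-lung attenuation; each planted class stamps
a texture (sparse or dense low-attenuation blobs, a diffuse uniform
low-attenuation decrease, or bright reticular strands) into a target set of
PDCM sub-regions computed from the phantom's own lung masks.  Ground-truth
per-voxel class labels and an emphysema mask make every downstream stage
verifiable.

The default three-class phantom plants texturally and spatially distinct
emphysema-like classes (mean attenuation below -910 HU) in disjoint
sub-region sets of both lungs, on a 96 x 80 x 112 grid at 2 mm isotropic
spacing — a desk-scale stand-in for a full-resolution CT cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

from .exceptions import PhantomSpecError
from .features import spatial_bin_volume, N_SUBREGIONS
from .pdcm import compute_pdcm
from .volio import Volume

AIR_HU = -1000.0
BODY_HU = 40.0

TEXTURE_KINDS = ("blob-sparse", "blob-dense", "diffuse-uniform", "bright-reticular")


def region_bins(r_bins=None, theta_bins=None, phi_bins=None,
                n_r: int = 3, n_theta: int = 4, n_phi: int = 3) -> frozenset:
    """Flat sub-region ids for the cartesian product of named bin indices.

    ``None`` selects all bins on that axis.  Bin orderings follow
    :mod:`sltp.features` (r: core/mid/peel; theta: anterior/lateral/
    posterior/medial; phi: superior/mid-level/inferior).
    """
    r_bins = range(n_r) if r_bins is None else r_bins
    theta_bins = range(n_theta) if theta_bins is None else theta_bins
    phi_bins = range(n_phi) if phi_bins is None else phi_bins
    return frozenset(r * (n_theta * n_phi) + t * n_phi + p
                     for r in r_bins for t in theta_bins for p in phi_bins)


@dataclass(frozen=True)
class PlantedClass:
    """A texture class stamped into a set of PDCM sub-regions (both lungs)."""

    name: str
    kind: str                     # one of TEXTURE_KINDS
    region: frozenset             # flat sub-region ids (subset of 0..35)
    blob_hu: float = -1000.0      # attenuation of blobs / strands
    background_hu: float = -880.0  # in-region attenuation between blobs
    blob_fraction: float = 0.3    # volume fraction occupied by blobs
    blob_radius_mm: float = 3.0   # correlation length of the blob field

    @property
    def mean_hu(self) -> float:
        if self.kind == "diffuse-uniform":
            return self.background_hu
        return (self.blob_fraction * self.blob_hu
                + (1.0 - self.blob_fraction) * self.background_hu)

    @property
    def is_emphysema(self) -> bool:
        return self.mean_hu < -910.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 80, 112)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_half_axes_mm: tuple[float, float, float] = (32.0, 52.0, 88.0)
    lung_center_x_mm: tuple[float, float] = (48.0, 144.0)  # right, left
    apical_taper: float = 0.3     # in-plane shrink factor at the apex
    parenchyma_mean_hu: float = -850.0
    parenchyma_sigma_hu: float = 30.0
    noise_smooth_vox: float = 0.7
    ct_smooth_vox: float = 0.5
    classes: tuple = ()
    seed: int = 0
    min_region_centers: int = 50  # ROI-center placements required per region

    def validate(self) -> None:
        if any(n < 8 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise PhantomSpecError("grid too small or spacing non-positive")
        if not (-900.0 <= self.parenchyma_mean_hu <= -800.0):
            raise PhantomSpecError("parenchyma mean must lie in [-900, -800] HU")
        seen = set()
        for cls in self.classes:
            if cls.kind not in TEXTURE_KINDS:
                raise PhantomSpecError(f"unknown texture kind {cls.kind!r}")
            if not cls.region or not all(0 <= b < N_SUBREGIONS for b in cls.region):
                raise PhantomSpecError(f"class {cls.name!r}: region must be a non-empty "
                                       f"subset of the {N_SUBREGIONS}-bin partition")
            if seen & cls.region:
                raise PhantomSpecError(f"class {cls.name!r}: regions overlap")
            seen |= cls.region
            if cls.is_emphysema and cls.mean_hu >= -910.0:  # pragma: no cover
                raise PhantomSpecError("inconsistent emphysema mean")
            if cls.kind in ("blob-sparse", "blob-dense") and cls.mean_hu >= -910.0:
                raise PhantomSpecError(
                    f"class {cls.name!r}: emphysema blob class mean {cls.mean_hu:.0f} HU "
                    "must be below -910 HU")


def three_class_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default phantom: three disjoint emphysema-like classes.

    Sparse small blobs superiorly (centrilobular-like), dense large blobs at
    mid-level (advanced destruction) and a diffuse uniform decrease
    inferiorly (panlobular-like), each restricted to two azimuthal sectors
    so no-emphysema lung remains in every elevation band.
    """
    classes = (
        PlantedClass("blobs-sparse-superior", "blob-sparse",
                     region_bins(theta_bins=(0, 1), phi_bins=(0,)),
                     blob_hu=-1000.0, background_hu=-880.0,
                     blob_fraction=0.30, blob_radius_mm=3.0),
        PlantedClass("blobs-dense-mid", "blob-dense",
                     region_bins(theta_bins=(2, 3), phi_bins=(1,)),
                     blob_hu=-1000.0, background_hu=-820.0,
                     blob_fraction=0.60, blob_radius_mm=7.0),
        PlantedClass("diffuse-inferior", "diffuse-uniform",
                     region_bins(theta_bins=(0, 2), phi_bins=(2,)),
                     background_hu=-975.0),
    )
    return PhantomSpec(classes=classes, seed=seed, **overrides)


def four_class_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Three emphysema classes plus a bright reticular (fibrosis-like) class."""
    base = three_class_spec(seed=seed, **overrides)
    reticular = PlantedClass("reticular-posterior-inferior", "bright-reticular",
                             region_bins(theta_bins=(3,), phi_bins=(2,)),
                             blob_hu=-300.0, background_hu=-850.0,
                             blob_fraction=0.15, blob_radius_mm=4.0)
    return replace(base, classes=base.classes + (reticular,))


def _lung_mask(spec: PhantomSpec, center_x_mm: float) -> np.ndarray:
    nx, ny, nz = spec.shape
    sp = np.asarray(spec.spacing)
    x = (np.arange(nx) + 0.5) * sp[0]
    y = (np.arange(ny) + 0.5) * sp[1]
    z = (np.arange(nz) + 0.5) * sp[2]
    a, b, c = spec.lung_half_axes_mm
    cy = ny * sp[1] / 2.0
    cz = nz * sp[2] / 2.0
    u = (z - cz) / c                              # -1 at the apex (slice 0 side)
    inplane = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    taper = 1.0 - spec.apical_taper * (1.0 - (u + 1.0) / 2.0)
    ax = a * inplane * taper
    by = b * inplane * taper
    dx = (x[:, None, None] - center_x_mm)
    dy = (y[None, :, None] - cy)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (np.where(ax > 0, (dx / np.where(ax > 0, ax, 1.0))**2, np.inf)
               + np.where(by > 0, (dy / np.where(by > 0, by, 1.0))**2, np.inf))
    return val <= 1.0


def _blob_field(shape, radius_mm, spacing, rng) -> np.ndarray:
    """Smoothed white noise whose level sets carve blob/strand geometry."""
    sigma_vox = [max(0.5, radius_mm / (2.0 * s)) for s in spacing]
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    return (f - f.mean()) / (f.std() or 1.0)


def _stamp_class(ct, region_mask, cls: PlantedClass, spec: PhantomSpec, rng) -> None:
    if cls.kind == "diffuse-uniform":
        ct[region_mask] = cls.background_hu
        return
    f = _blob_field(spec.shape, cls.blob_radius_mm, spec.spacing, rng)
    vals = f[region_mask]
    if cls.kind in ("blob-sparse", "blob-dense"):
        cut = np.quantile(vals, 1.0 - cls.blob_fraction)
        pattern = np.where(vals >= cut, cls.blob_hu, cls.background_hu)
    else:  # bright-reticular: thin strands near the zero level set
        cut = np.quantile(np.abs(vals), cls.blob_fraction)
        pattern = np.where(np.abs(vals) <= cut, cls.blob_hu, cls.background_hu)
    ct[region_mask] = pattern


def generate_phantom(spec: PhantomSpec) -> dict:
    """Generate CT, per-lung masks, PDCMs, truth labels and truth emphysema mask.

    Returns a dict with keys ``ct``, ``lung_masks`` (right/left), ``pdcms``,
    ``truth_labels`` (-1 outside lung, 0 normal, 1..K planted classes),
    ``truth_emphysema`` and ``spec``.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    masks = {"right": _lung_mask(spec, spec.lung_center_x_mm[0]),
             "left": _lung_mask(spec, spec.lung_center_x_mm[1])}
    if masks["right"].sum() == 0 or masks["left"].sum() == 0:
        raise PhantomSpecError("lung geometry does not fit the grid")
    lungs = masks["right"] | masks["left"]
    # chest wall thick enough that ROI cubes at the pleura stay inside the body
    wall_vox = max(4, int(np.ceil(16.0 / min(spec.spacing))))
    body = ndi.binary_dilation(lungs, iterations=wall_vox)
    ct = np.full(spec.shape, AIR_HU)
    ct[body] = BODY_HU
    ct[lungs] = spec.parenchyma_mean_hu

    pdcms = {side: compute_pdcm(masks[side], spec.spacing, side=side)
             for side in ("right", "left")}
    bin_vol = {side: spatial_bin_volume(pdcms[side]) for side in ("right", "left")}

    truth = np.full(spec.shape, -1, dtype=np.int16)
    truth[lungs] = 0
    truth_emph = np.zeros(spec.shape, dtype=bool)
    for cid, cls in enumerate(spec.classes, start=1):
        region = np.zeros(spec.shape, dtype=bool)
        for side in ("right", "left"):
            region |= np.isin(bin_vol[side], list(cls.region)) & masks[side]
        if not region.any():
            raise PhantomSpecError(f"class {cls.name!r}: region is empty inside the lung")
        _check_region_capacity(region, spec)
        _stamp_class(ct, region, cls, spec, rng)
        truth[region] = cid
        if cls.is_emphysema:
            truth_emph |= region

    noise = ndi.gaussian_filter(rng.standard_normal(spec.shape),
                                sigma=spec.noise_smooth_vox)
    noise *= spec.parenchyma_sigma_hu / (noise.std() or 1.0)
    ct[lungs] += noise[lungs]
    if spec.ct_smooth_vox > 0:
        ct = ndi.gaussian_filter(ct, sigma=spec.ct_smooth_vox)

    return {
        "ct": Volume(ct, spec.spacing),
        "lung_masks": masks,
        "pdcms": pdcms,
        "truth_labels": Volume(truth, spec.spacing),
        "truth_emphysema": Volume(truth_emph.astype(np.int16), spec.spacing),
        "spec": spec,
    }


def _check_region_capacity(region: np.ndarray, spec: PhantomSpec,
                           roi_edge_mm: float = 25.0) -> None:
    """Require enough in-region ROI-center placements with the cube on-grid."""
    half = [max(1, int(round(roi_edge_mm / 2.0 / s))) for s in spec.spacing]
    interior = np.zeros(spec.shape, dtype=bool)
    interior[half[0]:-half[0] or None, half[1]:-half[1] or None,
             half[2]:-half[2] or None] = True
    n = int((region & interior).sum())
    if n < spec.min_region_centers:
        raise PhantomSpecError(
            f"planted region supports only {n} ROI-center placements "
            f"(need >= {spec.min_region_centers}); enlarge the grid or the region")


def truth_class_of_centers(centers: np.ndarray, truth_labels: np.ndarray) -> np.ndarray:
    """Planted class id at each ROI center voxel (0 = normal lung)."""
    c = np.asarray(centers, dtype=int)
    return truth_labels[c[:, 0], c[:, 1], c[:, 2]].astype(int)


def generate_signature_fixture(n_scans: int, A_true: np.ndarray, noise_sigma: float,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random signature matrix X on the simplex and noisy targets Y = XA + eps.

    ``A_true`` must be row-stochastic with entries in [0, 1]; Y is clipped
    back to [0, 1].  Used for regression parameter-recovery experiments.
    """
    A_true = np.asarray(A_true, dtype=float)
    if A_true.ndim != 2 or (A_true < 0).any() or (A_true > 1).any() \
            or not np.allclose(A_true.sum(axis=1), 1.0, atol=1e-8):
        raise PhantomSpecError("A_true must be row-stochastic with entries in [0, 1]")
    rng = np.random.default_rng(seed)
    X = rng.dirichlet(np.ones(A_true.shape[0]), size=n_scans)
    Y = X @ A_true
    if noise_sigma > 0:
        Y = Y + rng.normal(0.0, noise_sigma, size=Y.shape)
    return X, np.clip(Y, 0.0, 1.0)
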