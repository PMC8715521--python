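"""Population PDCM intensity projections and sLTP sagittal density plots.

Angular projections average attenuation along r per (theta, phi) cell;
radial projections average over all angles at regular radial positions.
Density plots place labeled ROI centers on the sagittal plane (x = 0) in
projected coordinates r' = sqrt(y^2 + z^2), phi' = atan2(z, y), after
radius-proportional sub-sampling over isovolumetric radial bins so the
2D point density is not inflated near the core.  The per-cell density of
sLTP k is its local share relative to its overall share, so values > 1 mark
cells where the pattern concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdcm import PdcmMap


@dataclass
class ProjectionGrid:
    """Mean-HU grids; empty cells are NaN-flagged, never zero-filled."""

    values: np.ndarray            # (n_theta, n_phi) or (n_r,) mean HU
    counts: np.ndarray
    theta_edges: np.ndarray | None = None
    phi_edges: np.ndarray | None = None
    r_edges: np.ndarray | None = None


def angular_projection(ct: np.ndarray, pdcm: PdcmMap, n_theta: int = 36,
                       n_phi: int = 18) -> ProjectionGrid:
    """Mean attenuation per (theta, phi) cell, averaged along r."""
    m = pdcm.mask
    theta_edges = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    phi_edges = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_phi + 1)
    ti = np.clip(np.digitize(pdcm.theta[m], theta_edges) - 1, 0, n_theta - 1)
    pi_ = np.clip(np.digitize(pdcm.phi[m], phi_edges) - 1, 0, n_phi - 1)
    flat = ti * n_phi + pi_
    counts = np.bincount(flat, minlength=n_theta * n_phi).astype(float)
    sums = np.bincount(flat, weights=np.asarray(ct, dtype=float)[m],
                       minlength=n_theta * n_phi)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ProjectionGrid(values=vals.reshape(n_theta, n_phi),
                          counts=counts.reshape(n_theta, n_phi),
                          theta_edges=theta_edges, phi_edges=phi_edges)


def radial_projection(ct: np.ndarray, pdcm: PdcmMap, n_r: int = 60) -> ProjectionGrid:
    """Mean attenuation per radial bin, averaged over all angular directions."""
    m = pdcm.mask
    r_edges = np.linspace(0.0, 1.0, n_r + 1)
    ri = np.clip(np.digitize(np.clip(pdcm.r[m], 0, 1), r_edges) - 1, 0, n_r - 1)
    counts = np.bincount(ri, minlength=n_r).astype(float)
    sums = np.bincount(ri, weights=np.asarray(ct, dtype=float)[m], minlength=n_r)
    vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ProjectionGrid(values=vals, counts=counts, r_edges=r_edges)


def population_mean_projection(grids: list[ProjectionGrid]) -> ProjectionGrid:
    """Cell-wise population mean over subjects (NaN cells excluded per cell)."""
    stack = np.stack([g.values for g in grids])
    counts = np.stack([g.counts for g in grids]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(stack, axis=0)
    first = grids[0]
    return ProjectionGrid(values=vals, counts=counts, theta_edges=first.theta_edges,
                          phi_edges=first.phi_edges, r_edges=first.r_edges)


def population_relative_projection(group: list[ProjectionGrid],
                                   control: list[ProjectionGrid]) -> ProjectionGrid:
    """Cell-wise (group mean - control mean); grids must share binning."""
    g = population_mean_projection(group)
    c = population_mean_projection(control)
    for a, b in ((g.theta_edges, c.theta_edges), (g.phi_edges, c.phi_edges),
                 (g.r_edges, c.r_edges)):
        if (a is None) != (b is None) or (a is not None and not np.array_equal(a, b)):
            raise ValueError("projection binning mismatch between group and control")
    return ProjectionGrid(values=g.values - c.values, counts=g.counts + c.counts,
                          theta_edges=g.theta_edges, phi_edges=g.phi_edges,
                          r_edges=g.r_edges)


@dataclass
class DensityGrid:
    """Per-sLTP density over the sagittal (r', phi') plane."""

    density: np.ndarray           # (N_sltp, nr, nphi); NaN on empty cells
    cell_counts: np.ndarray       # (N_sltp, nr, nphi) sampled-center counts
    rp_edges: np.ndarray
    phip_edges: np.ndarray
    sltp_totals: np.ndarray       # sampled centers per sLTP
    alphas: np.ndarray            # per radial bin sub-sampling ratios
    r_mid: np.ndarray


def density_plot_data(centers_vox: np.ndarray, labels: np.ndarray, pdcm: PdcmMap,
                      n_sltp: int, n_isov: int = 5000, n_r: int = 60,
                      grid_shape: tuple[int, int] = (40, 40),
                      seed: int = 0) -> DensityGrid:
    """Sagittal density data of labeled ROI centers.

    Radial bins are isovolumetric (equal lung-voxel-count quantiles of r);
    per bin i at midpoint r_i, at most alpha_i * n_isov centers are kept
    (alpha_i = r_i / r_{N_r}), sampled without replacement.  Cell densities
    follow the local-share over overall-share ratio and obey the weighted-sum
    normalization (the label-share-weighted sum over sLTPs is 1 in every
    non-empty cell).
    """
    centers_vox = np.asarray(centers_vox, dtype=int)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    lung_r = np.clip(pdcm.r[pdcm.mask], 0.0, 1.0)
    edges = np.quantile(lung_r, np.linspace(0.0, 1.0, n_r + 1))
    edges[0], edges[-1] = 0.0, 1.0
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    alphas = r_mid / r_mid[-1]
    r_c = np.clip(pdcm.r[centers_vox[:, 0], centers_vox[:, 1], centers_vox[:, 2]], 0, 1)
    bins = np.clip(np.searchsorted(edges, r_c, side="right") - 1, 0, n_r - 1)
    keep = []
    for i in range(n_r):
        in_bin = np.flatnonzero(bins == i)
        if in_bin.size == 0:
            continue
        quota = max(1, int(round(alphas[i] * n_isov)))
        if in_bin.size > quota:
            in_bin = rng.choice(in_bin, quota, replace=False)
        keep.append(in_bin)
    keep = np.concatenate(keep) if keep else np.empty(0, dtype=int)
    sub_centers = centers_vox[keep]
    sub_labels = labels[keep]
    sp = np.asarray(pdcm.spacing)
    d = (sub_centers - np.asarray(pdcm.core)) * sp
    y, z = d[:, 1], d[:, 2]
    rp = np.hypot(y, z)
    phip = np.arctan2(z, y)
    nr_g, nphi_g = grid_shape
    rp_edges = np.linspace(0.0, max(rp.max(), 1e-9) * (1 + 1e-9), nr_g + 1)
    phip_edges = np.linspace(phip.min(), phip.max() + 1e-9, nphi_g + 1)
    ri = np.clip(np.digitize(rp, rp_edges) - 1, 0, nr_g - 1)
    pi_ = np.clip(np.digitize(phip, phip_edges) - 1, 0, nphi_g - 1)
    cell = ri * nphi_g + pi_
    n_cells = nr_g * nphi_g
    counts = np.zeros((n_sltp, n_cells))
    for k in range(1, n_sltp + 1):
        sel = sub_labels == k
        if sel.any():
            counts[k - 1] = np.bincount(cell[sel], minlength=n_cells)
    totals = counts.sum(axis=1)                      # |Lambda_k|
    cell_tot = counts.sum(axis=0)                    # |Lambda(r', phi')|
    grand = totals.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        num = counts / totals[:, None]
        den = cell_tot / grand
        density = num / den[None, :]
    density[:, cell_tot == 0] = np.nan
    density[totals == 0, :] = np.nan
    return DensityGrid(density=density.reshape(n_sltp, nr_g, nphi_g),
                       cell_counts=counts.reshape(n_sltp, nr_g, nphi_g),
                       rp_edges=rp_edges, phip_edges=phip_edges,
                       sltp_totals=totals, alphas=alphas, r_mid=r_mid)


def plot_angular_projection(grid: ProjectionGrid, title: str = "",
                            path: str | None = None):
    """Render a (theta, phi) mean-HU map; empty cells stay blank."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    mesh = ax.pcolormesh(np.degrees(grid.theta_edges), np.degrees(grid.phi_edges),
                         grid.values.T, shading="flat", cmap="RdYlBu")
    fig.colorbar(mesh, ax=ax, label="mean HU")
    ax.set_xlabel("theta (deg, 0 = anterior)")
    ax.set_ylabel("phi (deg, + = superior)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_density(grid: DensityGrid, sltp_id: int, title: str = "",
                 path: str | None = None):
    """Render one sLTP's sagittal density map (values > 1 mark concentration)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    mesh = ax.pcolormesh(grid.phip_edges, grid.rp_edges,
                         grid.density[sltp_id - 1], shading="flat",
                         cmap="magma", vmin=0.0)
    fig.colorbar(mesh, ax=ax, label="relative density")
    ax.set_xlabel("phi' (rad)")
    ax.set_ylabel("r' (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def density_normalization_residual(grid: DensityGrid) -> float:
    """Max abs deviation of the weighted-sum normalization identity.

    For every non-empty cell, sum_k density_k * (|Lambda_k| / sum_i |Lambda_i|)
    must equal 1.
    """
    totals = grid.sltp_totals
    grand = totals.sum()
    dens = np.nan_to_num(grid.density.reshape(len(totals), -1), nan=0.0)
    weighted = (dens * (totals / grand)[:, None]).sum(axis=0)
    nonempty = grid.cell_counts.reshape(len(totals), -1).sum(axis=0) > 0
    if not nonempty.any():
        return 0.0
    return float(np.max(np.abs(weighted[nonempty] - 1.0)))
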