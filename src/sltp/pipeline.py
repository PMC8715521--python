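"""End-to-end orchestration of the sLTP discovery pipeline on phantom data.

Stage order: phantom -> PDCM -> ROI sampling + features -> LTP learning
(init, W, lambda tuning, augmentation) -> replacement-graph merging ->
scan labeling -> visualization data -> evaluation.  Every stage derives its
randomness from one global seed through independent child seeds, so a run
is reproducible end to end and per stage.  Artifacts are written to the
output directory with a JSON manifest of parameters and versions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from . import __version__
from .config import RunConfig
from .exceptions import StageError
from .features import (RoiTable, TextonCodebook, collect_codebook_patches,
                       roi_slices, sample_roi_table)
from .labeling import label_scan, sltp_signature
from .ltp import LtpModel, augment_ltps, compute_W, init_ltps, tune_lambda
from .merge import SltpModel, merge_ltps
from .phantom import generate_phantom, three_class_spec, truth_class_of_centers
from .viz import density_normalization_residual, density_plot_data, radial_projection
from .volio import Volume, write_label_map, write_volume

logger = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    import zlib

    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


# ---------------------------------------------------------------------------
# training building blocks (shared by pipeline, tests and evaluation scripts)

def extract_training_set(ct: np.ndarray, pdcms: dict, emph_950: np.ndarray,
                         emph_smooth: np.ndarray, config: RunConfig, seed: int,
                         beta2: int | None = None) -> tuple[RoiTable, TextonCodebook]:
    """SURS-sample ROIs, learn the texton codebook on gated ROIs, fill features."""
    rng = stage_rng(seed, "sample")
    table = sample_roi_table(ct, pdcms, emph_950, emph_smooth, config, rng,
                             codebook=None, beta2=beta2)
    if not table.gated.any():
        raise StageError("sample: no ROI passed the emphysema gates")
    spacing = next(iter(pdcms.values())).spacing
    lungs = np.zeros_like(next(iter(pdcms.values())).mask)
    for p in pdcms.values():
        lungs |= p.mask
    patches = collect_codebook_patches(ct, table, config, stage_rng(seed, "codebook"),
                                       spacing, lung_mask=lungs)
    codebook = build_codebook_safe(patches, config, child_seed(seed, "codebook"))
    half = [max(1, int(round(config.roi_edge_mm / 2.0 / s))) for s in spacing]
    from .features import roi_texture

    for i in np.flatnonzero(table.gated):
        sl = roi_slices(table.centers[i], half)
        table.ft[i] = roi_texture(ct[sl], lungs[sl], codebook)
    return table, codebook


def build_codebook_safe(patches: np.ndarray, config: RunConfig, seed: int) -> TextonCodebook:
    from .features import build_texton_codebook

    k = min(config.n_textons, patches.shape[0])
    if k < config.n_textons:
        raise StageError(f"codebook: only {patches.shape[0]} patches for "
                         f"{config.n_textons} textons")
    return build_texton_codebook(patches, k=config.n_textons, seed=seed,
                                 patch_edge=config.texton_size)


@dataclass
class TrainResult:
    init_model: LtpModel
    model: LtpModel
    w: float
    lam_star: float
    lambda_trace: list


def fit_ltps(FT: np.ndarray, FS: np.ndarray, config: RunConfig, seed: int) -> TrainResult:
    """Initial chi2 clustering, W, data-driven lambda and final augmentation."""
    init = init_ltps(FT, config.n_ltp, seed=child_seed(seed, "ltp-init"))
    w = compute_W(FT, FS)
    lam_star, trace = tune_lambda(FT, FS, init, w, grid=config.lambda_grid,
                                  l_t=config.l_t)
    model = augment_ltps(FT, FS, init, lam_star, w, penalty=True)
    return TrainResult(init_model=init, model=model, w=w, lam_star=lam_star,
                       lambda_trace=trace)


def train_sltp_model(ct: np.ndarray, pdcms: dict, emph_950: np.ndarray,
                     emph_smooth: np.ndarray, config: RunConfig, seed: int,
                     beta2: int | None = None):
    """Full training: sampling, features, LTP learning and merging.

    Returns ``(sltp_model, train_result, table, codebook)``.
    """
    table, codebook = extract_training_set(ct, pdcms, emph_950, emph_smooth,
                                           config, seed, beta2=beta2)
    gated = table.subset(table.gated)
    tr = fit_ltps(gated.ft, gated.fs, config, seed)
    sltp, graph, part = merge_ltps(tr.model, gated.ft, gated.fs, gated.mean_hu,
                                   threshold=config.edge_threshold,
                                   seed=child_seed(seed, "merge"))
    return sltp, tr, table, codebook


def retrain_on_subset(gated: RoiTable, keep: np.ndarray, config: RunConfig,
                      seed: int) -> SltpModel:
    """Retrain LTPs + merge on a ROI subset (features are reused, not resampled)."""
    sub = gated.subset(keep)
    cfg_n = min(config.n_ltp, len(sub))
    init = init_ltps(sub.ft, cfg_n, seed=child_seed(seed, "ltp-init"))
    w = compute_W(sub.ft, sub.fs)
    lam_star, _ = tune_lambda(sub.ft, sub.fs, init, w, grid=config.lambda_grid,
                              l_t=config.l_t)
    model = augment_ltps(sub.ft, sub.fs, init, lam_star, w, penalty=True)
    sltp, _, _ = merge_ltps(model, sub.ft, sub.fs, sub.mean_hu,
                            threshold=config.edge_threshold,
                            seed=child_seed(seed, "merge"))
    return sltp


# ---------------------------------------------------------------------------
# phantom cohort study (scaled-down analogue of multi-scan training)

def phantom_study_config(seed: int = 0, **overrides) -> RunConfig:
    """Configuration for desk-scale phantom studies.

    Compared to the full-cohort defaults, the initial pattern count and the
    per-stack sampling density are rescaled so that cluster occupancy
    (ROIs per LTP) stays in the same regime as cohort training while the
    problem fits a single workstation: six initial LTPs for three planted
    classes plus boundary mixtures, and beta2 = 10 samples per stack on the
    coarse 2 mm grid.
    """
    params = dict(n_ltp=6, beta2=10, seed=seed)
    params.update(overrides)
    return RunConfig(**params)


@dataclass
class ScanData:
    """One phantom scan with masks, segmentations, PDCMs and its ROI table."""

    scan_id: str
    bundle: dict
    ct: np.ndarray
    lungs: np.ndarray
    emph_950: np.ndarray
    emph_smooth: np.ndarray
    table: RoiTable


def concat_tables(tables: list[RoiTable]) -> RoiTable:
    fields = ("centers", "side", "pem_950", "pem_smooth", "ft", "fs",
              "bin_index", "mean_hu", "scan_id")
    return RoiTable(*[np.concatenate([getattr(t, f) for t in tables]) for f in fields])


def build_cohort(config: RunConfig, n_scans: int, seed: int,
                 geometry_jitter: float = 0.08) -> dict:
    """Generate a phantom cohort with one shared texton codebook.

    Each scan draws its own noise, blob fields and mildly jittered lung
    geometry; the codebook is learned on patches pooled over all scans'
    emphysema-gated ROIs and frozen for every feature computation, mirroring
    a train-once codebook protocol.  Returns ``{"scans": [ScanData...],
    "codebook": TextonCodebook}``.
    """
    from dataclasses import replace as dc_replace

    from .features import roi_texture, segment_emphysema_smooth, segment_emphysema_threshold

    jitter_rng = np.random.default_rng(child_seed(seed, "geometry"))
    scans: list[ScanData] = []
    patch_chunks = []
    for i in range(n_scans):
        axes = np.array([32.0, 52.0, 88.0])
        axes = axes * (1.0 + jitter_rng.uniform(-geometry_jitter, geometry_jitter, 3))
        spec = three_class_spec(seed=child_seed(seed, f"phantom{i}"))
        spec = dc_replace(spec, lung_half_axes_mm=tuple(axes), **(config.phantom or {}))
        bundle = generate_phantom(spec)
        ct = bundle["ct"].voxels
        lungs = bundle["lung_masks"]["right"] | bundle["lung_masks"]["left"]
        e950 = segment_emphysema_threshold(ct, lungs, config.emph_threshold_hu)
        esm = segment_emphysema_smooth(ct, lungs, seed=child_seed(seed, f"hmmf{i}"))
        table = sample_roi_table(ct, bundle["pdcms"], e950, esm, config,
                                 stage_rng(seed, f"sample{i}"), codebook=None,
                                 scan_id=f"scan{i}")
        patch_chunks.append(collect_codebook_patches(
            ct, table, config, stage_rng(seed, f"patches{i}"),
            bundle["ct"].spacing, lung_mask=lungs))
        scans.append(ScanData(scan_id=f"scan{i}", bundle=bundle, ct=ct, lungs=lungs,
                              emph_950=e950, emph_smooth=esm, table=table))
    patches = np.concatenate(patch_chunks, axis=0)
    if patches.shape[0] > config.max_codebook_patches:
        sel = stage_rng(seed, "patch-subsample").choice(
            patches.shape[0], config.max_codebook_patches, replace=False)
        patches = patches[sel]
    codebook = build_codebook_safe(patches, config, child_seed(seed, "codebook"))
    spacing = scans[0].bundle["ct"].spacing
    half = [max(1, int(round(config.roi_edge_mm / 2.0 / s))) for s in spacing]
    for scan in scans:
        for i in np.flatnonzero(scan.table.gated):
            sl = roi_slices(scan.table.centers[i], half)
            scan.table.ft[i] = roi_texture(scan.ct[sl], scan.lungs[sl], codebook)
    return {"scans": scans, "codebook": codebook}


def cohort_training_table(scans: list[ScanData], train_ids: list[str]) -> RoiTable:
    """Pooled emphysema-gated training ROIs of the selected scans."""
    return concat_tables([s.table.subset(s.table.gated) for s in scans
                          if s.scan_id in train_ids])


def subset_reproducibility(train: RoiTable, test: RoiTable, reference: SltpModel,
                           config: RunConfig, seed: int) -> dict:
    """Label-reproducibility of sLTP learning against scan-level retraining.

    One retrained model per training scan (that scan's ROIs eliminated, the
    paper's leave-25%-out design at cohort size four); each model labels the
    common test ROI set and is Hungarian-matched to the reference labeling.
    Returns R_ln against the reference and the pairwise mean/sd among the
    retrained models.
    """
    from .evalstats import reproducibility_ln, reproducibility_ln_pairwise
    from .labeling import assign_sltp

    ref_labels = assign_sltp(test.ft, test.fs, reference)
    scan_ids = sorted(set(train.scan_id))
    subset_labels = []
    n_sltps = []
    for c, sid in enumerate(scan_ids):
        keep = train.scan_id != sid
        model = retrain_on_subset(train, keep, config, child_seed(seed, f"subset{c}"))
        n_sltps.append(model.n_sltp)
        subset_labels.append(assign_sltp(test.ft, test.fs, model))
    r_ln = reproducibility_ln(ref_labels, subset_labels)
    r_pair, r_sd = reproducibility_ln_pairwise(subset_labels)
    return {"r_ln": float(r_ln), "r_ln_pairwise": float(r_pair),
            "r_ln_pairwise_sd": float(r_sd), "n_sltp_subsets": n_sltps,
            "reference_labels": ref_labels, "subset_labels": subset_labels}


# ---------------------------------------------------------------------------
# artifact helpers

def save_roi_table(table: RoiTable, path: str) -> None:
    np.savez_compressed(path, centers=table.centers,
                        side=table.side.astype("U8"), pem_950=table.pem_950,
                        pem_smooth=table.pem_smooth, ft=table.ft, fs=table.fs,
                        bin_index=table.bin_index, mean_hu=table.mean_hu,
                        scan_id=table.scan_id.astype("U32"))


def load_roi_table(path: str) -> RoiTable:
    z = np.load(path)
    return RoiTable(centers=z["centers"], side=z["side"].astype(object),
                    pem_950=z["pem_950"], pem_smooth=z["pem_smooth"], ft=z["ft"],
                    fs=z["fs"], bin_index=z["bin_index"], mean_hu=z["mean_hu"],
                    scan_id=z["scan_id"].astype(object))


def save_sltp_model(model: SltpModel, path: str) -> None:
    np.savez_compressed(path, ft_centroids=model.ft_centroids,
                        fs_centroids=model.fs_centroids, labels=model.labels,
                        mean_hu=model.mean_hu, lam=model.lam, w=model.w,
                        member_sizes=np.array([len(m) for m in model.member_ltps]),
                        member_flat=np.array([x for m in model.member_ltps for x in m]))


def load_sltp_model(path: str) -> SltpModel:
    z = np.load(path)
    sizes = z["member_sizes"]
    flat = list(z["member_flat"])
    members, pos = [], 0
    for s in sizes:
        members.append([int(x) for x in flat[pos:pos + int(s)]])
        pos += int(s)
    return SltpModel(ft_centroids=z["ft_centroids"], fs_centroids=z["fs_centroids"],
                     member_ltps=members, labels=z["labels"], mean_hu=z["mean_hu"],
                     lam=float(z["lam"]), w=float(z["w"]))


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(config: RunConfig, outdir: str, seed: int | None = None) -> dict:
    """Run the whole phantom study and write artifacts + manifest to ``outdir``.

    Deterministic given the seed: the same configuration and seed produce
    byte-identical label maps.  Any stage failure raises :class:`StageError`
    with the stage name in the message.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    os.makedirs(outdir, exist_ok=True)
    results: dict = {"seed": seed}

    def run_stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc

    def _phantom():
        spec_kwargs = dict(config.phantom or {})
        spec = three_class_spec(seed=child_seed(seed, "phantom"), **spec_kwargs)
        bundle = generate_phantom(spec)
        write_volume(bundle["ct"], os.path.join(outdir, "ct.nii.gz"))
        for side in ("right", "left"):
            write_label_map(Volume(bundle["lung_masks"][side].astype(np.int16),
                                   spec.spacing),
                            os.path.join(outdir, f"lung_{side}.nii.gz"))
        write_label_map(bundle["truth_labels"], os.path.join(outdir, "truth_labels.nii.gz"))
        return bundle

    bundle = run_stage("phantom", _phantom)
    ct = bundle["ct"].voxels
    pdcms = bundle["pdcms"]
    lungs = bundle["lung_masks"]["right"] | bundle["lung_masks"]["left"]

    def _pdcm():
        with open(os.path.join(outdir, "pdcm.json"), "w") as fh:
            json.dump({s: p.summary() for s, p in pdcms.items()}, fh, indent=2)
        return pdcms

    run_stage("pdcm", _pdcm)

    def _segment():
        from .features import segment_emphysema_smooth, segment_emphysema_threshold

        e950 = segment_emphysema_threshold(ct, lungs, config.emph_threshold_hu)
        esm = segment_emphysema_smooth(ct, lungs, seed=child_seed(seed, "hmmf"))
        return e950, esm

    emph_950, emph_smooth = run_stage("segment", _segment)

    def _sample():
        table, codebook = extract_training_set(ct, pdcms, emph_950, emph_smooth,
                                               config, seed)
        save_roi_table(table, os.path.join(outdir, "rois.npz"))
        np.savez_compressed(os.path.join(outdir, "codebook.npz"),
                            centroids=codebook.centroids,
                            patch_edge=codebook.patch_edge)
        return table, codebook

    table, codebook = run_stage("sample", _sample)
    gated = table.subset(table.gated)

    def _train():
        tr = fit_ltps(gated.ft, gated.fs, config, seed)
        with open(os.path.join(outdir, "lambda_trace.csv"), "w") as fh:
            fh.write("lambda,delta_ssw_t_percent\n")
            for lam, delta in tr.lambda_trace:
                fh.write(f"{lam},{delta}\n")
        return tr

    tr = run_stage("train", _train)

    def _merge():
        sltp, graph, part = merge_ltps(tr.model, gated.ft, gated.fs, gated.mean_hu,
                                       threshold=config.edge_threshold,
                                       seed=child_seed(seed, "merge"))
        save_sltp_model(sltp, os.path.join(outdir, "sltp_model.npz"))
        with open(os.path.join(outdir, "merge_graph.csv"), "w") as fh:
            fh.write("i,j,weight\n")
            for u, v, w in graph.edges(data="weight"):
                fh.write(f"{u},{v},{w}\n")
        return sltp

    sltp = run_stage("merge", _merge)
    results["n_sltp"] = sltp.n_sltp
    results["lambda_star"] = tr.lam_star

    def _label():
        labels = label_scan(ct, pdcms, emph_950, emph_smooth, sltp, codebook,
                            config, stage_rng(seed, "label"))
        write_label_map(labels, os.path.join(outdir, "label_map.nii.gz"))
        sig = sltp_signature(labels, lungs, sltp.n_sltp)
        with open(os.path.join(outdir, "signature.csv"), "w") as fh:
            fh.write("code,percent\n")
            for code, pct in enumerate(sig):
                fh.write(f"{code},{pct}\n")
        return labels, sig

    labels, signature = run_stage("label", _label)
    results["signature"] = [float(x) for x in signature]

    def _viz():
        grids = {}
        for side in ("right", "left"):
            sel = gated.side == side
            if not sel.any():
                continue
            grids[side] = density_plot_data(
                gated.centers[sel], sltp.labels[sel], pdcms[side], sltp.n_sltp,
                n_isov=config.n_isov, n_r=config.n_r,
                seed=child_seed(seed, "viz"))
        radial = radial_projection(ct, pdcms["right"], n_r=config.n_r)
        np.savez_compressed(os.path.join(outdir, "viz.npz"),
                            radial_values=radial.values, radial_counts=radial.counts)
        from .viz import angular_projection, plot_angular_projection

        ang = angular_projection(ct, pdcms["right"])
        plot_angular_projection(ang, title="right lung, mean HU",
                                path=os.path.join(outdir, "angular_right.png"))
        return grids

    grids = run_stage("viz", _viz)
    results["density_norm_residual"] = max(
        (density_normalization_residual(g) for g in grids.values()), default=0.0)

    def _eval():
        from .evalstats import matched_ari

        truth = truth_class_of_centers(gated.centers, bundle["truth_labels"].voxels)
        planted = truth > 0
        ari = matched_ari(sltp.labels[planted], truth[planted]) if planted.any() else float("nan")
        return {"planted_ari": float(ari), "n_gated_rois": int(len(gated))}

    results.update(run_stage("eval", _eval))

    manifest = {"version": __version__, "config": config.to_dict(),
                "seed": seed, "results": {k: v for k, v in results.items()
                                          if not isinstance(v, np.ndarray)}}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return {**results, "sltp_model": sltp, "train": tr, "table": table,
            "codebook": codebook, "bundle": bundle, "label_map": labels}
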