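"""Thresholding of voxelwise statistic maps and cluster tables.

Whole-brain inference: voxelwise two-sided p < ``p_voxel``, connected
components under first-nearest-neighbour adjacency (NN1: voxels touch by
faces) labelled separately for positive and negative statistics, clusters
of size >= k retained. ROI inference: Benjamini-Hochberg FDR over the
ROI's voxel p-values, surviving voxels clustered the same way with a
smaller extent threshold. A subject-level permutation scheme provides a
data-driven cluster-extent null in place of smoothness-based Monte-Carlo
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VoxelStatMap",
    "cluster_threshold",
    "roi_fdr",
    "permutation_cluster_null",
    "save_stat_map",
]

#: NN1 adjacency: 6-connectivity, faces touch
NN1 = ndimage.generate_binary_structure(3, 1)


@dataclass
class VoxelStatMap:
    """Per-voxel estimate / statistic / p-value on a masked grid."""

    estimate: np.ndarray  # 3D, NaN outside mask
    stat: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # boolean 3D
    affine: np.ndarray
    effect: str = ""

    def __post_init__(self):
        if not (self.estimate.shape == self.stat.shape == self.p.shape == self.mask.shape):
            raise ValueError("map arrays must share one grid")


def _clusters_for_sign(supra: np.ndarray, stat: np.ndarray, k: int, sign: str, affine):
    labelled, n = ndimage.label(supra, structure=NN1)
    rows, keep = [], np.zeros_like(labelled)
    next_id = 0
    for lab in range(1, n + 1):
        comp = labelled == lab
        size = int(comp.sum())
        if size < k:
            continue
        next_id += 1
        keep[comp] = next_id
        vals = np.where(comp, np.abs(stat), -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        world = (affine @ np.array([*peak, 1.0]))[:3]
        rows.append(
            {
                "cluster_id": next_id,
                "sign": sign,
                "size": size,
                "peak_stat": float(stat[peak]),
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "peak_x": world[0],
                "peak_y": world[1],
                "peak_z": world[2],
            }
        )
    return rows, keep


def cluster_threshold(
    statmap: VoxelStatMap, p_voxel: float = 0.001, k: int = 20
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-extent thresholding under NN1 (face) adjacency.

    Suprathreshold voxels (p < ``p_voxel``) are labelled separately for
    positive and negative statistics; components with >= ``k`` voxels are
    kept. Returns the cluster table and a labelled volume (positive
    clusters numbered 1..m, negative clusters -1..-m').
    """
    if not statmap.mask.any():
        raise ValueError("empty mask")
    with np.errstate(invalid="ignore"):
        supra = (statmap.p < p_voxel) & statmap.mask
    rows_pos, lab_pos = _clusters_for_sign(
        supra & (statmap.stat > 0), statmap.stat, k, "positive", statmap.affine
    )
    rows_neg, lab_neg = _clusters_for_sign(
        supra & (statmap.stat < 0), statmap.stat, k, "negative", statmap.affine
    )
    table = pd.DataFrame(rows_pos + rows_neg)
    labelled = lab_pos.astype(int) - lab_neg.astype(int)
    return table, labelled


def roi_fdr(
    statmap: VoxelStatMap, roi_mask: np.ndarray, q: float = 0.05, k: int = 5
) -> tuple[pd.DataFrame, np.ndarray]:
    """Benjamini-Hochberg FDR within an ROI, then NN1 extent filter."""
    roi = np.asarray(roi_mask, dtype=bool) & statmap.mask
    if not roi.any():
        raise ValueError("empty ROI")
    pvals = statmap.p[roi]
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    survive = np.zeros_like(roi)
    survive[roi] = reject
    rows_pos, lab_pos = _clusters_for_sign(
        survive & (statmap.stat > 0), statmap.stat, k, "positive", statmap.affine
    )
    rows_neg, lab_neg = _clusters_for_sign(
        survive & (statmap.stat < 0), statmap.stat, k, "negative", statmap.affine
    )
    return pd.DataFrame(rows_pos + rows_neg), lab_pos.astype(int) - lab_neg.astype(int)


def permutation_cluster_null(
    mapset,
    subject_data,
    similarity_fn,
    group_sim=None,
    n_perm: int = 200,
    p_voxel: float = 0.001,
    seed: int = 0,
    percentile: float = 95.0,
):
    """Permutation null for the maximum suprathreshold cluster size.

    Respecting the crossed pair dependence, whole subjects' behavioural
    data (``subject_data``: Series or DataFrame indexed by subject) are
    permuted, the pair similarity rebuilt with ``similarity_fn``, the
    voxelwise LME-CRE refitted, and the maximum NN1 cluster size of the
    similarity effect at the voxelwise threshold recorded. ``group_sim``
    (a group-code SimilarityMatrix) optionally adds the group main effect
    and interaction to each refit. Returns ``(k_threshold, null_sizes)``
    where ``k_threshold`` is the requested percentile of the null sizes.
    """
    from .cre import build_pair_design, fit_cre_map
    from .similarity import grand_mean_centre

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    sizes = np.zeros(n_perm, dtype=int)
    index = subject_data.index
    for b in range(n_perm):
        perm = rng.permutation(len(index))
        shuffled = subject_data.iloc[perm]
        shuffled.index = index
        sim = grand_mean_centre(similarity_fn(shuffled))
        fixed = build_pair_design(
            sim.subject_ids,
            similarity=sim,
            group=group_sim,
            interaction=group_sim is not None,
        )
        stat_maps, _ = fit_cre_map(mapset, fixed)
        table, _ = cluster_threshold(stat_maps["similarity"], p_voxel=p_voxel, k=1)
        sizes[b] = int(table["size"].max()) if len(table) else 0
    return int(np.percentile(sizes, percentile)), sizes


def save_stat_map(statmap: VoxelStatMap, path, kind: str = "stat") -> None:
    """Write one component of a stat map as NIfTI (stat | estimate | p | neglog10p)."""
    import nibabel as nib

    if kind == "neglog10p":
        with np.errstate(divide="ignore", invalid="ignore"):
            data = -np.log10(statmap.p)
    else:
        data = getattr(statmap, kind if kind != "stat" else "stat")
    nib.save(nib.Nifti1Image(np.nan_to_num(data).astype(np.float32), statmap.affine), str(path))
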