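"""Detection and quantification of stimulus-specific adaptation (SSA).

A voxel shows SSA when it both adapts (its response to the first,
unadapted standard exceeds the mean adapted-standard response) and
detects deviants (its response to the least-expected deviant, dev4,
exceeds the mean adapted-standard response).  Both effects are tested
voxel-wise with right-tailed rank-sum tests across participants, after
averaging betas over runs.  The conjunction p-value is the maximum of
the two uncorrected p-values; significance is controlled by
Benjamini–Hochberg FDR across all ROI voxels, with peak-level
family-wise correction (Bonferroni within ROI, Holm across ROIs).

SSA magnitude is summarised by the index
SSAi = (dev4 − 0.5 std1 − 0.5 std2) / (dev4 + 0.5 std1 + 0.5 std2)
computed on min–max-normalised, participant/run-averaged betas; it is
bounded in [−1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .glm import BetaMaps

__all__ = [
    "ContrastResult",
    "Cluster",
    "SSAMap",
    "voxelwise_contrast_test",
    "ssa_conjunction",
    "extract_clusters",
    "ssai_map",
]

#: Contrast condition and weights on (std0, std1, std2) / (dev4, std1, std2)
CONTRAST_WEIGHTS = {
    "adaptation": {"std0": 1.0, "std1": -0.5, "std2": -0.5},
    "deviant_detection": {"dev4": 1.0, "std1": -0.5, "std2": -0.5},
}


def voxelwise_contrast_test(maps: BetaMaps, contrast: str) -> np.ndarray:
    """Right-tailed rank-sum p-value per voxel across participants.

    The participant sample of the target condition (std0 for adaptation,
    dev4 for deviant detection) is compared against the participant
    sample of the mean adapted standard, 0.5 std1 + 0.5 std2, after
    betas are averaged over runs.  Exact null for small cohorts,
    tie-corrected normal approximation otherwise.
    """
    if contrast not in CONTRAST_WEIGHTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if maps.n_participants < 3:
        raise ValueError("need at least 3 participants")
    avg = maps.run_average()                      # (S, C, V)
    target = "std0" if contrast == "adaptation" else "dev4"
    x = avg[:, maps.condition_index(target), :]
    y = 0.5 * avg[:, maps.condition_index("std1"), :] + \
        0.5 * avg[:, maps.condition_index("std2"), :]
    method = "exact" if maps.n_participants <= 8 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             axis=0)
    return np.asarray(res.pvalue)


@dataclass(frozen=True)
class ContrastResult:
    """Voxel-wise SSA conjunction with FDR and peak-level correction."""

    p_adaptation: np.ndarray
    p_deviant_detection: np.ndarray
    p_ssa: np.ndarray                   # elementwise max of the two
    q_ssa: np.ndarray                   # BH-adjusted
    significant_mask: np.ndarray        # BH at alpha
    alpha: float
    peak_p: dict[str, float]            # per ROI, Bonferroni + Holm corrected
    roi_labels: np.ndarray
    roi_names: dict[int, str]

    @property
    def significant_rois(self) -> list[str]:
        """ROIs whose peak survives family-wise correction at alpha."""
        return [r for r, p in self.peak_p.items() if p < self.alpha]


def ssa_conjunction(p_adapt: np.ndarray, p_dev: np.ndarray,
                    roi_labels: np.ndarray, roi_names: dict[int, str],
                    alpha: float = 0.05) -> ContrastResult:
    """Conjoin the two contrasts and correct for multiple comparisons.

    P_SSA = max(P_adaptation, P_deviant detection) per voxel;
    Benjamini–Hochberg across all ROI voxels at ``alpha`` gives the
    significance mask.  Peak-level p per ROI is the minimum P_SSA
    Bonferroni-corrected by the ROI's voxel count, then Holm-corrected
    across ROIs.
    """
    p_adapt = np.asarray(p_adapt, dtype=float)
    p_dev = np.asarray(p_dev, dtype=float)
    if p_adapt.shape != p_dev.shape or p_adapt.shape != roi_labels.shape:
        raise ValueError("p-maps and ROI labels must share one shape")
    p_ssa = np.maximum(p_adapt, p_dev)
    reject, q_ssa, _, _ = multipletests(p_ssa, alpha=alpha, method="fdr_bh")

    rois = sorted(roi_names)
    bonf = []
    for lab in rois:
        sel = roi_labels == lab
        n_vox = int(sel.sum())
        bonf.append(min(1.0, float(p_ssa[sel].min()) * n_vox) if n_vox
                    else 1.0)
    _, holm, _, _ = multipletests(bonf, alpha=alpha, method="holm")
    peak_p = {roi_names[lab]: float(h) for lab, h in zip(rois, holm)}
    return ContrastResult(p_adaptation=p_adapt, p_deviant_detection=p_dev,
                          p_ssa=p_ssa, q_ssa=q_ssa, significant_mask=reject,
                          alpha=alpha, peak_p=peak_p, roi_labels=roi_labels,
                          roi_names=dict(roi_names))


@dataclass(frozen=True)
class Cluster:
    roi: str
    size: int
    peak_coord: tuple[int, int, int]
    peak_p: float                       # Bonferroni-corrected within ROI


def extract_clusters(mask: np.ndarray, label_volume: np.ndarray,
                     p_volume: np.ndarray,
                     roi_names: dict[int, str]) -> list[Cluster]:
    """Connected components (26-connectivity) of a mask within each ROI.

    Each cluster reports its size, the coordinate of its peak (minimum
    conjunction p, ties broken by lowest linear index) and the peak p
    Bonferroni-corrected by the ROI voxel count.
    """
    if mask.shape != label_volume.shape or mask.shape != p_volume.shape:
        raise ValueError("mask, labels, and p-volume must share one shape")
    structure = np.ones((3, 3, 3), dtype=bool)
    clusters: list[Cluster] = []
    for lab in sorted(roi_names):
        roi_mask = label_volume == lab
        n_roi = int(roi_mask.sum())
        comp, n_comp = ndimage.label(mask & roi_mask, structure=structure)
        for c in range(1, n_comp + 1):
            sel = comp == c
            p_in = np.where(sel, p_volume, np.inf)
            flat_peak = int(np.argmin(p_in))        # first of ties in C order
            coord = np.unravel_index(flat_peak, mask.shape)
            clusters.append(Cluster(
                roi=roi_names[lab], size=int(sel.sum()),
                peak_coord=tuple(int(i) for i in coord),
                peak_p=min(1.0, float(p_volume[coord]) * n_roi)))
    return clusters


def to_volume(values: np.ndarray, coords: np.ndarray,
              shape: tuple[int, ...], fill: float = np.nan) -> np.ndarray:
    """Scatter a per-voxel vector back into a 3D volume."""
    vol = np.full(shape, fill, dtype=float)
    vol[tuple(coords.T)] = values
    return vol


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster summary: ROI, size, peak coordinate, corrected peak p."""
    return pd.DataFrame([
        {"roi": c.roi, "size": c.size,
         "peak_x": c.peak_coord[0], "peak_y": c.peak_coord[1],
         "peak_z": c.peak_coord[2], "peak_p": c.peak_p}
        for c in clusters])


@dataclass(frozen=True)
class SSAMap:
    """SSA index per voxel with validity flags."""

    ssai: np.ndarray                    # NaN where undefined
    defined: np.ndarray                 # boolean
    roi_labels: np.ndarray
    roi_names: dict[int, str]


def ssai_map(maps: BetaMaps) -> SSAMap:
    """SSA index from min–max-normalised dev4/std1/std2 betas.

    Per voxel, the pooled (dev4, std1, std2) × (participant, run) values
    are rescaled to [0, 1], averaged per condition, and combined as
    SSAi = (dev4 − 0.5 std1 − 0.5 std2) / (dev4 + 0.5 std1 + 0.5 std2).
    Voxels with a degenerate range or zero denominator are flagged
    undefined and excluded (NaN).
    """
    idx = [maps.condition_index(c) for c in ("dev4", "std1", "std2")]
    vals = maps.betas[:, :, idx, :]                      # (S, R, 3, V)
    pooled = vals.reshape(-1, vals.shape[-1])            # (S*R*3, V)
    mn, mx = pooled.min(axis=0), pooled.max(axis=0)
    rng = mx - mn
    degenerate = rng <= 0
    rng_safe = np.where(degenerate, 1.0, rng)
    norm = (vals - mn) / rng_safe                        # broadcast over V
    d, s1, s2 = norm.mean(axis=(0, 1))                   # (3, V) -> rows
    num = d - 0.5 * s1 - 0.5 * s2
    den = d + 0.5 * s1 + 0.5 * s2
    undefined = degenerate | (np.abs(den) < 1e-12)
    ssai = np.where(undefined, np.nan,
                    num / np.where(undefined, 1.0, den))
    return SSAMap(ssai=ssai, defined=~undefined,
                  roi_labels=maps.roi_labels, roi_names=dict(maps.roi_names))
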