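"""Group-level inference on subject accuracy maps.

Subject-level delay-period accuracy maps (mean Fisher-z over the six
retention time bins) are smoothed with a Gaussian kernel (8 mm FWHM by
default) and entered into a voxelwise one-sample t-test against 0, the
chance level of Fisher-z accuracy.  Family-wise error is controlled at the
cluster level: voxels exceeding the t-quantile of a cluster-defining
threshold (p < 0.001 one-sided) are grouped with 26-connectivity, and each
cluster's extent is referred to the permutation null distribution of the
maximum cluster size obtained by randomly sign-flipping the subject maps —
a distribution-free substitute for parametric random-field cluster
correction, exact under the null symmetry of chance-level accuracy maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .firstlevel import DELAY_BINS

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class GroupInput:
    """Per-subject accuracy maps on a shared grid."""

    subject_maps: list  # one dict {time_bin -> 3D array} per subject
    mask: np.ndarray
    voxel_mm: float = 3.0
    fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        if len(self.subject_maps) < 3:
            raise ValueError("group inference needs at least 3 subjects")
        shapes = {m.shape for maps in self.subject_maps for m in maps.values()}
        if len(shapes) != 1 or shapes.pop() != self.mask.shape:
            raise ValueError("all subject maps must share the mask's grid")


def smooth_map(volume: np.ndarray, fwhm_mm: float, voxel_mm: float,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Gaussian smoothing with mask-aware renormalization.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in voxel units.  Values outside
    the mask (or NaN) do not bleed in: the smoothed map is divided by the
    smoothed mask so constant regions stay constant up to the border.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.array(volume, dtype=float)
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    vol = np.array(volume, dtype=float)
    valid = np.isfinite(vol)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    vol[~valid] = 0.0
    num = ndimage.gaussian_filter(vol, sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full(vol.shape, np.nan)
    nz = den > 1e-12
    out[nz] = num[nz] / den[nz]
    out[~valid] = np.nan
    return out


def subject_delay_means(group: GroupInput, delay_bins=DELAY_BINS,
                        smooth: bool = True) -> np.ndarray:
    """Per-subject smoothed delay-window mean maps, shape (n_subjects, x, y, z)."""
    out = []
    for maps in group.subject_maps:
        missing = [b for b in delay_bins if b not in maps]
        if missing:
            raise ValueError(f"subject is missing time bins {missing}")
        mean_map = np.mean([maps[b] for b in delay_bins], axis=0)
        if smooth:
            mean_map = smooth_map(mean_map, group.fwhm_mm, group.voxel_mm, group.mask)
        out.append(mean_map)
    return np.stack(out)


def one_sample_t(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t against 0; zero-variance voxels get +/-inf."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    if np.any(zero_var & (mean != 0)):
        t[zero_var] = np.sign(mean[zero_var]) * np.inf
    return t


def delay_t_map(group: GroupInput, delay_bins=DELAY_BINS) -> np.ndarray:
    """Group t-map of delay-period accuracy against the chance level 0.

    Implements the delay-window t-contrast of the second-level model as a
    one-sample t-test on subject delay-bin means.
    """
    return one_sample_t(subject_delay_means(group, delay_bins))


@dataclass
class ClusterTable:
    """Supra-threshold clusters with permutation-corrected p-values.

    ``labels`` holds the 26-connectivity cluster id per voxel (0 elsewhere);
    ids match the table's ``cluster_id`` column.
    """

    table: pd.DataFrame  # cluster_id, size_vox, peak_ijk, peak_t, p_fwe
    cdt_p: float
    alpha: float
    t_threshold: float
    n_perm: int
    labels: np.ndarray | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_fwe"] < self.alpha]

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        if self.labels is None:
            raise ValueError("cluster labels were not retained")
        return self.labels == cluster_id


def _cluster_sizes(t_map: np.ndarray, threshold: float, mask: np.ndarray):
    supra = (t_map > threshold) & mask
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def cluster_fwe(
    subject_maps: np.ndarray,
    mask: np.ndarray,
    cdt_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterTable:
    """Cluster-extent FWE correction by sign-flip max-statistic permutation.

    ``subject_maps`` holds one delay-mean map per subject.  The observed
    t-map is thresholded at the one-sided t-quantile of ``cdt_p``;
    26-connected clusters are formed, and the null distribution of the
    maximum cluster size is built from ``n_perm`` random sign-flips of the
    subject maps (valid because chance-level Fisher-z accuracy maps are
    symmetric about 0).  Corrected p = rank of the observed size in the
    max-size null.  An empty table is a valid (null) result.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    subject_maps = np.asarray(subject_maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_sub = subject_maps.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    df = n_sub - 1
    t_thresh = float(stats.t.ppf(1.0 - cdt_p, df))

    flat = subject_maps.reshape(n_sub, -1)
    finite = np.all(np.isfinite(flat), axis=0).reshape(mask.shape)
    mask = mask & finite

    t_obs = one_sample_t(subject_maps)
    labels, sizes = _cluster_sizes(t_obs, t_thresh, mask)

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        t_perm = one_sample_t(subject_maps * signs[:, None, None, None])
        _, perm_sizes = _cluster_sizes(t_perm, t_thresh, mask)
        max_null[p] = perm_sizes.max() if perm_sizes.size else 0

    rows = []
    for c, size in enumerate(sizes, start=1):
        in_cluster = labels == c
        peak_flat = np.nanargmax(np.where(in_cluster, t_obs, -np.inf))
        peak_ijk = np.unravel_index(peak_flat, mask.shape)
        p_fwe = (1.0 + np.sum(max_null >= size)) / (n_perm + 1.0)
        rows.append(
            {
                "cluster_id": c,
                "size_vox": int(size),
                "peak_ijk": tuple(int(i) for i in peak_ijk),
                "peak_t": float(t_obs[peak_ijk]),
                "p_fwe": float(p_fwe),
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size_vox", "peak_ijk", "peak_t", "p_fwe"]
    )
    table = table.sort_values("size_vox", ascending=False).reset_index(drop=True)
    return ClusterTable(table, cdt_p, alpha, t_thresh, n_perm, labels)


def group_delay_inference(
    group: GroupInput,
    delay_bins=DELAY_BINS,
    cdt_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    report_uncorrected: bool = False,
) -> tuple[np.ndarray, ClusterTable]:
    """Smooth, contrast the delay window, and correct at the cluster level.

    With ``report_uncorrected`` the table keeps every supra-threshold
    cluster regardless of corrected p (exploratory reporting).
    """
    maps = subject_delay_means(group, delay_bins)
    t_map = one_sample_t(maps)
    result = cluster_fwe(maps, group.mask, cdt_p, alpha, n_perm, seed)
    if report_uncorrected:
        result = ClusterTable(result.table, cdt_p, 1.0, result.t_threshold, n_perm)
    return t_map, result
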