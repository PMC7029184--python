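"""Time-resolved searchlight decoding of numerosity with support vector regression.

For every brain voxel, the parameter estimates of all voxels within a
4-voxel-radius sphere form 16 pattern vectors (4 memorized numerosities x
4 runs) per time bin.  A linear epsilon-insensitive SVR (C = 1) is trained
to map patterns onto the numerosity continuum under leave-one-run-out
cross-validation: train on 12 vectors from three runs, predict the 4
held-out vectors, score the fold by the Fisher z-transformed Pearson
correlation between predicted and true numerosities, and assign the mean
over the four folds to the sphere's center voxel.  Each of the 10 trial
time bins is decoded independently; the delay-period summary is the
voxelwise mean over bins 3-8 (the 12 s retention).

Unlike a classifier, the regression treats numerosity as a continuum: high
accuracy requires the multivariate representation to be linearly ordered by
numerosity, with distances proportional to rank distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR

try:  # low-level libsvm entry point: same solver as SVR, far less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fallback for other sklearn builds
    _libsvm = None

from .firstlevel import DELAY_BINS, FIR_N_BINS, BetaMaps

FISHER_Z_CAP = float(np.arctanh(1.0 - 1e-15))


@dataclass(frozen=True)
class DecoderConfig:
    """Searchlight + SVR settings.

    ``label_map`` maps each condition (numerosity) to its regression target;
    identity by default, replaced by permuted assignments in the
    label-permutation control.
    """

    radius_vox: float = 4.0
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_tol: float = 1e-8
    label_map: dict | None = None
    delay_bins: tuple[int, ...] = DELAY_BINS
    fisher_z_cap: float = FISHER_Z_CAP
    min_sphere_voxels: int = 10
    pooled_scaling: bool = False

    def __post_init__(self) -> None:
        if self.radius_vox < 0:
            raise ValueError("radius must be >= 0")
        if not set(self.delay_bins) <= set(range(1, FIR_N_BINS + 1)):
            raise ValueError(f"delay bins must lie in 1..{FIR_N_BINS}")

    def targets(self, conditions) -> np.ndarray:
        if self.label_map is None:
            return np.asarray(conditions, dtype=float)
        return np.asarray([self.label_map[c] for c in conditions], dtype=float)


def sphere_offsets(radius_vox: float) -> np.ndarray:
    """All integer lattice offsets with Euclidean norm <= radius (center included)."""
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_vox))
    axis = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = X**2 + Y**2 + Z**2 <= radius_vox**2
    return np.stack([X[keep], Y[keep], Z[keep]], axis=1)


def zscale_patterns(
    train: np.ndarray, test: np.ndarray, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-voxel z-scaling across samples.

    Mean and SD come from the training vectors only (applied unchanged to
    the test vectors) unless ``pooled``; zero-variance voxels are set to 0
    and flagged.
    """
    ref = np.vstack([train, test]) if pooled else train
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    degenerate = sd == 0
    sd = np.where(degenerate, 1.0, sd)
    train_z = (train - mu) / sd
    test_z = (test - mu) / sd
    if degenerate.any():
        train_z[:, degenerate] = 0.0
        test_z[:, degenerate] = 0.0
    return train_z, test_z, bool(degenerate.any())


def svr_fit_predict(
    train_vectors: np.ndarray,
    train_targets: np.ndarray,
    test_vectors: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
) -> np.ndarray:
    """Linear epsilon-SVR: fit on training patterns, predict test targets."""
    if np.unique(train_targets).size < 2:
        raise ValueError("need at least 2 distinct training targets")
    if np.allclose(train_vectors, train_vectors[0]):
        warnings.warn("degenerate searchlight: all training vectors identical")
        return np.full(test_vectors.shape[0], float(np.mean(train_targets)))
    if _libsvm is not None:
        X = np.ascontiguousarray(train_vectors, dtype=np.float64)
        y = np.ascontiguousarray(train_targets, dtype=np.float64)
        _, SVs, _, coef, intercept, *_ = _libsvm.fit(
            X,
            y,
            svm_type=3,  # epsilon-SVR
            kernel="linear",
            C=config.svr_c,
            epsilon=config.svr_epsilon,
            tol=config.svr_tol,
        )
        w = coef[0] @ SVs
        return np.asarray(test_vectors, dtype=np.float64) @ w + intercept[0]
    model = SVR(  # pragma: no cover - exercised only without the fast path
        kernel="linear",
        C=config.svr_c,
        epsilon=config.svr_epsilon,
        tol=config.svr_tol,
    )
    model.fit(train_vectors, train_targets)
    return model.predict(test_vectors)


def fisher_z(r: float, cap: float = FISHER_Z_CAP) -> float:
    r = float(np.clip(r, -1.0, 1.0))
    z = np.arctanh(r) if abs(r) < 1.0 else np.sign(r) * np.inf
    return float(np.clip(z, -cap, cap))


def _make_folds(runs: np.ndarray, targets: np.ndarray) -> list[tuple]:
    """Precompute per-fold index arrays and centered test targets."""
    runs = np.asarray(runs)
    targets = np.asarray(targets, dtype=float)
    folds = []
    for run in np.unique(runs):
        test = np.flatnonzero(runs == run)
        train = np.flatnonzero(runs != run)
        tt = targets[test]
        tc = tt - tt.mean()
        folds.append((train, test, np.ascontiguousarray(targets[train]), tc,
                      float(np.sqrt(tc @ tc))))
    return folds


def _fold_mean_z(patterns: np.ndarray, folds: list[tuple], config: DecoderConfig) -> float:
    """Mean capped Fisher-z over precomputed folds (hot path of the searchlight)."""
    total = 0.0
    for train, test, train_targets, test_centered, test_norm in folds:
        tr = patterns[train]
        te = patterns[test]
        if config.pooled_scaling:
            mu = patterns.mean(axis=0)
            sd = patterns.std(axis=0)
        else:
            mu = tr.mean(axis=0)
            sd = tr.std(axis=0)
        sd[sd == 0] = np.inf  # zero-variance voxels scale to 0
        trz = (tr - mu) / sd
        tez = (te - mu) / sd
        if _libsvm is not None:
            _, SVs, _, coef, intercept, *_ = _libsvm.fit(
                np.ascontiguousarray(trz),
                train_targets,
                svm_type=3,
                kernel="linear",
                C=config.svr_c,
                epsilon=config.svr_epsilon,
                tol=config.svr_tol,
            )
            pred = tez @ (coef[0] @ SVs) + intercept[0]
        else:  # pragma: no cover
            pred = svr_fit_predict(trz, train_targets, tez, config)
        pc = pred - pred.mean()
        denom = np.sqrt(pc @ pc) * test_norm
        if denom == 0:
            continue  # zero-variance predictions: fold scores 0
        r = float(np.clip((pc @ test_centered) / denom, -1.0, 1.0))
        total += fisher_z(r, config.fisher_z_cap)
    return total / len(folds)


def loro_accuracy(
    patterns: np.ndarray,
    runs: np.ndarray,
    targets: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
) -> float:
    """Mean Fisher-z accuracy over leave-one-run-out folds.

    ``patterns`` is (16, V) with run and target labels per row.  Within each
    fold the patterns are z-scaled on the training statistics, the SVR is
    fit on the 12 training vectors and predicts the 4 held-out vectors, and
    the fold score is atanh(Pearson r(predicted, true)), capped.  Folds with
    zero-variance predictions score 0.
    """
    runs = np.asarray(runs)
    targets = np.asarray(targets, dtype=float)
    if patterns.shape[0] != runs.size or runs.size != targets.size:
        raise ValueError("patterns, runs and targets must align")
    return float(_fold_mean_z(np.asarray(patterns, dtype=np.float64),
                              _make_folds(runs, targets), config))


@dataclass
class AccuracyMap:
    """Per-time-bin 3D maps of mean Fisher-z prediction accuracy."""

    maps: dict  # time_bin -> 3D array (NaN where undefined)
    subject_id: int = 0
    label_source: str = "cued"
    config: DecoderConfig = field(default_factory=DecoderConfig)


def _center_sphere_indices(mask: np.ndarray, offsets: np.ndarray, min_voxels: int):
    """Yield (center, in-mask flat indices) for every usable sphere center."""
    shape = mask.shape
    r = int(np.max(np.abs(offsets)))
    idx = np.full(np.array(shape) + 2 * r, -1, dtype=np.int64)
    inner = tuple(slice(r, r + s) for s in shape)
    flat = np.full(shape, -1, dtype=np.int64)
    flat[mask] = np.arange(int(mask.sum()))
    idx[inner] = flat
    centers = np.argwhere(mask)
    for center in centers:
        coords = center + offsets + r
        cols = idx[coords[:, 0], coords[:, 1], coords[:, 2]]
        cols = cols[cols >= 0]
        if cols.size < min_voxels:
            continue
        yield tuple(center), cols


def run_searchlight(
    betamaps: BetaMaps,
    mask: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
    time_bins: tuple[int, ...] | None = None,
    subject_id: int = 0,
) -> AccuracyMap:
    """Move the searchlight voxel by voxel and decode every requested time bin.

    Spheres are truncated to in-mask voxels at the borders; centers whose
    sphere retains fewer than ``min_sphere_voxels`` voxels are skipped and
    left NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if time_bins is None:
        time_bins = tuple(range(1, betamaps.n_bins + 1))
    offsets = sphere_offsets(config.radius_vox)

    n_runs = betamaps.n_runs
    conds = betamaps.conditions
    runs_label = np.repeat(np.arange(n_runs), len(conds))
    targets = np.tile(config.targets(conds), n_runs)

    folds = _make_folds(runs_label, targets)

    # (bin -> (16, n_mask_voxels)) pattern matrices
    bin_patterns = {}
    for b in time_bins:
        stack = betamaps.data[:, :, b - 1]  # (runs, conds, x, y, z)
        bin_patterns[b] = np.ascontiguousarray(
            stack.reshape(n_runs * len(conds), *mask.shape)[:, mask], dtype=np.float64
        )

    maps = {b: np.full(mask.shape, np.nan) for b in time_bins}
    for center, cols in _center_sphere_indices(mask, offsets, config.min_sphere_voxels):
        for b in time_bins:
            X = bin_patterns[b][:, cols]
            maps[b][center] = _fold_mean_z(X, folds, config)
    return AccuracyMap(maps=maps, subject_id=subject_id, config=config)


def delay_average(accuracy: AccuracyMap | dict, delay_bins=DELAY_BINS) -> np.ndarray:
    """Voxelwise mean accuracy over the delay-period time bins (3-8)."""
    maps = accuracy.maps if isinstance(accuracy, AccuracyMap) else accuracy
    missing = [b for b in delay_bins if b not in maps]
    if missing:
        raise ValueError(f"missing time bins {missing}")
    return np.mean([maps[b] for b in delay_bins], axis=0)
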