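"""First-level GLMs: time-resolved FIR models and the parametric univariate control.

The main model is a finite-impulse-response (FIR) GLM: each 2 s acquisition
volume within the 20 s modeled trial gets its own regressor per memorized
numerosity (4 conditions x 10 time bins = 40 task columns per run).  The
per-run, per-condition, per-bin parameter estimates are the pattern vectors
consumed by the searchlight decoder.  Nuisance structure follows aCompCor:
the top five principal components of the CSF and of the white-matter voxel
time courses, six motion parameters, and a 128 s discrete-cosine high-pass
basis, all as regressors of no interest.

The univariate control replaces the FIR set with HRF-convolved regressors: a
working-memory delay regressor, its numerosity parametric modulator (the
effect of interest), and boxcar + modulator pairs for each sample and test
stimulus (eight columns).  If memorized numerosity only modulated mean
activity levels, this model would detect it; the decoder's multivariate
effect should survive its absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .stimgen import NUMEROSITIES

FIR_N_BINS = 10
DELAY_BINS = (3, 4, 5, 6, 7, 8)  # 1-based bins covering the 12 s retention
DEFAULT_HIGHPASS_S = 128.0


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

def double_gamma_hrf(tr_s: float, duration_s: float = 32.0, oversampling: int = 16) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr_s / oversampling``.

    Positive lobe peaking at 6 s, undershoot at 16 s, undershoot/peak ratio
    1/6.  Samples are normalized to unit sum, so convolving a sustained
    unit boxcar yields a plateau of 1 and regressor amplitudes stay in
    signal units regardless of the oversampling rate.
    """
    dt = tr_s / oversampling
    t = np.arange(0, duration_s, dt)

    def gamma_pdf(x, shape):
        with np.errstate(divide="ignore"):
            logpdf = (shape - 1) * np.log(x) - x - gammaln(shape)
        out = np.exp(logpdf)
        out[x <= 0] = 0.0
        return out

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    return h / h.sum()


def hrf_convolve(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    amplitudes: np.ndarray,
    n_volumes: int,
    tr_s: float,
    oversampling: int = 16,
) -> np.ndarray:
    """Convolve an amplitude-modulated boxcar train with the canonical HRF.

    Returns the regressor sampled at volume acquisition times.
    """
    dt = tr_s / oversampling
    n_hi = n_volumes * oversampling
    stick = np.zeros(n_hi)
    for onset, dur, amp in zip(onsets_s, durations_s, amplitudes):
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        stick[a : max(b, a + 1)] += amp
    hrf = double_gamma_hrf(tr_s, oversampling=oversampling)
    conv = np.convolve(stick, hrf)[:n_hi]
    return conv[::oversampling]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with labeled columns.

    Task columns are labeled ``fir_<condition>_bin<k>`` (k = 1..10) for FIR
    models; nuisance columns keep their own prefixes.  ``task_columns`` maps
    (condition, bin) -> column index.
    """

    matrix: np.ndarray
    labels: list[str]
    task_columns: dict = field(default_factory=dict)
    run_index: int = 0

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def append(self, columns: np.ndarray, labels: list[str]) -> "DesignMatrix":
        columns = np.atleast_2d(np.asarray(columns, dtype=float))
        if columns.shape[0] != self.n_volumes:
            columns = columns.T
        if columns.shape[0] != self.n_volumes:
            raise ValueError("appended columns must have one row per volume")
        if columns.shape[1] != len(labels):
            raise ValueError("one label per appended column required")
        return DesignMatrix(
            np.hstack([self.matrix, columns]),
            self.labels + list(labels),
            dict(self.task_columns),
            self.run_index,
        )


def _trial_rows(events: pd.DataFrame) -> pd.DataFrame:
    rows = events[events["event_type"] == "sample1"]
    if rows.empty:
        raise ValueError("events table contains no sample1 (trial onset) rows")
    return rows


def build_fir_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    label_source: str = "cued",
    run_index: int = 0,
) -> DesignMatrix:
    """FIR task design: one indicator column per (condition, 2 s time bin).

    Bin 1 is aligned to trial onset (first sample); each trial contributes a 1
    to the 10 consecutive volume rows starting at its onset, in the columns
    of its condition.  ``label_source`` selects whether the memorized (cued)
    or the nonmemorized (uncued) numerosity labels the trial — the latter is
    the perceptual-residue control model.  Overlapping trials superpose
    linearly.
    """
    if label_source not in ("cued", "uncued"):
        raise ValueError("label_source must be 'cued' or 'uncued'")
    label_col = f"{label_source}_numerosity"
    trials = _trial_rows(events)

    conditions = list(NUMEROSITIES)
    columns = {}
    labels = []
    mat = np.zeros((n_volumes, len(conditions) * FIR_N_BINS))
    j = 0
    for cond in conditions:
        for b in range(1, FIR_N_BINS + 1):
            columns[(cond, b)] = j
            labels.append(f"fir_{cond}_bin{b}")
            j += 1

    for _, row in trials.iterrows():
        vol = row["onset"] / tr_s
        if abs(vol - round(vol)) > 1e-9:
            raise ValueError(f"trial onset {row['onset']} s is not TR-aligned")
        vol = int(round(vol))
        if vol + FIR_N_BINS > n_volumes:
            raise ValueError(
                f"trial at volume {vol} extends past the run end ({n_volumes} volumes)"
            )
        cond = int(row[label_col])
        for b in range(1, FIR_N_BINS + 1):
            mat[vol + b - 1, columns[(cond, b)]] += 1.0
    return DesignMatrix(mat, labels, columns, run_index)


def dct_highpass(n_volumes: int, tr_s: float, cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Discrete-cosine high-pass basis (nuisance columns), SPM convention.

    Returns the K = floor(2 * n_volumes * tr_s / cutoff_s) slowest non-constant
    cosines, i.e. the components a high-pass filter with the given cutoff
    period would remove.  May be empty.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    n_basis = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, n_basis))
    for k in range(1, n_basis + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * (2 * t + 1) * k / (2 * n_volumes)
        )
    return basis


def extract_nuisance_pcs(volumes: np.ndarray, tissue_mask: np.ndarray, k: int = 5) -> np.ndarray:
    """aCompCor: top-k principal component time courses of a tissue compartment.

    ``volumes`` is a 4D (x, y, z, t) array; voxel time courses are demeaned,
    and the leading left singular vectors of the time x voxel matrix are
    returned as unit-norm columns ordered by explained variance.
    """
    if k == 0:
        return np.empty((volumes.shape[-1], 0))
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("tissue mask is empty")
    if mask.sum() < k:
        raise ValueError(f"tissue mask has {mask.sum()} voxels, fewer than k={k}")
    X = volumes[mask].T.astype(float)  # time x voxels
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k]


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

@dataclass
class BetaMaps:
    """Per run x condition x time-bin FIR parameter-estimate volumes.

    ``data`` has shape (n_runs, n_conditions, n_bins, x, y, z); the decoder
    consumes these as pattern vectors within each searchlight.
    """

    data: np.ndarray
    conditions: tuple[int, ...]
    n_bins: int
    label_source: str = "cued"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.conditions) or self.data.shape[2] != self.n_bins:
            raise ValueError("BetaMaps shape does not match (runs, conditions, bins)")

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR pivot magnitudes
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'undetermined'}"
        )


def fit_glm_run(volumes: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None,
                add_intercept: bool = True) -> np.ndarray:
    """Per-voxel OLS fit of one run; returns task betas only.

    Output shape (n_conditions, n_bins, x, y, z), with NaN outside the mask.
    """
    X = design.matrix
    labels = list(design.labels)
    if add_intercept:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
        labels = labels + ["intercept"]
    _check_full_rank(X, labels)

    if mask is None:
        mask = np.ones(volumes.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    Y = volumes[mask].T.astype(float)  # time x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    conditions = sorted({c for c, _ in design.task_columns})
    n_bins = max(b for _, b in design.task_columns)
    out = np.full((len(conditions), n_bins) + volumes.shape[:3], np.nan)
    for (cond, b), j in design.task_columns.items():
        vol = np.full(volumes.shape[:3], np.nan)
        vol[mask] = beta[j]
        out[conditions.index(cond), b - 1] = vol
    return out


def fit_fir_betas(
    run_volumes: list[np.ndarray],
    run_designs: list[DesignMatrix],
    mask: np.ndarray | None = None,
    label_source: str = "cued",
) -> BetaMaps:
    """Fit the FIR GLM run by run and stack the task betas into BetaMaps."""
    if len(run_volumes) != len(run_designs):
        raise ValueError("one design per run required")
    stacks = [fit_glm_run(v, d, mask) for v, d in zip(run_volumes, run_designs)]
    conditions = tuple(sorted({c for c, _ in run_designs[0].task_columns}))
    n_bins = max(b for _, b in run_designs[0].task_columns)
    return BetaMaps(np.stack(stacks), conditions, n_bins, label_source, mask)


# ---------------------------------------------------------------------------
# parametric univariate control model
# ---------------------------------------------------------------------------

@dataclass
class ParametricModel:
    """HRF-convolved control design and its numerosity-modulation contrast."""

    design: DesignMatrix
    contrast: np.ndarray  # over the design's columns
    degenerate: bool = False  # all trials share one numerosity


def build_parametric_model(
    events: pd.DataFrame, n_volumes: int, tr_s: float, run_index: int = 0
) -> ParametricModel:
    """Univariate control GLM: 10 HRF-convolved task regressors.

    One delay-period regressor for WM processes, one delay regressor
    parametrically modulated by the memorized numerosity (mean-centered per
    run; the effect of interest), and boxcar + numerosity-modulator pairs for
    each of the two sample and two test stimuli (eight columns).  The
    contrast selects the WM x numerosity modulator.
    """
    trials = _trial_rows(events)
    onsets = trials["onset"].to_numpy(dtype=float)
    for onset in onsets:
        if abs(onset / tr_s - round(onset / tr_s)) > 1e-9:
            raise ValueError(f"trial onset {onset} s is not TR-aligned")
    if np.any(onsets + 20.0 > n_volumes * tr_s):
        raise ValueError("trial extends past the run end")
    cued = trials["cued_numerosity"].to_numpy(dtype=float)
    uncued = trials["uncued_numerosity"].to_numpy(dtype=float)
    cue = trials["cue"].to_numpy(dtype=int)
    match_pos = trials["match_position"].to_numpy(dtype=int)
    foil = trials["foil_numerosity"].to_numpy(dtype=float)

    centered_cued = cued - cued.mean()
    degenerate = bool(np.allclose(centered_cued, 0.0))
    if degenerate:
        warnings.warn("all trials share one memorized numerosity; WM modulator is zero")

    sample1_n = np.where(cue == 1, cued, uncued)
    sample2_n = np.where(cue == 2, cued, uncued)
    test1_n = np.where(match_pos == 1, cued, foil)
    test2_n = np.where(match_pos == 2, cued, foil)

    ones = np.ones_like(onsets)

    def reg(rel_onset, dur, amps):
        return hrf_convolve(onsets + rel_onset, dur * ones, amps, n_volumes, tr_s)

    def centered(x):
        return x - x.mean()

    cols = [
        ("wm_delay", reg(4.0, 12.0, ones)),
        ("wm_delay_x_numerosity", reg(4.0, 12.0, centered_cued)),
        ("sample1", reg(0.0, 1.0, ones)),
        ("sample1_x_numerosity", reg(0.0, 1.0, centered(sample1_n))),
        ("sample2", reg(2.0, 1.0, ones)),
        ("sample2_x_numerosity", reg(2.0, 1.0, centered(sample2_n))),
        ("test1", reg(16.0, 1.0, ones)),
        ("test1_x_numerosity", reg(16.0, 1.0, centered(test1_n))),
        ("test2", reg(18.0, 1.0, ones)),
        ("test2_x_numerosity", reg(18.0, 1.0, centered(test2_n))),
    ]
    mat = np.column_stack([c for _, c in cols])
    labels = [name for name, _ in cols]
    design = DesignMatrix(mat, labels, {}, run_index)
    contrast = np.zeros(len(labels))
    contrast[labels.index("wm_delay_x_numerosity")] = 1.0
    return ParametricModel(design, contrast, degenerate)


def parametric_contrast_map(
    volumes: np.ndarray,
    model: ParametricModel,
    nuisance: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Contrast-estimate (effect size) map for the numerosity modulator."""
    X = model.design.matrix
    labels = list(model.design.labels)
    contrast = model.contrast
    if nuisance is not None and nuisance.size:
        X = np.hstack([X, nuisance])
        labels += [f"nuisance{i}" for i in range(nuisance.shape[1])]
        contrast = np.concatenate([contrast, np.zeros(nuisance.shape[1])])
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    labels += ["intercept"]
    contrast = np.concatenate([contrast, [0.0]])
    if model.degenerate:
        # zero modulator column would make the design singular; drop it
        j = labels.index("wm_delay_x_numerosity")
        keep = [i for i in range(X.shape[1]) if i != j]
        out_shape = volumes.shape[:3]
        return np.zeros(out_shape)
    _check_full_rank(X, labels)
    if mask is None:
        mask = np.ones(volumes.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    Y = volumes[mask].T.astype(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    cmap = np.full(volumes.shape[:3], np.nan)
    cmap[mask] = contrast @ beta
    return cmap
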