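"""Synthetic 4D BOLD runs with a planted, linearly ordered numerosity code.

The simulator emulates the acquisition the analysis expects — 4 runs of
TR-locked DMTN trials — and plants, in a small region of interest, a
multivariate delay-period pattern whose per-voxel amplitude is affine in the
memorized numerosity.  The pattern weights are mean-centered across the ROI,
so the planted code carries no mean-level (univariate) numerosity effect:
only a multivariate decoder should recover it, mirroring the
univariate/multivariate dissociation the pipeline is designed to test.

On top of the signal, each voxel time course carries a baseline, a slow
cosine drift, AR(1)-correlated noise, latent nuisance time courses loading
on CSF and white-matter compartments (and leaking weakly into the brain),
and motion-coupled fluctuations.  All ground truth (ROI, weights,
amplitudes, nuisance loadings, motion traces) is retained for recovery
tests.

Defaults are a scaled-down acquisition (24 x 24 x 15 grid, 120 volumes/run,
8 subjects) so the full pipeline runs in minutes; the full-scale geometry
(64 x 64 x 37, 565 volumes, TR 2 s, 3 mm voxels) is reachable through the
config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stimgen
from .firstlevel import FIR_N_BINS, hrf_convolve
from .stimgen import NUMEROSITIES, RunSpec


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulated acquisition.

    ``snr`` is the planted pattern amplitude step between the extreme
    numerosities (7 vs 13), in units of the stationary noise standard
    deviation; ``consistency`` blends each subject's pattern weights between
    a shared template (1.0) and independent draws (0.0).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 15)
    voxel_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes_per_run: int = 120
    n_runs: int = 4
    n_subjects: int = 8
    snr: float = 2.0
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    nuisance_amplitude: float = 1.0
    motion_amplitude: float = 0.2
    consistency: float = 0.0
    roi_radius_vox: float = 3.0
    encoding_response: bool = False
    seed: int = 0

    def amplitude_map(self, numerosity: float) -> float:
        """Delay-pattern amplitude for a numerosity: affine, centered at 10."""
        return self.snr * self.noise_sd * (numerosity - 10.0) / 6.0


@dataclass
class GroundTruth:
    """Everything the simulator planted, for parameter-recovery tests."""

    signal_roi: np.ndarray  # boolean mask
    pattern_weights: np.ndarray  # per-voxel, zero outside ROI, zero-sum inside
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    wm_mask: np.ndarray
    nuisance_loadings: np.ndarray  # (x, y, z, n_latents)
    config: SimConfig
    roi_center: tuple[int, int, int] = (0, 0, 0)


@dataclass
class VolumeSeries:
    """One simulated 4D run plus its (possibly truncated) events table."""

    data: np.ndarray  # (x, y, z, t), float32
    tr_s: float
    mask: np.ndarray
    run_index: int
    events: pd.DataFrame | None = None
    motion: np.ndarray | None = None  # (t, 6)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume series contains non-finite values")


@dataclass
class SubjectData:
    subject_id: int
    runs: list[VolumeSeries]
    truth: GroundTruth


def _ball_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _ellipsoid_mask(shape) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2 for s in shape]
    radii = [max(s / 2 - 0.5, 1) for s in shape]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


N_LATENT_NUISANCE = 3


def make_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Place the signal ROI, tissue compartments, and pattern weights.

    The ROI is a small ball at the grid center (well inside the brain mask,
    leaving a searchlight-radius margin to the edge); weights are i.i.d.
    normal draws mean-centered over the ROI so the planted code has no
    mean-level component.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(config.grid_shape)
    center = tuple(s // 2 for s in shape)
    roi = _ball_mask(shape, center, config.roi_radius_vox)
    ijk = np.argwhere(roi)
    if np.any(ijk.min(axis=0) < 4) or np.any(ijk.max(axis=0) > np.array(shape) - 5):
        raise ValueError(
            f"grid {shape} too small for the ROI plus a radius-4 searchlight margin"
        )
    brain = _ellipsoid_mask(shape)

    # tissue compartments: small blocks at opposite ends, inside the brain
    csf = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    cx, cy, cz = center
    csf[2:5, cy - 1 : cy + 2, cz - 1 : cz + 2] = True
    wm[-5:-2, cy - 1 : cy + 2, cz - 1 : cz + 2] = True
    csf &= brain
    wm &= brain
    csf &= ~roi
    wm &= ~roi

    weights = np.zeros(shape)
    w = rng.standard_normal(int(roi.sum()))
    w -= w.mean()
    w /= np.sqrt(np.mean(w**2))  # unit RMS
    weights[roi] = w

    loadings = np.zeros(shape + (N_LATENT_NUISANCE,))
    loadings[csf, 0] = 1.0 + 0.3 * rng.standard_normal(int(csf.sum()))
    loadings[csf, 1] = 0.5 * rng.standard_normal(int(csf.sum()))
    loadings[wm, 1] = 1.0 + 0.3 * rng.standard_normal(int(wm.sum()))
    loadings[wm, 2] = 0.5 * rng.standard_normal(int(wm.sum()))
    leak = brain & ~csf & ~wm
    loadings[leak, :] = 0.05 * rng.standard_normal((int(leak.sum()), N_LATENT_NUISANCE))

    return GroundTruth(
        signal_roi=roi,
        pattern_weights=weights,
        brain_mask=brain,
        csf_mask=csf,
        wm_mask=wm,
        nuisance_loadings=loadings,
        config=config,
        roi_center=center,
    )


def ar1_noise(n_time: int, n_series: int, rho: float, sd: float, rng) -> np.ndarray:
    """Stationary AR(1) series, shape (n_time, n_series), marginal SD ``sd``."""
    white = rng.standard_normal((n_time, n_series))
    if rho == 0:
        return sd * white
    innovation_sd = sd * np.sqrt(1.0 - rho**2)
    out = np.empty_like(white)
    out[0] = sd * white[0]  # stationary start
    for t in range(1, n_time):
        out[t] = rho * out[t - 1] + innovation_sd * white[t]
    return out


def _smooth_latents(n_time: int, n_latents: int, rng) -> np.ndarray:
    """Slowly varying latent nuisance time courses, unit SD."""
    x = rng.standard_normal((n_time + 20, n_latents))
    kernel = np.hanning(11)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 0, x)[10:-10]
    sm = sm - sm.mean(axis=0)
    sd = sm.std(axis=0)
    sd[sd == 0] = 1.0
    return sm / sd


def truncated_events(run_spec: RunSpec, n_volumes: int, tr_s: float) -> pd.DataFrame:
    """Events of the trials whose full 10-bin model span fits in the run."""
    events = stimgen.events_table(run_spec)
    run_len_s = n_volumes * tr_s
    trial_onsets = events.loc[events.event_type == "sample1", "onset"]
    keep_onsets = set(
        o for o in trial_onsets if o + FIR_N_BINS * tr_s <= run_len_s + 1e-9
    )
    trial_of_row = np.repeat(
        trial_onsets.to_numpy(), len(stimgen.EVENT_ONSETS_S)
    )
    kept = events[np.isin(trial_of_row, list(keep_onsets))].reset_index(drop=True)
    if kept.empty:
        raise ValueError("run too short: no trial fits within the volume count")
    return kept


def _delay_signal(
    events: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    n_volumes: int,
    label_col: str = "cued_numerosity",
) -> np.ndarray:
    """ROI-voxel signal time courses, shape (t, n_roi_voxels)."""
    trials = events[events.event_type == "sample1"]
    regs = {}
    for cond in NUMEROSITIES:
        onsets = trials.loc[trials[label_col] == cond, "onset"].to_numpy(dtype=float)
        if onsets.size == 0:
            regs[cond] = np.zeros(n_volumes)
            continue
        ones = np.ones_like(onsets)
        reg = hrf_convolve(onsets + 4.0, 12.0 * ones, ones, n_volumes, config.tr_s)
        if config.encoding_response:
            sample_onsets = np.where(
                trials.loc[trials[label_col] == cond, "cue"].to_numpy() == 1, 0.0, 2.0
            )
            reg = reg + hrf_convolve(
                onsets + sample_onsets, ones, 0.5 * ones, n_volumes, config.tr_s
            )
        regs[cond] = reg
    w = truth.pattern_weights[truth.signal_roi]
    out = np.zeros((n_volumes, w.size))
    for cond, reg in regs.items():
        out += np.outer(reg, w) * config.amplitude_map(cond)
    return out


def simulate_run(
    run_spec: RunSpec,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> VolumeSeries:
    """Simulate one 4D run for one subject.

    Voxel time course = baseline + cosine drift + AR(1) noise + latent
    nuisance components + motion-coupled signal + (ROI voxels only) the
    planted numerosity pattern: pattern weight x amplitude(numerosity) x an
    HRF-convolved boxcar over the 12 s retention of each trial.
    """
    shape = tuple(config.grid_shape)
    n_t = config.n_volumes_per_run
    events = truncated_events(run_spec, n_t, config.tr_s)

    brain = truth.brain_mask
    n_vox = int(brain.sum())

    data = np.zeros((n_t, n_vox), dtype=np.float64)
    data += 100.0  # baseline

    # slow drift: one cosine per voxel, random phase, period ~ run length
    t = np.arange(n_t) * config.tr_s
    run_len = n_t * config.tr_s
    phases = rng.uniform(0, 2 * np.pi, n_vox)
    periods = run_len * rng.uniform(1.0, 2.0, n_vox)
    amp = config.drift_amplitude * rng.uniform(0.5, 1.5, n_vox)
    data += amp * np.cos(2 * np.pi * t[:, None] / periods + phases)

    data += ar1_noise(n_t, n_vox, config.ar1_rho, config.noise_sd, rng)

    latents = _smooth_latents(n_t, N_LATENT_NUISANCE, rng)
    loadings = truth.nuisance_loadings[brain]  # (n_vox, n_latents)
    data += config.nuisance_amplitude * latents @ loadings.T

    motion = np.cumsum(rng.standard_normal((n_t, 6)) * 0.02, axis=0)
    motion_loadings = config.motion_amplitude * rng.standard_normal((6, n_vox))
    data += motion @ motion_loadings

    roi_in_brain = truth.signal_roi[brain]
    data[:, roi_in_brain] += _delay_signal(events, truth, config, n_t)

    vol = np.zeros(shape + (n_t,), dtype=np.float32)
    vol[brain] = data.T
    return VolumeSeries(
        data=vol,
        tr_s=config.tr_s,
        mask=brain,
        run_index=run_spec.run_index,
        events=events,
        motion=motion,
    )


def simulate_subject(
    config: SimConfig, subject_id: int, template: GroundTruth | None = None
) -> SubjectData:
    """All runs for one subject, with subject-specific pattern weights.

    Weights blend a shared template with an independent draw according to
    ``config.consistency``; geometry (ROI, masks, nuisance loadings) is
    shared across subjects.
    """
    if template is None:
        template = make_ground_truth(config)
    seed_seq = np.random.SeedSequence([config.seed, 1000 + subject_id])
    rng = np.random.Generator(np.random.Philox(seed_seq))

    c = float(config.consistency)
    roi = template.signal_roi
    w_t = template.pattern_weights[roi]
    w_i = rng.standard_normal(w_t.size)
    w_i -= w_i.mean()
    w_i /= np.sqrt(np.mean(w_i**2))
    w = c * w_t + np.sqrt(max(0.0, 1.0 - c**2)) * w_i
    weights = np.zeros(template.pattern_weights.shape)
    weights[roi] = w
    truth = dataclasses.replace(template, pattern_weights=weights)

    runs = []
    for r in range(config.n_runs):
        run_seed = int(
            np.random.SeedSequence([config.seed, 1000 + subject_id, r]).generate_state(1)[0]
            % (2**31)
        )
        run_spec = stimgen.make_run(r, run_seed)
        runs.append(simulate_run(run_spec, truth, config, rng))
    return SubjectData(subject_id=subject_id, runs=runs, truth=truth)


def simulate_cohort(config: SimConfig) -> list[SubjectData]:
    """Independent subjects sharing truth geometry (and, per ``consistency``,
    the pattern template)."""
    template = make_ground_truth(config)
    return [simulate_subject(config, s, template) for s in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# NIfTI / disk interface
# ---------------------------------------------------------------------------

def nifti_affine(config: SimConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = config.voxel_mm
    return aff


def write_subject(subject: SubjectData, out_dir: str | Path) -> Path:
    """Write one subject's runs, masks, events and truth to disk (NIfTI/TSV/JSON)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = subject.truth.config
    aff = nifti_affine(config)
    for run in subject.runs:
        stem = f"sub-{subject.subject_id:02d}_run-{run.run_index:02d}"
        nib.Nifti1Image(run.data, aff).to_filename(out_dir / f"{stem}_bold.nii.gz")
        run.events.to_csv(out_dir / f"{stem}_events.tsv", sep="\t", index=False)
        np.savetxt(out_dir / f"{stem}_motion.tsv", run.motion, delimiter="\t")
    for name, mask in [
        ("brain", subject.truth.brain_mask),
        ("csf", subject.truth.csf_mask),
        ("wm", subject.truth.wm_mask),
        ("roi", subject.truth.signal_roi),
    ]:
        nib.Nifti1Image(mask.astype(np.uint8), aff).to_filename(
            out_dir / f"sub-{subject.subject_id:02d}_mask-{name}.nii.gz"
        )
    truth_json = {
        "roi_center": list(subject.truth.roi_center),
        "amplitude_map": {str(n): config.amplitude_map(n) for n in NUMEROSITIES},
        "config": dataclasses.asdict(config),
    }
    (out_dir / f"sub-{subject.subject_id:02d}_truth.json").write_text(
        json.dumps(truth_json, indent=1)
    )
    return out_dir
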