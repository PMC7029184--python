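"""End-to-end subject and cohort pipelines over the simulator output.

These helpers chain the stages exactly as the analysis scripts do: events ->
FIR design with aCompCor/motion/high-pass nuisance -> per-run OLS betas ->
searchlight SVR decoding -> delay-period summary, and the univariate
parametric control alongside.  Tests and the acceptance checks run the
pipeline through this module so every stage is exercised as wired, not in
isolation.
"""

from __future__ import annotations

import numpy as np

from . import firstlevel, searchlight
from .firstlevel import DELAY_BINS
from .group import GroupInput
from .searchlight import AccuracyMap, DecoderConfig
from .synthetic_bold import SubjectData


def run_design(run, label_source: str = "cued"):
    """Full first-level design for one run: FIR task columns plus nuisance."""
    n_vol = run.data.shape[-1]
    return firstlevel.build_fir_design(
        run.events, n_vol, run.tr_s, label_source, run.run_index
    )


def add_run_nuisance(design, run, truth):
    csf = firstlevel.extract_nuisance_pcs(run.data, truth.csf_mask, k=5)
    wm = firstlevel.extract_nuisance_pcs(run.data, truth.wm_mask, k=5)
    hp = firstlevel.dct_highpass(run.data.shape[-1], run.tr_s)
    design = design.append(csf, [f"nuisance_pc_csf{i+1}" for i in range(5)])
    design = design.append(wm, [f"nuisance_pc_wm{i+1}" for i in range(5)])
    design = design.append(run.motion, [f"motion{i+1}" for i in range(6)])
    if hp.shape[1]:
        design = design.append(hp, [f"highpass{i+1}" for i in range(hp.shape[1])])
    return design


def subject_betamaps(subject: SubjectData, label_source: str = "cued"):
    """Per-run FIR parameter estimates for one simulated subject."""
    designs = []
    for run in subject.runs:
        d = run_design(run, label_source)
        designs.append(add_run_nuisance(d, run, subject.truth))
    volumes = [run.data for run in subject.runs]
    betas = firstlevel.fit_fir_betas(
        volumes, designs, subject.truth.brain_mask, label_source
    )
    return betas


def decode_subject(
    subject: SubjectData,
    config: DecoderConfig = DecoderConfig(),
    time_bins=None,
    label_source: str = "cued",
) -> AccuracyMap:
    """Simulated subject -> FIR betas -> searchlight accuracy maps."""
    betas = subject_betamaps(subject, label_source)
    acc = searchlight.run_searchlight(
        betas, subject.truth.brain_mask, config, time_bins, subject.subject_id
    )
    acc.label_source = label_source
    return acc


def subject_parametric_map(subject: SubjectData) -> np.ndarray:
    """Univariate numerosity-modulation contrast, averaged over runs."""
    maps = []
    for run in subject.runs:
        n_vol = run.data.shape[-1]
        model = firstlevel.build_parametric_model(
            run.events, n_vol, run.tr_s, run.run_index
        )
        csf = firstlevel.extract_nuisance_pcs(run.data, subject.truth.csf_mask, k=5)
        wm = firstlevel.extract_nuisance_pcs(run.data, subject.truth.wm_mask, k=5)
        hp = firstlevel.dct_highpass(n_vol, run.tr_s)
        nuisance = np.hstack([csf, wm, run.motion, hp])
        maps.append(
            firstlevel.parametric_contrast_map(
                run.data, model, nuisance, subject.truth.brain_mask
            )
        )
    return np.mean(maps, axis=0)


def decode_cohort(
    cohort: list[SubjectData],
    config: DecoderConfig = DecoderConfig(),
    time_bins=DELAY_BINS,
    label_source: str = "cued",
    fwhm_mm: float = 8.0,
) -> GroupInput:
    """Decode every subject and assemble the group input."""
    subject_maps = [
        decode_subject(s, config, time_bins, label_source).maps for s in cohort
    ]
    truth = cohort[0].truth
    return GroupInput(
        subject_maps=subject_maps,
        mask=truth.brain_mask,
        voxel_mm=truth.config.voxel_mm,
        fwhm_mm=fwhm_mm,
    )
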