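#!/usr/bin/env python
"""Fit the first-level FIR models (cued and nonmemorized labelings).

Per run: 40 FIR task columns (4 numerosities x 10 two-second bins), five
CSF and five white-matter aCompCor components, six motion parameters and
the 128 s discrete-cosine high-pass set.  The per-run parameter-estimate
volumes are stored as the decoder's pattern input.
"""

import argparse
from pathlib import Path

import numpy as np

from paramwm import pipeline, synthetic_bold


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--snr", type=float, default=2.0)
    ap.add_argument("--out", type=Path, default=Path("results/firstlevel"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = synthetic_bold.SimConfig(snr=args.snr, seed=args.seed)
    subject = synthetic_bold.simulate_subject(cfg, 0)

    for label_source in ("cued", "uncued"):
        betas = pipeline.subject_betamaps(subject, label_source)
        np.savez_compressed(
            args.out / f"sub-00_betas_{label_source}.npz",
            data=betas.data.astype(np.float32),
            conditions=np.array(betas.conditions),
            mask=subject.truth.brain_mask,
        )
        n_runs, n_cond, n_bins = betas.data.shape[:3]
        print(f"{label_source}: {n_runs} runs x {n_cond} conditions x "
              f"{n_bins} bins = {n_runs * n_cond * n_bins} beta volumes")

    design = pipeline.add_run_nuisance(
        pipeline.run_design(subject.runs[0]), subject.runs[0], subject.truth
    )
    print(f"design matrix per run: {design.matrix.shape[0]} volumes x "
          f"{design.matrix.shape[1]} regressors "
          f"({len(design.task_columns)} task, rest nuisance)")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
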