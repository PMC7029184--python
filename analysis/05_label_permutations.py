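#!/usr/bin/env python
"""Rank-distance label-permutation control at the decoding peak.

Re-runs the searchlight SVR at the planted-ROI peak under all 12
representative numerosity-label orderings and profiles mean delay accuracy
by distance class — on a genuine linear code the profile decreases with
distance from the correct order.
"""

import argparse
from pathlib import Path

from paramwm import pipeline, synthetic_bold
from paramwm.permutation import class_profile, profile_permutations


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--snr", type=float, default=2.0)
    ap.add_argument("--out", type=Path, default=Path("results/permutations"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = synthetic_bold.SimConfig(snr=args.snr, seed=args.seed)
    subject = synthetic_bold.simulate_subject(cfg, 0)
    betas = pipeline.subject_betamaps(subject)
    peak = tuple(int(c) for c in subject.truth.roi_center)

    profile = profile_permutations(betas, subject.truth.brain_mask, [peak])
    means = class_profile(profile).sort_values("distance")
    profile.accuracies.to_csv(args.out / "permutation_accuracies.tsv",
                              sep="\t", index=False)
    means.to_csv(args.out / "class_profile.tsv", sep="\t", index=False)

    sizes = {d: len(ps) for d, ps in profile.classes.items()}
    print(f"12 representative orderings in 5 distance classes (sizes {sizes})")
    print("mean delay accuracy by distance class at the ROI peak:")
    for _, row in means.iterrows():
        print(f"  distance {int(row.distance)}: {row.accuracy:+.3f}")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
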