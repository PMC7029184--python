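"""Rank-distance label-permutation control for the SVR decoder.

If the decoder truly exploits a linear numerosity continuum, decoding
accuracy should be highest when the regression targets follow the correct
order (7 < 9 < 11 < 13) and degrade as the assigned ordering departs from
it.  Departure is quantified by the rank distance: map the numerosities to
ranks 1..4 by ascending value and sum the absolute differences of adjacent
ranks in the assigned ordering; e.g. (11, 13, 7, 9) has ranks (3, 4, 1, 2)
and distance |3-4| + |4-1| + |1-2| = 5.  The correct order scores the
minimum, 3; the 24 orderings collapse to 12 representatives because an
ordering and its reversal have equal distance (and, for a correlation-based
accuracy, identical |accuracy|), and group into five distance classes
{3: 1, 4: 2, 5: 6, 6: 2, 7: 1}.

Decoding is re-run with each representative ordering's targets at
designated peak voxels, and per-class mean delay-period accuracies are
profiled; on data carrying a genuine linear code the profile decreases
with distance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .firstlevel import BetaMaps
from .searchlight import (
    DecoderConfig,
    _center_sphere_indices,
    _fold_mean_z,
    _make_folds,
    sphere_offsets,
)
from .stimgen import NUMEROSITIES

CORRECT_ORDER = tuple(sorted(NUMEROSITIES))


def rank_distance(ordering) -> int:
    """Sum of absolute differences of adjacent ranks of a label ordering."""
    ordering = tuple(ordering)
    if sorted(ordering) != sorted(NUMEROSITIES):
        raise ValueError(f"{ordering} is not a permutation of {NUMEROSITIES}")
    rank = {n: i + 1 for i, n in enumerate(CORRECT_ORDER)}
    ranks = [rank[n] for n in ordering]
    return int(sum(abs(a - b) for a, b in zip(ranks, ranks[1:])))


@dataclass(frozen=True)
class LabelPermutation:
    ordering: tuple[int, ...]

    @property
    def ranks(self) -> tuple[int, ...]:
        rank = {n: i + 1 for i, n in enumerate(CORRECT_ORDER)}
        return tuple(rank[n] for n in self.ordering)

    @property
    def distance(self) -> int:
        return rank_distance(self.ordering)

    def label_map(self) -> dict:
        """Target value assigned to each condition under this ordering.

        The condition at position i of the ordering is regressed onto the
        i-th value of the correct numerosity scale.
        """
        return {cond: float(CORRECT_ORDER[i]) for i, cond in enumerate(self.ordering)}


@dataclass
class DistanceClassProfile:
    """Permutations grouped by rank distance, with per-class accuracies."""

    classes: dict = field(default_factory=dict)  # distance -> [LabelPermutation]
    accuracies: pd.DataFrame | None = None  # columns: voxel, distance, accuracy

    @property
    def representatives(self) -> list[LabelPermutation]:
        return [p for ps in self.classes.values() for p in ps]


def enumerate_classes() -> DistanceClassProfile:
    """All 24 orderings reduced to 12 reversal-pair representatives in 5 classes.

    An ordering and its reversal share the same rank distance; the
    lexicographically smaller member represents the pair.  Class sizes over
    distances {3, 4, 5, 6, 7} are {1, 2, 6, 2, 1}.
    """
    reps = []
    seen = set()
    for p in permutations(NUMEROSITIES):
        if p in seen:
            continue
        seen.add(p)
        seen.add(p[::-1])
        reps.append(LabelPermutation(min(p, p[::-1])))
    classes: dict[int, list[LabelPermutation]] = {}
    for perm in sorted(reps, key=lambda q: (q.distance, q.ordering)):
        classes.setdefault(perm.distance, []).append(perm)
    return DistanceClassProfile(classes=classes)


def permuted_accuracy(
    betamaps: BetaMaps,
    mask: np.ndarray,
    peak_voxels,
    ordering,
    config: DecoderConfig = DecoderConfig(),
) -> np.ndarray:
    """Mean delay-bin decoding accuracy at peak-voxel searchlights under a
    permuted label ordering.

    Conditions are re-assigned regression targets according to ``ordering``
    and the leave-one-run-out SVR is re-run at the searchlights centered on
    each peak voxel, averaging accuracy over the delay time bins.
    """
    mask = np.asarray(mask, dtype=bool)
    perm = LabelPermutation(tuple(ordering))
    cfg_targets = dataclasses.replace(config, label_map=perm.label_map())
    peak_voxels = [tuple(v) for v in peak_voxels]
    for v in peak_voxels:
        if not mask[v]:
            raise ValueError(f"peak voxel {v} lies outside the mask")

    offsets = sphere_offsets(config.radius_vox)
    n_runs = betamaps.n_runs
    conds = betamaps.conditions
    runs_label = np.repeat(np.arange(n_runs), len(conds))
    targets = np.tile(cfg_targets.targets(conds), n_runs)
    folds = _make_folds(runs_label, targets)

    sphere_cols = {
        center: cols
        for center, cols in _center_sphere_indices(mask, offsets, config.min_sphere_voxels)
        if center in set(peak_voxels)
    }
    out = np.empty(len(peak_voxels))
    for i, v in enumerate(peak_voxels):
        if v not in sphere_cols:
            raise ValueError(f"peak voxel {v} has too few in-mask sphere voxels")
        cols = sphere_cols[v]
        accs = []
        for b in config.delay_bins:
            stack = betamaps.data[:, :, b - 1]
            X = np.ascontiguousarray(
                stack.reshape(n_runs * len(conds), *mask.shape)[:, mask][:, cols]
            )
            accs.append(_fold_mean_z(X, folds, cfg_targets))
        out[i] = np.mean(accs)
    return out


def profile_permutations(
    betamaps: BetaMaps,
    mask: np.ndarray,
    peak_voxels,
    config: DecoderConfig = DecoderConfig(),
) -> DistanceClassProfile:
    """Run all 12 representative orderings at the peak voxels."""
    profile = enumerate_classes()
    rows = []
    for perm in profile.representatives:
        accs = permuted_accuracy(betamaps, mask, peak_voxels, perm.ordering, config)
        for v, acc in zip(peak_voxels, accs):
            rows.append(
                {
                    "voxel": tuple(v),
                    "ordering": perm.ordering,
                    "distance": perm.distance,
                    "accuracy": acc,
                }
            )
    profile.accuracies = pd.DataFrame(rows)
    return profile


def class_profile(profile: DistanceClassProfile) -> pd.DataFrame:
    """Per-voxel, per-distance-class mean accuracy (the monotonicity report)."""
    if profile.accuracies is None or profile.accuracies.empty:
        raise ValueError("no permutation accuracies recorded")
    counts = profile.accuracies.groupby("voxel")["ordering"].nunique()
    if (counts != len(profile.representatives)).any():
        raise ValueError("missing permutation results for some voxels")
    return (
        profile.accuracies.groupby(["voxel", "distance"])["accuracy"]
        .mean()
        .reset_index()
    )
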