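"""Tactile pulse-train stimuli and the delayed match-to-numerosity (DMTN) protocol.

A stimulus is a train of brief electric pulses whose *numerosity* (7, 9, 11 or
13 pulses) is the to-be-remembered quantity.  To decouple numerosity from
stimulus length and mean pulse rate, each train is built on a 60 ms onset grid
("slots") spanning one of four durations (960, 1020, 1080, 1140 ms, i.e. 17,
18, 19 or 20 onset slots), and the pulses are scattered randomly over the
slots with the first and last slot always occupied.

A DMTN trial presents two sample trains with different numerosities, a
retro-cue plus a full 20-pulse mask, a 12 s retention period, and two test
trains (the match and a foil at target ± 3 pulses, with 7 − 3 mapped to 5 to
stay above the tactile subitizing range).  A run contains every ordered pair
of distinct numerosities four times: 12 pairings x 4 = 48 trials.

All event onsets sit on the 2 s acquisition grid (TR-locked), so one trial
spans 10 acquisition volumes: samples at 0 s and 2 s, cue+mask at 4 s, tests
at 16 s and 18 s, response window from 20 s.  The retention interval
(cue onset to first test onset) is exactly 12 s and covers volume bins 3-8 of
the 10-bin trial model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUMEROSITIES = (7, 9, 11, 13)
DURATIONS_MS = (960, 1020, 1080, 1140)
SHORT_DURATIONS_MS = (960, 1020)
LONG_DURATIONS_MS = (1080, 1140)
SLOT_MS = 60
TR_S = 2.0
TRIAL_DURATION_S = 21.0  # samples + cue/mask + 12 s retention + tests + response
ITI_CHOICES_S = (1.5, 3.5)
N_TRIALS_PER_RUN = 48

#: within-trial event onsets (s), all multiples of the 2 s TR
EVENT_ONSETS_S = {
    "sample1": 0.0,
    "sample2": 2.0,
    "cue_mask": 4.0,
    "delay": 6.0,
    "test1": 16.0,
    "test2": 18.0,
    "response": 20.0,
}
RESPONSE_WINDOW_S = 1.5
DELAY_EVENT_DURATION_S = 10.0  # delay event row: from mask volume end to test1


def n_slots_for_duration(duration_ms: int) -> int:
    """Number of 60 ms onset slots in a stimulus of the given duration.

    Slots are onset positions on the grid 0, 60, ..., duration_ms (fencepost
    count), giving 17, 18, 19 and 20 slots for the four standard durations.
    """
    if duration_ms not in DURATIONS_MS:
        raise ValueError(
            f"unknown stimulus duration {duration_ms} ms; expected one of {DURATIONS_MS}"
        )
    return duration_ms // SLOT_MS + 1


@dataclass(frozen=True)
class PulseTrain:
    """One tactile stimulus: pulses scattered over a 60 ms onset grid."""

    numerosity: int
    duration_ms: int
    slots: tuple[int, ...]

    def __post_init__(self) -> None:
        n_slots = n_slots_for_duration(self.duration_ms)
        if len(self.slots) != n_slots:
            raise ValueError(f"expected {n_slots} slots, got {len(self.slots)}")
        if sum(self.slots) != self.numerosity:
            raise ValueError("slot occupancy does not sum to numerosity")
        if any(s not in (0, 1) for s in self.slots):
            raise ValueError("slots must be a binary occupancy vector")

    @property
    def pulse_times_ms(self) -> tuple[int, ...]:
        return tuple(i * SLOT_MS for i, s in enumerate(self.slots) if s)

    @property
    def n_slots(self) -> int:
        return len(self.slots)


def make_pulse_train(
    numerosity: int, duration_ms: int, rng: np.random.Generator
) -> PulseTrain:
    """Scatter ``numerosity`` pulses over the slot grid of ``duration_ms``.

    First and last slot are always occupied; the remaining pulses are drawn
    uniformly without replacement from the interior slots.
    """
    n_slots = n_slots_for_duration(duration_ms)
    if not 2 <= numerosity <= n_slots:
        raise ValueError(
            f"numerosity {numerosity} cannot occupy both endpoints of a "
            f"{n_slots}-slot grid (need 2 <= numerosity <= {n_slots})"
        )
    slots = np.zeros(n_slots, dtype=int)
    slots[0] = slots[-1] = 1
    interior = rng.choice(np.arange(1, n_slots - 1), size=numerosity - 2, replace=False)
    slots[interior] = 1
    return PulseTrain(numerosity, duration_ms, tuple(int(s) for s in slots))


def make_mask() -> PulseTrain:
    """The backward mask: longest duration (1140 ms) with all 20 slots pulsed."""
    n = n_slots_for_duration(1140)
    return PulseTrain(n, 1140, (1,) * n)


def foil_numerosity(target: int, sign: str) -> int:
    """Numerosity of the non-matching test stimulus: target +/- 3 pulses.

    The lower alternative for target 7 is set to 5 (not 4) to stay above the
    tactile subitizing range.
    """
    if target not in NUMEROSITIES:
        raise ValueError(f"target {target} not in the stimulus set {NUMEROSITIES}")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    if sign == "+":
        return target + 3
    return 5 if target == 7 else target - 3


def spectral_profile(train: PulseTrain) -> np.ndarray:
    """Amplitude spectrum of the slot-grid indicator sequence.

    Used to check that stimuli of different numerosities are composed of
    similar frequency mixtures (a report, not a gate).
    """
    return np.abs(np.fft.rfft(np.asarray(train.slots, dtype=float)))


@dataclass(frozen=True)
class TrialSpec:
    """One DMTN trial: two samples, retro-cue + mask, retention, two tests."""

    sample_1: PulseTrain
    sample_2: PulseTrain
    cue: int  # 1 or 2: which sample to retain
    mask: PulseTrain
    test_1: PulseTrain
    test_2: PulseTrain
    match_position: int  # 1 or 2: which test matches the cued numerosity
    iti_s: float
    onsets_s: dict = field(default_factory=lambda: dict(EVENT_ONSETS_S))

    def __post_init__(self) -> None:
        if self.sample_1.numerosity == self.sample_2.numerosity:
            raise ValueError("sample numerosities must differ")
        cued = self.cued_sample
        match = self.match_test
        if match.numerosity != cued.numerosity:
            raise ValueError("matching test must share the cued numerosity")
        if match.duration_ms == cued.duration_ms:
            raise ValueError("matching test must not share the cued sample's duration")
        if match.slots == cued.slots:
            raise ValueError("matching test must not be slot-identical to the sample")
        for onset in self.onsets_s.values():
            if (onset / TR_S) % 1 != 0:
                raise ValueError(f"event onset {onset} s is not TR-locked (TR {TR_S} s)")

    @property
    def cued_sample(self) -> PulseTrain:
        return self.sample_1 if self.cue == 1 else self.sample_2

    @property
    def uncued_sample(self) -> PulseTrain:
        return self.sample_2 if self.cue == 1 else self.sample_1

    @property
    def match_test(self) -> PulseTrain:
        return self.test_1 if self.match_position == 1 else self.test_2

    @property
    def foil_test(self) -> PulseTrain:
        return self.test_2 if self.match_position == 1 else self.test_1

    @property
    def cued_numerosity(self) -> int:
        return self.cued_sample.numerosity

    @property
    def uncued_numerosity(self) -> int:
        return self.uncued_sample.numerosity


def make_trial(
    cued_numerosity: int,
    uncued_numerosity: int,
    rng: np.random.Generator,
    cued_duration_ms: int | None = None,
    uncued_duration_ms: int | None = None,
) -> TrialSpec:
    """Assemble a full trial for one ordered (cued, uncued) numerosity pair.

    Cue position, foil sign, match position, ITI, and all pulse placements
    are drawn from ``rng``; durations may be pinned by the run-level
    balancing scheme, otherwise they are drawn at random.
    """
    if cued_numerosity == uncued_numerosity:
        raise ValueError("cued and uncued numerosities must differ")
    for n in (cued_numerosity, uncued_numerosity):
        if n not in NUMEROSITIES:
            raise ValueError(f"numerosity {n} not in the stimulus set {NUMEROSITIES}")

    if cued_duration_ms is None:
        cued_duration_ms = int(rng.choice(DURATIONS_MS))
    if uncued_duration_ms is None:
        uncued_duration_ms = int(rng.choice(DURATIONS_MS))

    cued_train = make_pulse_train(cued_numerosity, cued_duration_ms, rng)
    uncued_train = make_pulse_train(uncued_numerosity, uncued_duration_ms, rng)

    cue = int(rng.integers(1, 3))
    sample_1, sample_2 = (
        (cued_train, uncued_train) if cue == 1 else (uncued_train, cued_train)
    )

    sign = "+" if rng.random() < 0.5 else "-"
    foil_n = foil_numerosity(cued_numerosity, sign)

    match_duration = int(
        rng.choice([d for d in DURATIONS_MS if d != cued_duration_ms])
    )
    match_train = make_pulse_train(cued_numerosity, match_duration, rng)
    # the foil is only constrained away from the match-test's duration
    foil_duration = int(rng.choice([d for d in DURATIONS_MS if d != match_duration]))
    foil_train = make_pulse_train(foil_n, foil_duration, rng)

    match_position = int(rng.integers(1, 3))
    test_1, test_2 = (
        (match_train, foil_train) if match_position == 1 else (foil_train, match_train)
    )

    iti_s = float(rng.choice(ITI_CHOICES_S))
    return TrialSpec(
        sample_1=sample_1,
        sample_2=sample_2,
        cue=cue,
        mask=make_mask(),
        test_1=test_1,
        test_2=test_2,
        match_position=match_position,
        iti_s=iti_s,
    )


@dataclass(frozen=True)
class RunSpec:
    """A balanced 48-trial run with TR-locked trial onsets."""

    trials: tuple[TrialSpec, ...]
    trial_onsets_s: tuple[float, ...]
    run_index: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS_PER_RUN:
            raise ValueError(f"a run has {N_TRIALS_PER_RUN} trials")

    @property
    def duration_s(self) -> float:
        return self.trial_onsets_s[-1] + TRIAL_DURATION_S + self.trials[-1].iti_s


def _ordered_pairs() -> list[tuple[int, int]]:
    return [(a, b) for a in NUMEROSITIES for b in NUMEROSITIES if a != b]


def _duration_assignment(run_index: int) -> dict[int, tuple[int, int]]:
    """Per-run (short, long) duration for each numerosity, rotated across runs.

    A Latin-square style rotation so every numerosity is paired with both
    short-grid and both long-grid durations over the 4 runs.
    """
    out = {}
    for i, n in enumerate(NUMEROSITIES):
        out[n] = (
            SHORT_DURATIONS_MS[(i + run_index) % 2],
            LONG_DURATIONS_MS[(i + run_index) % 2],
        )
    return out


def make_run(run_index: int, seed: int) -> RunSpec:
    """Build one balanced run of 48 trials.

    Every ordered pair of distinct numerosities appears exactly 4 times as
    (cued, uncued).  The trial sequence is shuffled within blocks of 4 whose
    (cued, uncued) pairs form a fixed-point-free bijection of the numerosity
    set (the three double-transpositions partition all 12 ordered pairs), so
    any block prefix is balanced over both cued and uncued conditions — this
    is what lets scaled-down simulations truncate a run without losing a
    condition in either labeling.  Each cued numerosity is presented in both
    a short-grid and a long-grid duration within the run, alternating over
    its presentations.  ITIs of 1.5 s and 3.5 s are used for half of the
    trials each; the next trial onset is snapped down to the TR grid so that
    all event onsets coincide with volume acquisitions.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, run_index])))

    # the three fixed-point-free pairings partitioning the 12 ordered pairs
    a, b, c, d = NUMEROSITIES
    pairings = (
        ((a, b), (b, a), (c, d), (d, c)),
        ((a, c), (c, a), (b, d), (d, b)),
        ((a, d), (d, a), (b, c), (c, b)),
    )
    block_kinds = [0, 1, 2] * 4
    rng.shuffle(block_kinds)
    blocks: list[list[tuple[int, int]]] = []
    for kind in block_kinds:
        block = list(pairings[kind])
        rng.shuffle(block)
        blocks.append(block)
    pair_sequence = [p for block in blocks for p in block]

    itis = np.array([ITI_CHOICES_S[0]] * 24 + [ITI_CHOICES_S[1]] * 24)
    rng.shuffle(itis)

    durations = _duration_assignment(run_index)
    presentation_count = {n: 0 for n in NUMEROSITIES}

    trials = []
    onsets = []
    t = 0.0
    for (cued, uncued), iti in zip(pair_sequence, itis):
        # alternate short/long grid over this numerosity's cued presentations
        k = presentation_count[cued]
        presentation_count[cued] += 1
        cued_dur = durations[cued][k % 2]
        uncued_dur = int(rng.choice(durations[uncued]))
        trial = make_trial(cued, uncued, rng, cued_dur, uncued_dur)
        trial = dataclasses.replace(trial, iti_s=float(iti))
        trials.append(trial)
        onsets.append(t)
        raw_next = t + TRIAL_DURATION_S + float(iti)
        t = np.floor(raw_next / TR_S) * TR_S  # snap to the acquisition grid
    return RunSpec(tuple(trials), tuple(onsets), run_index, seed)


def make_naming_battery(seed: int) -> list[PulseTrain]:
    """The post-scan number-naming battery: numerosities 1-15, 5 stimuli each.

    75 stimuli total, with durations cycling through the four standard values
    (plus one repeat) for the 5 duration/temporal-distribution combinations.
    Numerosity 1 places its single pulse in the first slot and numerosity 2
    occupies both endpoints, relaxing the two-endpoint rule where it cannot
    apply.
    """
    rng = np.random.default_rng(seed)
    battery = []
    combo_durations = DURATIONS_MS + (DURATIONS_MS[0],)
    for numerosity in range(1, 16):
        for duration_ms in combo_durations:
            if numerosity == 1:
                n_slots = n_slots_for_duration(duration_ms)
                slots = (1,) + (0,) * (n_slots - 1)
                battery.append(PulseTrain(1, duration_ms, slots))
            else:
                battery.append(make_pulse_train(numerosity, duration_ms, rng))
    return battery


EVENTS_COLUMNS = [
    "onset",
    "duration",
    "event_type",
    "cued_numerosity",
    "uncued_numerosity",
    "cue",
    "match_position",
    "foil_numerosity",
]


def events_table(run: RunSpec) -> pd.DataFrame:
    """BIDS-style events table for one run (one row per event)."""
    rows = []
    for trial, trial_onset in zip(run.trials, run.trial_onsets_s):
        event_durations = {
            "sample1": trial.sample_1.duration_ms / 1000.0,
            "sample2": trial.sample_2.duration_ms / 1000.0,
            "cue_mask": trial.mask.duration_ms / 1000.0,
            "delay": DELAY_EVENT_DURATION_S,
            "test1": trial.test_1.duration_ms / 1000.0,
            "test2": trial.test_2.duration_ms / 1000.0,
            "response": RESPONSE_WINDOW_S,
        }
        for event_type, rel_onset in EVENT_ONSETS_S.items():
            rows.append(
                {
                    "onset": trial_onset + rel_onset,
                    "duration": event_durations[event_type],
                    "event_type": event_type,
                    "cued_numerosity": trial.cued_numerosity,
                    "uncued_numerosity": trial.uncued_numerosity,
                    "cue": trial.cue,
                    "match_position": trial.match_position,
                    "foil_numerosity": trial.foil_test.numerosity,
                }
            )
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events_tsv(run: RunSpec, path: str | Path) -> Path:
    path = Path(path)
    events_table(run).to_csv(path, sep="\t", index=False)
    return path


def export_protocol_json(runs: Iterable[RunSpec], path: str | Path) -> Path:
    """JSON schedule of per-stimulus pulse onset times, for replay/simulation."""
    payload = []
    for run in runs:
        run_entry = {"run_index": run.run_index, "seed": run.seed, "trials": []}
        for trial, onset in zip(run.trials, run.trial_onsets_s):
            run_entry["trials"].append(
                {
                    "onset_s": onset,
                    "cue": trial.cue,
                    "match_position": trial.match_position,
                    "iti_s": trial.iti_s,
                    "stimuli": {
                        name: {
                            "numerosity": st.numerosity,
                            "duration_ms": st.duration_ms,
                            "pulse_times_ms": list(st.pulse_times_ms),
                        }
                        for name, st in {
                            "sample1": trial.sample_1,
                            "sample2": trial.sample_2,
                            "mask": trial.mask,
                            "test1": trial.test_1,
                            "test2": trial.test_2,
                        }.items()
                    },
                }
            )
        payload.append(run_entry)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
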