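"""Experimental design: the 16-condition delayed-match-to-sample task.

One run presents each of 16 trial conditions exactly once: 12 conditions pair
one of four target objects with one of the three remaining objects as the
delay-period distractor stream, and 4 conditions present the target with a
blank delay.  Every trial lasts 15 s (fixation 0.5 s, target 0.5 s, blank
1.5 s, delay 10 s, probe 2.5 s); in distractor trials the 10 s delay carries
20 distractor images (10 exemplars, each twice, never back to back; 0.3 s on,
0.2 s off).  Runs open and close with an 8 s blank and the 15 intertrial
blanks comprise 3 long (8 s) and 12 short (2 s) periods in random positions,
for a run duration of 304 s = 380 TRs at TR = 0.8 s.

Both the simulator and the GLM consume :class:`RunSchedule`, so the forward
model and the estimator share a single timing ground truth.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TR_SECONDS = 0.8

#: stage durations within a trial, in seconds
FIXATION_S = 0.5
TARGET_S = 0.5
EARLY_DELAY_S = 1.5
MAIN_DELAY_S = 10.0
PROBE_S = 2.5
TRIAL_S = FIXATION_S + TARGET_S + EARLY_DELAY_S + MAIN_DELAY_S + PROBE_S  # 15 s

RUN_EDGE_BLANK_S = 8.0
N_LONG_ITI = 3
N_SHORT_ITI = 12
LONG_ITI_S = 8.0
SHORT_ITI_S = 2.0

N_DISTRACTOR_IMAGES = 20
N_DISTRACTOR_EXEMPLARS = 10
DISTRACTOR_ON_S = 0.3
DISTRACTOR_GAP_S = 0.2


class ObjectID(enum.Enum):
    """The four object categories; enum order fixes pair enumeration."""

    BIKE = "bike"
    COUCH = "couch"
    HANGER = "hanger"
    SHOE = "shoe"

    def __lt__(self, other: "ObjectID") -> bool:
        members = list(ObjectID)
        return members.index(self) < members.index(other)


class EventKind(enum.Enum):
    FIXATION = "fixation"
    TARGET = "target"
    BLANK_DELAY = "blank_delay"
    DISTRACTOR_IMAGE = "distractor_image"
    PROBE = "probe"
    INTERTRIAL_BLANK = "intertrial_blank"
    RUN_BLANK = "run_blank"


@dataclass(frozen=True, order=True)
class TrialCondition:
    """A (target, distractor) cell of the design; ``distractor=None`` for
    blank-delay trials."""

    target: ObjectID
    distractor: ObjectID | None = None

    def __post_init__(self) -> None:
        if self.distractor is not None and self.distractor == self.target:
            raise ValueError("target and distractor must differ")

    @property
    def has_distractor(self) -> bool:
        return self.distractor is not None

    def label(self) -> str:
        if self.distractor is None:
            return f"{self.target.value}_nodist"
        return f"{self.target.value}_{self.distractor.value}"


def enumerate_conditions() -> list[TrialCondition]:
    """The deterministic 16-condition roster.

    All ordered (target, distractor) pairs with target != distractor in enum
    order (12), followed by the four no-distractor conditions.
    """
    objs = list(ObjectID)
    with_d = [
        TrialCondition(t, d) for t, d in itertools.product(objs, objs) if t != d
    ]
    without = [TrialCondition(t, None) for t in objs]
    return with_d + without


@dataclass(frozen=True)
class TrialEvent:
    onset: float  # seconds from run start
    duration: float
    kind: EventKind
    condition: TrialCondition | None = None
    exemplar_index: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class RunSchedule:
    """Fully timed event list for one run."""

    events: tuple[TrialEvent, ...]
    tr_seconds: float = TR_SECONDS
    n_trials: int = 16

    @property
    def duration(self) -> float:
        last = max(self.events, key=lambda e: e.onset + e.duration)
        return last.onset + last.duration

    @property
    def n_trs(self) -> int:
        n = self.duration / self.tr_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("run duration is not a whole number of TRs")
        return int(round(n))

    def trial_onsets(self) -> list[tuple[float, TrialCondition]]:
        """(onset, condition) per trial, anchored at the fixation event."""
        return [
            (e.onset, e.condition)
            for e in self.events
            if e.kind is EventKind.FIXATION
        ]


@dataclass(frozen=True)
class SessionPlan:
    """Run counts for the two scan sessions, e.g. ``[13, 14]``."""

    runs_per_session: tuple[int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.runs_per_session) != 2:
            raise ValueError("exactly two sessions are expected")

    @property
    def n_runs(self) -> int:
        return sum(self.runs_per_session)


def _distractor_sequence(rng: np.random.Generator, max_attempts: int = 1000) -> list[int]:
    """A length-20 exemplar sequence, each of 10 exemplars twice, no adjacent
    repeats; rejection-sampled permutations."""
    base = np.repeat(np.arange(N_DISTRACTOR_EXEMPLARS), 2)
    for _ in range(max_attempts):
        seq = rng.permutation(base)
        if np.all(seq[1:] != seq[:-1]):
            return seq.tolist()
    raise RuntimeError(
        f"no repeat-free distractor sequence found in {max_attempts} attempts"
    )


def build_run_schedule(
    condition_order: list[TrialCondition] | None = None,
    blank_assignment: list[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> RunSchedule:
    """Lay out one run as a fully timed event list.

    Parameters
    ----------
    condition_order
        A permutation of the 16 conditions; drawn uniformly from the seed
        when omitted.
    blank_assignment
        The 15 intertrial blank durations (three 8 s, twelve 2 s); shuffled
        from the seed when omitted.
    seed
        Seed (or Generator) for condition order, blank placement and
        distractor exemplar sequences.  Same seed, same schedule.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_conditions = enumerate_conditions()
    if condition_order is None:
        condition_order = [all_conditions[i] for i in rng.permutation(16)]
    if len(condition_order) != 16 or set(condition_order) != set(all_conditions):
        raise ValueError("condition_order must be a permutation of the 16 conditions")
    if blank_assignment is None:
        blanks = [LONG_ITI_S] * N_LONG_ITI + [SHORT_ITI_S] * N_SHORT_ITI
        blank_assignment = [blanks[i] for i in rng.permutation(len(blanks))]
    if len(blank_assignment) != N_LONG_ITI + N_SHORT_ITI:
        raise ValueError("blank_assignment must have 15 entries")
    if sorted(blank_assignment) != sorted(
        [LONG_ITI_S] * N_LONG_ITI + [SHORT_ITI_S] * N_SHORT_ITI
    ):
        raise ValueError("blank_assignment must contain three 8 s and twelve 2 s blanks")

    events: list[TrialEvent] = []
    t = 0.0
    events.append(TrialEvent(t, RUN_EDGE_BLANK_S, EventKind.RUN_BLANK))
    t += RUN_EDGE_BLANK_S
    for i, cond in enumerate(condition_order):
        events.append(TrialEvent(t, FIXATION_S, EventKind.FIXATION, cond))
        events.append(TrialEvent(t + FIXATION_S, TARGET_S, EventKind.TARGET, cond))
        events.append(
            TrialEvent(t + FIXATION_S + TARGET_S, EARLY_DELAY_S, EventKind.BLANK_DELAY, cond)
        )
        delay_start = t + FIXATION_S + TARGET_S + EARLY_DELAY_S
        if cond.has_distractor:
            seq = _distractor_sequence(rng)
            for k, ex in enumerate(seq):
                events.append(
                    TrialEvent(
                        delay_start + k * (DISTRACTOR_ON_S + DISTRACTOR_GAP_S),
                        DISTRACTOR_ON_S,
                        EventKind.DISTRACTOR_IMAGE,
                        cond,
                        exemplar_index=int(ex),
                    )
                )
        else:
            events.append(
                TrialEvent(delay_start, MAIN_DELAY_S, EventKind.BLANK_DELAY, cond)
            )
        events.append(
            TrialEvent(delay_start + MAIN_DELAY_S, PROBE_S, EventKind.PROBE, cond)
        )
        t += TRIAL_S
        if i < 15:
            iti = blank_assignment[i]
            events.append(TrialEvent(t, iti, EventKind.INTERTRIAL_BLANK))
            t += iti
    events.append(TrialEvent(t, RUN_EDGE_BLANK_S, EventKind.RUN_BLANK))
    return RunSchedule(events=tuple(events))


def round_onsets_to_tr(schedule: RunSchedule) -> RunSchedule:
    """Snap each trial to the TR grid by rounding its onset to the nearest TR.

    All events of a trial shift rigidly with the trial onset, so within-trial
    timing is preserved.  Exact half-TR ties round up.  Idempotent.
    """
    tr = schedule.tr_seconds
    if tr <= 0:
        raise ValueError("tr_seconds must be positive")
    new_events: list[TrialEvent] = []
    current_shift = 0.0
    for ev in schedule.events:
        if ev.kind is EventKind.FIXATION:
            idx = np.floor(ev.onset / tr + 0.5)  # round half up
            current_shift = idx * tr - ev.onset
        if ev.condition is None:
            new_events.append(ev)  # blanks stay put; only trials are snapped
        else:
            new_events.append(replace(ev, onset=round(ev.onset + current_shift, 10)))
    return replace(schedule, events=tuple(new_events))


# ---------------------------------------------------------------------------
# BIDS-style events tables

_EVENTS_COLUMNS = ["onset", "duration", "trial_type", "target", "distractor", "exemplar"]


def schedule_to_events(schedule: RunSchedule) -> pd.DataFrame:
    """Serialize to a BIDS-style events table (one row per event)."""
    rows = []
    for ev in schedule.events:
        rows.append(
            {
                "onset": ev.onset,
                "duration": ev.duration,
                "trial_type": ev.kind.value,
                "target": ev.condition.target.value if ev.condition else "n/a",
                "distractor": (
                    ev.condition.distractor.value
                    if ev.condition and ev.condition.distractor
                    else "n/a"
                ),
                "exemplar": ev.exemplar_index if ev.exemplar_index is not None else "n/a",
            }
        )
    return pd.DataFrame(rows, columns=_EVENTS_COLUMNS)


def events_to_schedule(df: pd.DataFrame) -> RunSchedule:
    """Inverse of :func:`schedule_to_events`."""
    missing = [c for c in _EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    events = []
    for _, row in df.iterrows():
        cond = None
        if row["target"] != "n/a":
            distr = None if row["distractor"] == "n/a" else ObjectID(row["distractor"])
            cond = TrialCondition(ObjectID(row["target"]), distr)
        ex = None if row["exemplar"] == "n/a" else int(row["exemplar"])
        events.append(
            TrialEvent(
                float(row["onset"]),
                float(row["duration"]),
                EventKind(row["trial_type"]),
                cond,
                exemplar_index=ex,
            )
        )
    return RunSchedule(events=tuple(events))


def write_events_tsv(schedule: RunSchedule, path) -> None:
    schedule_to_events(schedule).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> RunSchedule:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"target": str, "distractor": str, "exemplar": str},
    )
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    return events_to_schedule(df)
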