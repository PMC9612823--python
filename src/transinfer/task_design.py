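"""Transitive-hierarchy task structure and trial schedules.

Two independent 7-item reward hierarchies (A>B>C>D>E>F>G), one learnt per
session ("recent" = day of scanning, "remote" = the day before).  Six adjacent
premise discriminations per hierarchy are trained before scanning; six
non-adjacent inferred discriminations (never involving the terminal items A or
G) are probed only in the scanner.  This module generates the interleaved and
progressive training schedules and the in-scanner trial list, together with
validators for the counting constraints each design must satisfy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABELS = "ABCDEFG"
SESSIONS = ("recent", "remote")

#: Trial timing (seconds): response window, fixation, null-event duration.
RESPONSE_WINDOW_S = 3.0
FIXATION_S = 3.5
NULL_EVENT_S = 6.5

N_TRAINING_TRIALS = 360
REPS_PER_PREMISE = 60
N_SCAN_REPS = 8
N_NULL_EVENTS = 16

#: Per-epoch presentation counts for the progressive schedule.  Row j is
#: premise discrimination j (A>B .. F>G), column e is epoch e.  Each row sums
#: to 60; discrimination j first appears in epoch j and its count strictly
#: decreases over subsequent epochs.  Configurable: any matrix satisfying
#: those constraints is accepted by ``generate_progressive_schedule``.
DEFAULT_PROGRESSIVE_MATRIX = np.array(
    [
        [17, 14, 11, 8, 6, 4],
        [0, 20, 14, 11, 8, 7],
        [0, 0, 20, 16, 13, 11],
        [0, 0, 0, 22, 20, 18],
        [0, 0, 0, 0, 31, 29],
        [0, 0, 0, 0, 0, 60],
    ]
)


@dataclass(frozen=True)
class Texture:
    """One wall texture: a rank in a session's 7-item hierarchy."""

    label: str
    session: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS!r}, got {self.label!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")

    @property
    def rank(self) -> int:
        """0 for A (highest reward value) .. 6 for G."""
        return LABELS.index(self.label)


@dataclass(frozen=True)
class Discrimination:
    """An ordered stimulus pair within one session's hierarchy.

    ``high`` ranks above ``low``; ``distance`` is the number of hierarchy
    steps separating them (premise pairs are adjacent, distance 1; inferred
    pairs span 2-4 steps and never include A or G).
    """

    high: Texture
    low: Texture
    trial_type: str
    distance: int = field(init=False)

    def __post_init__(self) -> None:
        if self.high.session != self.low.session:
            raise ValueError("both textures of a discrimination share a session")
        d = self.low.rank - self.high.rank
        if d < 1:
            raise ValueError("high must rank above low")
        object.__setattr__(self, "distance", d)
        if self.trial_type == "premise":
            if d != 1:
                raise ValueError("premise discriminations are adjacent (distance 1)")
        elif self.trial_type == "inferred":
            if d not in (2, 3, 4):
                raise ValueError("inferred distances are 2-4")
            if self.high.label == "A" or self.low.label == "G":
                raise ValueError("inferred discriminations exclude the hierarchy ends")
        else:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")

    @property
    def session(self) -> str:
        return self.high.session

    @property
    def name(self) -> str:
        return f"{self.high.label}>{self.low.label}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.session}:{self.name}"


def build_hierarchy(session: str) -> list[Discrimination]:
    """Return the 6 premise + 6 inferred discriminations of one hierarchy.

    Premise set: A>B, B>C, ... F>G.  Inferred set: the six pairs among B..F
    at distances 2-4 (three at Δ2, two at Δ3, one at Δ4).
    """
    tex = {lab: Texture(lab, session) for lab in LABELS}
    premises = [
        Discrimination(tex[LABELS[i]], tex[LABELS[i + 1]], "premise") for i in range(6)
    ]
    inferred = [
        Discrimination(tex[LABELS[i]], tex[LABELS[j]], "inferred")
        for i in range(1, 6)
        for j in range(i + 2, 6)
    ]
    return premises + inferred


def premise_pairs(session: str) -> list[Discrimination]:
    return [d for d in build_hierarchy(session) if d.trial_type == "premise"]


def inferred_pairs(session: str) -> list[Discrimination]:
    return [d for d in build_hierarchy(session) if d.trial_type == "inferred"]


@dataclass
class TrainingSchedule:
    """An ordered 360-trial training sequence for one session.

    ``trials`` is a DataFrame with columns trial (1-based), epoch (1-6 for
    progressive, 0 for interleaved), pair, high, low, high_on_left (bool).
    """

    trials: pd.DataFrame
    condition: str
    session: str
    seed: int

    def validate(self) -> None:
        t = self.trials
        if len(t) != N_TRAINING_TRIALS:
            raise ValueError(f"expected {N_TRAINING_TRIALS} trials, got {len(t)}")
        counts = t["pair"].value_counts()
        names = [d.name for d in premise_pairs(self.session)]
        for name in names:
            if counts.get(name, 0) != REPS_PER_PREMISE:
                raise ValueError(f"{name} occurs {counts.get(name, 0)} times, not 60")
        for name, grp in t.groupby("pair"):
            if grp["high_on_left"].sum() != REPS_PER_PREMISE // 2:
                raise ValueError(f"left/right placement unbalanced for {name}")
        if self.condition == "progressive":
            mat = (
                t.groupby(["pair", "epoch"]).size().unstack(fill_value=0)
                .reindex(index=names, columns=range(1, 7), fill_value=0)
            )
            validate_progressive_matrix(mat.to_numpy())


def validate_progressive_matrix(mat: np.ndarray) -> None:
    """Check the epoch-count constraints of a progressive design matrix."""
    mat = np.asarray(mat)
    if mat.shape != (6, 6):
        raise ValueError("progressive matrix must be 6 premises x 6 epochs")
    if (mat < 0).any():
        raise ValueError("negative epoch counts")
    if not np.all(mat.sum(axis=1) == REPS_PER_PREMISE):
        raise ValueError("each premise must total 60 presentations")
    for j in range(6):
        if np.any(mat[j, :j] != 0):
            raise ValueError(f"discrimination {j + 1} appears before its epoch")
        row = mat[j, j:]
        if np.any(row <= 0):
            raise ValueError(
                f"discrimination {j + 1} must appear in every epoch from {j + 1}"
            )
        if np.any(np.diff(row) >= 0):
            raise ValueError(
                f"counts for discrimination {j + 1} must strictly decrease"
            )


def _placement_flags(n: int, rng: np.random.Generator) -> np.ndarray:
    """n booleans, exactly half True, in random order (n must be even)."""
    flags = np.zeros(n, dtype=bool)
    flags[: n // 2] = True
    rng.shuffle(flags)
    return flags


def _schedule_frame(pairs: list[Discrimination], epochs: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    placements = {d.name: list(_placement_flags(REPS_PER_PREMISE, rng)) for d in pairs}
    rows = []
    by_name = {d.name: d for d in pairs}
    for i, (name, epoch) in enumerate(epochs, start=1):
        d = by_name[name]
        rows.append(
            {
                "trial": i,
                "epoch": int(epoch),
                "pair": name,
                "high": d.high.label,
                "low": d.low.label,
                "high_on_left": placements[name].pop(),
            }
        )
    return pd.DataFrame(rows)


def generate_interleaved_schedule(
    seed: int, session: str = "recent"
) -> TrainingSchedule:
    """Seeded shuffle of the balanced multiset (60 copies of each premise).

    Realises the pseudorandom interleaved schedule: every premise pair has a
    uniform 1/6 marginal probability at any position while the 60-per-pair
    total and the 30/30 left/right placement balance hold exactly.
    """
    rng = np.random.default_rng(seed)
    pairs = premise_pairs(session)
    multiset = np.repeat([d.name for d in pairs], REPS_PER_PREMISE)
    rng.shuffle(multiset)
    epochs = [(name, 0) for name in multiset]
    sched = TrainingSchedule(_schedule_frame(pairs, epochs, rng), "interleaved", session, seed)
    sched.validate()
    return sched


def generate_progressive_schedule(
    seed: int, session: str = "recent", matrix: np.ndarray | None = None
) -> TrainingSchedule:
    """Six epochs introducing the premise pairs one-by-one, top-down.

    Epoch 1 trains A>B alone (17 trials); epoch 2 adds B>C (20 of 34 trials);
    each introduced pair recurs in every later epoch with strictly decreasing
    counts, and every pair totals 60 presentations.  Order within an epoch is
    a seeded shuffle.
    """
    mat = DEFAULT_PROGRESSIVE_MATRIX if matrix is None else np.asarray(matrix)
    validate_progressive_matrix(mat)
    rng = np.random.default_rng(seed)
    pairs = premise_pairs(session)
    epochs: list[tuple[str, int]] = []
    for e in range(6):
        block = np.repeat([d.name for d in pairs], mat[:, e])
        rng.shuffle(block)
        epochs.extend((name, e + 1) for name in block)
    sched = TrainingSchedule(_schedule_frame(pairs, epochs, rng), "progressive", session, seed)
    sched.validate()
    return sched


def count_chains(pair_sequence, directional: bool = False) -> dict[int, int]:
    """Histogram of maximal chain lengths in a trial sequence.

    A chain is a maximal run of consecutive trials in which each successive
    discrimination shares a texture with its predecessor.  In directional
    mode the successor must sit one step lower in the hierarchy (its higher
    texture equals the predecessor's lower texture, e.g. B>C then C>D).
    Sequences may be given as "X>Y" strings or Discrimination objects.
    Only runs of length >= 2 are counted.
    """
    names = [p.name if isinstance(p, Discrimination) else str(p) for p in pair_sequence]
    if not names:
        raise ValueError("empty schedule")

    def linked(a: str, b: str) -> bool:
        ah, al = a[0], a[-1]
        bh, bl = b[0], b[-1]
        if directional:
            return bh == al
        return len({ah, al} & {bh, bl}) > 0

    hist: Counter[int] = Counter()
    run = 1
    for a, b in zip(names, names[1:]):
        if linked(a, b):
            run += 1
        else:
            if run >= 2:
                hist[run] += 1
            run = 1
    if run >= 2:
        hist[run] += 1
    return dict(hist)


@dataclass
class ScanTrialList:
    """The in-scanner trial list: 192 discrimination trials + 16 nulls.

    ``trials`` has columns trial, pair (null rows have pair=""), session,
    trial_type, high, low, distance, onset_s, high_on_left.  Each of the 24
    discriminations (12 per session) appears 8 times with the higher-valued
    texture on the left in exactly 4.
    """

    trials: pd.DataFrame
    seed: int

    @property
    def events(self) -> pd.DataFrame:
        return self.trials[self.trials["pair"] != ""].reset_index(drop=True)

    @property
    def duration_s(self) -> float:
        return float(len(self.trials) * NULL_EVENT_S)

    def validate(self) -> None:
        ev = self.events
        if len(ev) != 192:
            raise ValueError(f"expected 192 discrimination trials, got {len(ev)}")
        n_null = (self.trials["pair"] == "").sum()
        if n_null != N_NULL_EVENTS:
            raise ValueError(f"expected {N_NULL_EVENTS} null events, got {n_null}")
        for (sess, name), grp in ev.groupby(["session", "pair"]):
            if len(grp) != N_SCAN_REPS:
                raise ValueError(f"{sess}:{name} tested {len(grp)} times, not 8")
            if grp["high_on_left"].sum() != N_SCAN_REPS // 2:
                raise ValueError(f"placement unbalanced for {sess}:{name}")


def generate_scan_trials(seed: int) -> ScanTrialList:
    """Seeded pseudorandom in-scanner list over both hierarchies.

    Each trial occupies a 3 s response window plus 3.5 s fixation; null
    events last 6.5 s; onsets accumulate accordingly.  The original study
    ordered trials by a design-efficiency optimiser; here the order is a
    constrained seeded shuffle, which is sufficient for synthetic analyses.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for session in SESSIONS:
        for d in build_hierarchy(session):
            flags = _placement_flags(N_SCAN_REPS, rng)
            for rep in range(N_SCAN_REPS):
                entries.append((d, bool(flags[rep])))
    entries.extend([(None, False)] * N_NULL_EVENTS)
    order = rng.permutation(len(entries))
    rows = []
    onset = 0.0
    for i, idx in enumerate(order, start=1):
        d, left = entries[idx]
        if d is None:
            rows.append(
                {"trial": i, "pair": "", "session": "", "trial_type": "null",
                 "high": "", "low": "", "distance": 0, "onset_s": onset,
                 "high_on_left": False}
            )
        else:
            rows.append(
                {"trial": i, "pair": d.name, "session": d.session,
                 "trial_type": d.trial_type, "high": d.high.label,
                 "low": d.low.label, "distance": d.distance, "onset_s": onset,
                 "high_on_left": left}
            )
        onset += NULL_EVENT_S
    lst = ScanTrialList(pd.DataFrame(rows), seed)
    lst.validate()
    return lst
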