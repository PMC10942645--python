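"""Spatial Stroop-Simon task geometry.

The task presents an up/down arrow at one of 10 peripheral locations; the
participant responds left/right to the arrow direction.  The vertical
coordinate of the location can conflict with the arrow direction (spatial
Stroop) and the horizontal coordinate can conflict with the response side
(Simon).  Locations lie on five axes whose angle from the horizontal sets
the mix of the two conflict sources, so each axis defines one *conflict
type*; the cosine of the angle between two axes is the conflict similarity.

Two participant groups see mirrored stimulus quadrants with orthogonal
stimulus-response mappings, which de-correlates conflict type from raw
stimulus orientation across groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical axis angles, ordered pure-Stroop (vertical) to pure-Simon (horizontal)
CONFLICT_TYPE_NAMES = ("Stroop", "StHSmL", "StMSmM", "StLSmH", "Simon")
CONFLICT_TYPE_ANGLES = (90.0, 67.5, 45.0, 22.5, 0.0)

GROUPS = ("TL-BR", "TR-BL")
#: group -> required response mapping (direction of the "up" arrow response)
GROUP_MAPPING = {"TL-BR": "up-left", "TR-BL": "up-right"}

_EPS = 1e-9


@dataclass(frozen=True)
class ConflictType:
    """One of the five axes of the 1-D conflict space."""

    name: str
    axis_angle: float  # degrees from horizontal, in [0, 90]

    @property
    def stroop_weight(self) -> float:
        return math.sin(math.radians(self.axis_angle))

    @property
    def simon_weight(self) -> float:
        return math.cos(math.radians(self.axis_angle))


@dataclass(frozen=True)
class SubjectProfile:
    """A participant: stimulus-quadrant group plus response mapping.

    Group ``TL-BR`` (stimuli in top-left / bottom-right quadrants) responds
    up->left; group ``TR-BL`` responds up->right.  Any other pairing breaks
    the coincidence of Stroop and Simon congruency and is rejected.
    """

    subject_id: int
    group: str
    response_mapping: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.response_mapping is None:
            object.__setattr__(self, "response_mapping", GROUP_MAPPING[self.group])

    @property
    def is_consistent(self) -> bool:
        return self.response_mapping == GROUP_MAPPING[self.group]

    def response_for(self, direction: str) -> str:
        up_resp = "left" if self.response_mapping == "up-left" else "right"
        if direction == "up":
            return up_resp
        return "right" if up_resp == "left" else "left"


@dataclass(frozen=True)
class StimulusLocation:
    """A point on the unit circle (polar angle counterclockwise from +x)."""

    polar_angle: float

    @property
    def axial_angle(self) -> float:
        return self.polar_angle % 180.0

    @property
    def x(self) -> float:
        return math.cos(math.radians(self.polar_angle))

    @property
    def y(self) -> float:
        return math.sin(math.radians(self.polar_angle))


@dataclass(frozen=True)
class Condition:
    """A task condition: conflict type x congruency x arrow direction."""

    conflict_type: ConflictType
    congruency: str  # "C" or "I"
    direction: str  # "up" or "down"


def conflict_types() -> list[ConflictType]:
    """The five conflict types, ordered Stroop -> Simon (angles 90..0)."""
    return [ConflictType(n, a) for n, a in zip(CONFLICT_TYPE_NAMES, CONFLICT_TYPE_ANGLES)]


def conflict_type_by_name(name: str) -> ConflictType:
    idx = CONFLICT_TYPE_NAMES.index(name)
    return ConflictType(name, CONFLICT_TYPE_ANGLES[idx])


def conflict_similarity(a: ConflictType, b: ConflictType) -> float:
    """Cosine of the angular difference between two conflict-type axes."""
    return math.cos(math.radians(abs(a.axis_angle - b.axis_angle)))


def conflict_similarity_matrix() -> np.ndarray:
    """5x5 Gram matrix of conflict similarities (symmetric PSD)."""
    types = conflict_types()
    return np.array([[conflict_similarity(a, b) for b in types] for a in types])


def fold_axial_difference(delta: float) -> float:
    """Fold an axial-angle difference into [0, 90] degrees."""
    d = abs(delta) % 180.0
    return 180.0 - d if d > 90.0 else d


def orientation_similarity(p: StimulusLocation, q: StimulusLocation) -> float:
    """Cosine of the folded axial-angle difference between two locations."""
    return math.cos(math.radians(fold_axial_difference(p.axial_angle - q.axial_angle)))


def group_axis_angle(ct: ConflictType, group: str) -> float:
    """Axial angle (degrees, [0, 180)) of a conflict type's axis for a group."""
    if group == "TR-BL":
        return ct.axis_angle
    return (180.0 - ct.axis_angle) % 180.0


def rotated_axis_angle(axial_angle: float) -> float:
    """Mirror an axis into the top-right/bottom-left quadrant ([0, 90])."""
    a = axial_angle % 180.0
    return 180.0 - a if a > 90.0 else a


def _stroop_congruent(direction: str, y: float) -> bool | None:
    if abs(y) < _EPS:
        return None
    return (direction == "up") == (y > 0)


def _simon_congruent(response: str, x: float) -> bool | None:
    if abs(x) < _EPS:
        return None
    return (response == "right") == (x > 0)


def condition_location(cond: Condition, profile: SubjectProfile) -> StimulusLocation:
    """The unique stimulus location realizing a condition for a participant.

    The location's vertical half must (mis)match the arrow direction per the
    spatial-Stroop congruency and its horizontal side must (mis)match the
    response per the Simon congruency; for a well-formed group/mapping
    pairing both rules select the same endpoint of the conflict-type axis.
    """
    axis = group_axis_angle(cond.conflict_type, profile.group)
    response = profile.response_for(cond.direction)
    want = cond.congruency == "C"
    chosen = None
    for polar in (axis, (axis + 180.0) % 360.0):
        loc = StimulusLocation(polar)
        st = _stroop_congruent(cond.direction, loc.y)
        sm = _simon_congruent(response, loc.x)
        flags = [f for f in (st, sm) if f is not None]
        if not flags:  # cannot happen on the unit circle
            raise ValueError("degenerate location")
        if len(flags) == 2 and flags[0] != flags[1]:
            raise ValueError(
                f"group {profile.group!r} with mapping {profile.response_mapping!r} "
                "breaks the Stroop/Simon congruency coincidence (malformed profile)"
            )
        if all(f == want for f in flags):
            chosen = loc
    if chosen is None:
        raise ValueError(f"no location realizes {cond} for {profile}")
    return chosen


def generate_balanced_sequence(task_conditions: list, seed) -> list:
    """A sequence in which every ordered transition occurs exactly once.

    Builds a seed-randomized Eulerian circuit (Hierholzer's algorithm) on the
    complete directed graph with self-loops over the task conditions, so the
    returned sequence has length k**2 + 1 and an all-ones transition-count
    matrix.
    """
    k = len(task_conditions)
    if k < 1:
        raise ValueError("need at least one task condition")
    rng = np.random.default_rng(seed)
    # adjacency: for each node a shuffled stack of successors (incl. itself)
    adj = {}
    for i in range(k):
        succ = list(range(k))
        rng.shuffle(succ)
        adj[i] = succ
    start = int(rng.integers(k))
    # iterative Hierholzer
    stack = [start]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == k * k + 1
    return [task_conditions[i] for i in circuit]


def task_conditions() -> list[tuple[str, str]]:
    """The 10 task conditions: conflict type x congruency."""
    return [(n, c) for n in CONFLICT_TYPE_NAMES for c in ("C", "I")]


def conditions() -> list[Condition]:
    """All 20 conditions: conflict type x congruency x direction."""
    return [
        Condition(conflict_type_by_name(n), c, d)
        for n in CONFLICT_TYPE_NAMES
        for c in ("C", "I")
        for d in ("up", "down")
    ]


def make_profiles(n_subjects: int, group_split: int | None = None) -> list[SubjectProfile]:
    """Assign subjects to the two groups (first `group_split` to TL-BR)."""
    if group_split is None:
        group_split = n_subjects // 2
    return [
        SubjectProfile(i, "TL-BR" if i < group_split else "TR-BL")
        for i in range(n_subjects)
    ]


EXP1_RUNS, EXP1_SESSIONS = 30, 3
EXP2_RUNS, EXP2_TRIALS_PER_RUN = 2, 170


def _assign_directions(seq, rng):
    """Alternate up/down within each task condition to balance the 20 cells."""
    counters = {}
    out = []
    for tc in seq:
        if tc not in counters:
            counters[tc] = int(rng.integers(2))
        out.append("up" if counters[tc] % 2 == 0 else "down")
        counters[tc] += 1
    return out


def _exp2_condition_counts(rng) -> dict:
    """Per-conflict-type trial counts for a 340-trial session.

    Counts are randomized around 68 within [64, 73] (sum 340) to emulate the
    near-equal allocation of the scanner experiment's optimized sequences.
    """
    offsets = rng.permutation([-2, -1, 0, 1, 2])
    return {n: 68 + int(o) for n, o in zip(CONFLICT_TYPE_NAMES, offsets)}


def build_experiment(config: dict, profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Full per-subject trial schedule for experiment 1 or 2.

    exp1: 30 runs x 101 balanced trials (every ordered task-condition
    transition once per run) over 3 sessions.  exp2: 2 runs x 170 trials with
    shuffled sequences constrained to near-equal per-condition counts.
    """
    experiment = config.get("experiment", "exp1")
    seed = config.get("seed", 0)
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(seed)
    rows = []
    tcs = task_conditions()
    for profile in profiles:
        if experiment == "exp1":
            runs = []
            for r in range(EXP1_RUNS):
                seq = generate_balanced_sequence(tcs, rng.integers(2**31))
                runs.append(seq)
            runs_per_session = EXP1_RUNS // EXP1_SESSIONS
        else:
            counts = _exp2_condition_counts(rng)
            pool = []
            for name, n_type in counts.items():
                n_inc = n_type // 2 + int(rng.integers(2)) * (n_type % 2)
                pool += [(name, "I")] * n_inc + [(name, "C")] * (n_type - n_inc)
            pool = [pool[i] for i in rng.permutation(len(pool))]
            runs = [pool[:EXP2_TRIALS_PER_RUN], pool[EXP2_TRIALS_PER_RUN:]]
            runs_per_session = EXP2_RUNS
        for r, seq in enumerate(runs):
            dirs = _assign_directions(seq, rng)
            fix1 = rng.integers(100, 301, size=len(seq))
            for t, ((name, congr), d) in enumerate(zip(seq, dirs)):
                cond = Condition(conflict_type_by_name(name), congr, d)
                loc = condition_location(cond, profile)
                rows.append(
                    (
                        profile.subject_id,
                        profile.group,
                        profile.response_mapping,
                        r // runs_per_session,
                        r,
                        t,
                        name,
                        congr,
                        d,
                        loc.polar_angle,
                        profile.response_for(d),
                        int(fix1[t]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "group",
            "mapping",
            "session",
            "run",
            "trial",
            "conflict_type",
            "congruency",
            "direction",
            "polar_angle_deg",
            "correct_response",
            "fix1_ms",
        ],
    )
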