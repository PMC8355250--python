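"""Experimental designs and per-session trial-schedule generation.

Four massed-training Pavlovian designs are built in, each a two-group
(agency / yoked-passive) magazine-approach experiment:

``exp1_blocking``
    A(1)/B(0) pretraining followed by AX(1)/BY(1) compounds; X is the
    blocked cue, Y its control.  Nonreinforced X and Y probe trials are
    interleaved from session 9 of the compound phase.
``exp2_competition``
    A(1), B(0), X(0.75), Y(0.25) pretraining; in the compound phase X is
    paired with A on its reinforced trials and Y with B on its
    nonreinforced trials, so responding on X(0)/Y(1) trials tracks the
    outcome of cue competition online.
``exp3_no_configural``
    A(1)/B(0) pretraining then AX(0.75)/BY(0.25) compounds, with X/Y
    probe trials from session 13 — a competition design with no explicit
    configural solution.
``exp4_patterning``
    Concurrent negative (A+, X+, AX-) and positive (B-, Y-, BY+)
    patterning, single phase.

Reward probabilities are realized as exact per-session counts (e.g. a
0.75 cue is reinforced on exactly 18 of its 24 trials each session), and
trial order is pseudorandom under the constraint that no trial type runs
more than three in a row.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "EXPERIMENT_IDS",
    "Trial",
    "TrialType",
    "PhaseSpec",
    "DesignSpec",
    "TrialSchedule",
    "SubjectSchedule",
    "ScheduleAudit",
    "MAX_RUN_LENGTH",
    "cue_modality",
    "elements",
    "load_design",
    "generate_session",
    "yoke",
    "validate_schedule",
    "max_run_length",
    "session_seed",
    "design_to_dict",
    "design_from_dict",
    "design_to_yaml",
    "design_from_yaml",
]

#: visual cues are lamps, auditory cues tone/noise; compounds are audiovisual
_VISUAL = frozenset({"A", "B"})
_AUDITORY = frozenset({"X", "Y"})

#: maximum allowed run of identical trial types within a session
MAX_RUN_LENGTH = 3

#: default retry budget for the constrained shuffle
DEFAULT_RETRY_BUDGET = 10_000


def cue_modality(label: str) -> str:
    """Return ``visual``, ``auditory`` or ``compound`` for a cue label."""
    els = elements(label)
    if len(els) > 1:
        return "compound"
    if label in _VISUAL:
        return "visual"
    if label in _AUDITORY:
        return "auditory"
    raise ValueError(f"unknown cue label {label!r}")


def elements(label: str) -> frozenset[str]:
    """Decompose a (possibly compound) cue label into elemental cues."""
    els = frozenset(label)
    bad = els - (_VISUAL | _AUDITORY)
    if bad:
        raise ValueError(f"unknown elemental cues {sorted(bad)} in {label!r}")
    return els


@dataclass(frozen=True)
class TrialType:
    """One row of a design table: a cue (set) with exact per-session counts.

    ``n_reinforced`` of the type's trials per session end in sucrose, the
    remaining ``n_nonreinforced`` do not; the implied reward probability
    is their ratio.  Probe types are nonreinforced test presentations
    flagged so the analysis stage can isolate them.
    """

    name: str
    n_reinforced: int
    n_nonreinforced: int
    is_probe: bool = False

    def __post_init__(self) -> None:
        if self.n_reinforced < 0 or self.n_nonreinforced < 0:
            raise ValueError("trial counts must be non-negative")
        elements(self.name)  # validates the label

    @property
    def cues(self) -> frozenset[str]:
        return elements(self.name)

    @property
    def n_trials(self) -> int:
        return self.n_reinforced + self.n_nonreinforced

    @property
    def reward_probability(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return self.n_reinforced / self.n_trials


@dataclass(frozen=True)
class PhaseSpec:
    """A training phase: trial types, session count and probe rule.

    ``probe_types`` are appended to every session from
    ``probe_start_session`` (1-based, inclusive) onward.
    """

    name: str
    trial_types: tuple[TrialType, ...]
    n_sessions: int
    probe_types: tuple[TrialType, ...] = ()
    probe_start_session: int | None = None

    def __post_init__(self) -> None:
        if self.probe_types and self.probe_start_session is None:
            raise ValueError("probe_types given without probe_start_session")
        if (
            self.probe_start_session is not None
            and not 1 <= self.probe_start_session <= self.n_sessions
        ):
            raise ValueError("probe_start_session outside the phase")

    def session_trial_types(self, session_index: int) -> tuple[TrialType, ...]:
        """Trial types presented on 1-based ``session_index``, probes included."""
        if not 1 <= session_index <= self.n_sessions:
            raise ValueError(
                f"session_index {session_index} outside phase "
                f"{self.name!r} (1..{self.n_sessions})"
            )
        types = self.trial_types
        if (
            self.probe_start_session is not None
            and session_index >= self.probe_start_session
        ):
            types = types + self.probe_types
        return types

    def n_trials(self, session_index: int) -> int:
        return sum(t.n_trials for t in self.session_trial_types(session_index))


@dataclass(frozen=True)
class DesignSpec:
    """A full experiment: ordered phases under one identifier."""

    experiment_id: str
    phases: tuple[PhaseSpec, ...]

    @property
    def n_sessions(self) -> int:
        return sum(p.n_sessions for p in self.phases)


@dataclass(frozen=True)
class Trial:
    trial_index: int
    trial_type: str
    cues: frozenset[str]
    reinforced: bool
    probe: bool


@dataclass
class TrialSchedule:
    """An ordered realization of one session for one yoked pair."""

    trials: list[Trial]
    session_index: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def events(self) -> list[tuple[str, bool, bool]]:
        """The event sequence: (trial_type, reinforced, probe) per trial."""
        return [(t.trial_type, t.reinforced, t.probe) for t in self.trials]


@dataclass
class SubjectSchedule:
    """A session schedule annotated with the subject's agency status."""

    group: str  # "agency" (master) or "passive" (yoked)
    pair_id: int
    schedule: TrialSchedule


# ---------------------------------------------------------------------------
# built-in designs (counts per session)

def _design_exp1() -> DesignSpec:
    return DesignSpec(
        "exp1_blocking",
        (
            PhaseSpec(
                "pretraining",
                (TrialType("A", 48, 0), TrialType("B", 0, 48)),
                n_sessions=14,
            ),
            PhaseSpec(
                "compound",
                (
                    TrialType("A", 36, 0),
                    TrialType("B", 0, 36),
                    TrialType("AX", 12, 0),
                    TrialType("BY", 12, 0),
                ),
                n_sessions=20,
                probe_types=(
                    TrialType("X", 0, 2, is_probe=True),
                    TrialType("Y", 0, 2, is_probe=True),
                ),
                probe_start_session=9,
            ),
        ),
    )


def _design_exp2() -> DesignSpec:
    return DesignSpec(
        "exp2_competition",
        (
            PhaseSpec(
                "pretraining",
                (
                    TrialType("A", 24, 0),
                    TrialType("B", 0, 24),
                    TrialType("X", 18, 6),
                    TrialType("Y", 6, 18),
                ),
                n_sessions=10,
            ),
            PhaseSpec(
                "compound",
                (
                    TrialType("A", 10, 0),
                    TrialType("B", 0, 10),
                    TrialType("AX", 30, 0),
                    TrialType("X", 0, 10),
                    TrialType("BY", 0, 30),
                    TrialType("Y", 10, 0),
                ),
                n_sessions=20,
            ),
        ),
    )


def _design_exp3() -> DesignSpec:
    return DesignSpec(
        "exp3_no_configural",
        (
            PhaseSpec(
                "pretraining",
                (TrialType("A", 48, 0), TrialType("B", 0, 48)),
                n_sessions=8,
            ),
            PhaseSpec(
                "compound",
                (
                    TrialType("A", 24, 0),
                    TrialType("B", 0, 24),
                    TrialType("AX", 18, 6),
                    TrialType("BY", 6, 18),
                ),
                n_sessions=32,
                probe_types=(
                    TrialType("X", 0, 2, is_probe=True),
                    TrialType("Y", 0, 2, is_probe=True),
                ),
                probe_start_session=13,
            ),
        ),
    )


def _design_exp4() -> DesignSpec:
    return DesignSpec(
        "exp4_patterning",
        (
            PhaseSpec(
                "single_phase",
                (
                    TrialType("A", 16, 0),
                    TrialType("X", 16, 0),
                    TrialType("AX", 0, 16),
                    TrialType("B", 0, 16),
                    TrialType("Y", 0, 16),
                    TrialType("BY", 16, 0),
                ),
                n_sessions=42,
            ),
        ),
    )


_DESIGN_BUILDERS = {
    "exp1_blocking": _design_exp1,
    "exp2_competition": _design_exp2,
    "exp3_no_configural": _design_exp3,
    "exp4_patterning": _design_exp4,
}

EXPERIMENT_IDS = tuple(_DESIGN_BUILDERS)


def load_design(experiment_id: str) -> DesignSpec:
    """Return the built-in design for ``experiment_id``.

    Raises ``ValueError`` naming the valid identifiers otherwise.
    """
    try:
        return _DESIGN_BUILDERS[experiment_id]()
    except KeyError:
        raise ValueError(
            f"unknown experiment_id {experiment_id!r}; "
            f"valid ids: {', '.join(EXPERIMENT_IDS)}"
        ) from None


# ---------------------------------------------------------------------------
# schedule generation

def session_seed(base_seed: int, pair_id: int, phase_index: int,
                 session_index: int) -> int:
    """Derive an independent per-(pair, phase, session) stream seed.

    Uses a SeedSequence over the key tuple so pairs and sessions are
    reproducible in isolation.
    """
    ss = np.random.SeedSequence(
        [int(base_seed), int(pair_id), int(phase_index), int(session_index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def max_run_length(labels) -> int:
    """Length of the longest run of identical consecutive labels."""
    best = run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        best = max(best, run)
    return best


def _feasible(counts: dict[str, int]) -> bool:
    # a type with k trials needs at least ceil(k/MAX_RUN)-1 separators
    total = sum(counts.values())
    for k in counts.values():
        groups = -(-k // MAX_RUN_LENGTH)
        if groups - 1 > total - k:
            return False
    return True


def generate_session(
    phase: PhaseSpec,
    session_index: int,
    seed: int,
    max_retries: int = DEFAULT_RETRY_BUDGET,
) -> TrialSchedule:
    """Generate one session's pseudorandom trial schedule.

    Reinforcement is assigned by exact count within each trial type
    (shuffled across that type's trials).  The pseudorandom order is
    drawn sequentially, each position sampled among the remaining trial
    types in proportion to their remaining counts, excluding any type
    that has already run ``MAX_RUN_LENGTH`` times; a dead end restarts
    the draw, up to ``max_retries`` restarts.  Identical
    ``(phase, session_index, seed)`` yields an identical schedule.
    """
    types = phase.session_trial_types(session_index)
    counts = {t.name: t.n_trials for t in types if t.n_trials}
    if not _feasible(counts):
        raise RuntimeError(
            "session composition cannot satisfy the run-length constraint "
            f"(max {MAX_RUN_LENGTH} in succession): counts {counts}"
        )
    rng = np.random.default_rng(seed)

    # per-type reinforced flags, exact counts, order randomized within type
    flag_pools: dict[str, list[bool]] = {}
    by_name: dict[str, TrialType] = {}
    for t in types:
        if t.n_trials == 0:
            continue
        flags = [True] * t.n_reinforced + [False] * t.n_nonreinforced
        rng.shuffle(flags)
        flag_pools[t.name] = flags
        by_name[t.name] = t

    names = list(counts)
    base = [float(counts[n]) for n in names]
    total = sum(counts.values())
    order: list[str] | None = None
    for _ in range(max_retries):
        remaining = base.copy()
        seq: list[str] = []
        prev_i, run = -1, 0
        for _pos in range(total):
            weights = remaining.copy()
            if run >= MAX_RUN_LENGTH and prev_i >= 0:
                weights[prev_i] = 0.0
            w_total = sum(weights)
            if w_total <= 0.0:
                break  # dead end: only the just-run type remains
            u = rng.random() * w_total
            acc = 0.0
            for i, w in enumerate(weights):
                acc += w
                if u < acc:
                    break
            remaining[i] -= 1.0
            run = run + 1 if i == prev_i else 1
            prev_i = i
            seq.append(names[i])
        else:
            order = seq
            break
    if order is None:
        raise RuntimeError(
            f"no admissible ordering found in {max_retries} attempts for "
            f"run-length constraint (max {MAX_RUN_LENGTH}); counts {counts}"
        )

    iters = {name: iter(flags) for name, flags in flag_pools.items()}
    trials = []
    for i, name in enumerate(order):
        t = by_name[name]
        trials.append(
            Trial(i, name, t.cues, next(iters[name]), t.is_probe)
        )
    return TrialSchedule(trials, session_index, int(seed))


def yoke(schedule: TrialSchedule, pair_id: int = 0
         ) -> tuple[SubjectSchedule, SubjectSchedule]:
    """Pair a master schedule with its yoked copy.

    The yoked (passive) copy is event-identical — same trial types, same
    order, same reinforcement — and differs only in the agency
    annotation.
    """
    master = SubjectSchedule("agency", pair_id, schedule)
    yoked = SubjectSchedule("passive", pair_id, copy.deepcopy(schedule))
    return master, yoked


@dataclass
class ScheduleAudit:
    """Conformance report for a generated (or hand-built) schedule."""

    type_counts: dict[str, int]
    reinforced_counts: dict[str, int]
    reinforced_proportions: dict[str, float]
    max_run_length: int
    probe_count: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_schedule(schedule: TrialSchedule, phase: PhaseSpec) -> ScheduleAudit:
    """Audit a schedule against its originating phase.

    Violations (count mismatches, reinforcement mismatches, run-length
    breaches, probe-rule breaches) are reported, not raised.
    """
    expected = {
        t.name: t for t in phase.session_trial_types(schedule.session_index)
        if t.n_trials
    }
    type_counts: dict[str, int] = {}
    reinf_counts: dict[str, int] = {}
    probe_count = 0
    for tr in schedule.trials:
        type_counts[tr.trial_type] = type_counts.get(tr.trial_type, 0) + 1
        if tr.reinforced:
            reinf_counts[tr.trial_type] = reinf_counts.get(tr.trial_type, 0) + 1
        if tr.probe:
            probe_count += 1
    props = {
        name: reinf_counts.get(name, 0) / n for name, n in type_counts.items()
    }
    run = max_run_length(tr.trial_type for tr in schedule.trials)

    violations = []
    if run > MAX_RUN_LENGTH:
        violations.append(
            f"run-length violation: {run} consecutive presentations "
            f"(max {MAX_RUN_LENGTH})"
        )
    for name, spec in expected.items():
        if type_counts.get(name, 0) != spec.n_trials:
            violations.append(
                f"{name}: {type_counts.get(name, 0)} trials, "
                f"expected {spec.n_trials}"
            )
        if reinf_counts.get(name, 0) != spec.n_reinforced:
            violations.append(
                f"{name}: {reinf_counts.get(name, 0)} reinforced, "
                f"expected {spec.n_reinforced}"
            )
    for name in type_counts:
        if name not in expected:
            violations.append(f"{name}: not a trial type of this session")
    expected_probes = sum(
        t.n_trials for t in expected.values() if t.is_probe
    )
    if probe_count != expected_probes:
        violations.append(
            f"probe trials: {probe_count}, expected {expected_probes}"
        )
    return ScheduleAudit(
        type_counts, reinf_counts, props, run, probe_count, violations
    )


# ---------------------------------------------------------------------------
# serialization

def _trial_type_to_dict(t: TrialType) -> dict:
    d = {
        "name": t.name,
        "n_reinforced": t.n_reinforced,
        "n_nonreinforced": t.n_nonreinforced,
    }
    if t.is_probe:
        d["is_probe"] = True
    return d


def design_to_dict(design: DesignSpec) -> dict:
    return {
        "experiment_id": design.experiment_id,
        "phases": [
            {
                "name": p.name,
                "n_sessions": p.n_sessions,
                "trial_types": [_trial_type_to_dict(t) for t in p.trial_types],
                **(
                    {
                        "probe_start_session": p.probe_start_session,
                        "probe_types": [
                            _trial_type_to_dict(t) for t in p.probe_types
                        ],
                    }
                    if p.probe_types
                    else {}
                ),
            }
            for p in design.phases
        ],
    }


def design_from_dict(d: dict) -> DesignSpec:
    phases = []
    for p in d["phases"]:
        phases.append(
            PhaseSpec(
                p["name"],
                tuple(TrialType(**tt) for tt in p["trial_types"]),
                n_sessions=p["n_sessions"],
                probe_types=tuple(
                    TrialType(**tt) for tt in p.get("probe_types", [])
                ),
                probe_start_session=p.get("probe_start_session"),
            )
        )
    return DesignSpec(d["experiment_id"], tuple(phases))


def design_to_yaml(design: DesignSpec) -> str:
    return yaml.safe_dump(design_to_dict(design), sort_keys=False)


def design_from_yaml(text: str) -> DesignSpec:
    return design_from_dict(yaml.safe_load(text))
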