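"""Run the learning model over generated schedules and summarize the outcome.

A *subject* is one simulated animal: a parameter set applied trial by
trial to a realized schedule of its design.  Master-yoked pairs share a
single schedule realization; the agency and passive members differ only
in their learning parameters, never in the events they experience.

"Responding" at this level is the pre-update aggregate prediction for
the trial's cue set; mapping predictions to head-entry counts is the
business of :mod:`cuecomp.behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import (
    DesignSpec,
    TrialSchedule,
    generate_session,
    session_seed,
)
from .model import (
    AssociativeState,
    ModelParams,
    RepresentationConfig,
    active_units,
    default_representation,
)

__all__ = [
    "SubjectTrajectory",
    "GroupSummary",
    "pair_schedules",
    "run_subject",
    "run_yoked_groups",
    "session_block_means",
    "competition_index",
    "patterning_index",
]

RECORD_COLUMNS = [
    "phase", "session", "session_in_phase", "trial_index",
    "trial_type", "reinforced", "probe", "prediction",
]


@dataclass
class SubjectTrajectory:
    """Per-trial record of one simulated subject.

    ``records`` has one row per trial with the aggregate prediction for
    the trial's cue set *before* the update, plus session / trial-type /
    reinforcement / probe bookkeeping.  ``session`` is global (1-based,
    continuing across phases).
    """

    experiment_id: str
    group: str
    pair_id: int
    records: pd.DataFrame
    final_state: AssociativeState

    def session_means(self) -> pd.DataFrame:
        """Mean prediction per session x trial type (probe types separate)."""
        if self.records.empty:
            return pd.DataFrame(
                columns=["session", "trial_type", "probe", "prediction"]
            )
        return (
            self.records
            .groupby(["session", "trial_type", "probe"], as_index=False)
            ["prediction"].mean()
        )


@dataclass
class GroupSummary:
    """Across-subject summary for one group of one simulated experiment."""

    experiment_id: str
    group: str
    n_subjects: int
    block_size: int
    #: mean/sd of prediction per session block x trial type across subjects
    table: pd.DataFrame
    #: per-subject qualitative indices and their group mean
    indices: dict[str, float] = field(default_factory=dict)


def pair_schedules(
    design: DesignSpec, base_seed: int, pair_id: int = 0
) -> list[tuple[str, int, int, TrialSchedule]]:
    """Realize every session of a design for one yoked pair.

    Returns ``(phase_name, global_session, session_in_phase, schedule)``
    tuples; each session draws from an independent stream derived from
    ``(base_seed, pair_id, phase, session)``.
    """
    out = []
    global_session = 0
    for phase_index, phase in enumerate(design.phases):
        for s in range(1, phase.n_sessions + 1):
            global_session += 1
            sched = generate_session(
                phase, s, session_seed(base_seed, pair_id, phase_index, s)
            )
            out.append((phase.name, global_session, s, sched))
    return out


def _simulate(
    design: DesignSpec,
    schedules: list[tuple[str, int, int, TrialSchedule]],
    params: ModelParams,
    rep: RepresentationConfig,
    group: str,
    pair_id: int,
) -> SubjectTrajectory:
    # enumerate the units any trial type of this design can activate
    unit_index: dict[str, int] = {}
    type_units: dict[str, tuple[str, ...]] = {}
    for phase in design.phases:
        for t in list(phase.trial_types) + list(phase.probe_types):
            if t.name not in type_units:
                units = active_units(t.cues, rep)
                type_units[t.name] = units
                for u in units:
                    unit_index.setdefault(u, len(unit_index))
    n_units = len(unit_index)
    idx_of = {
        name: np.array([unit_index[u] for u in units], dtype=np.intp)
        for name, units in type_units.items()
    }
    rate_of = {
        name: np.array(
            [params.alpha_for(u, rep) * params.beta for u in units]
        )
        for name, units in type_units.items()
    }

    V = np.zeros(n_units)
    lam, w_pos, w_neg = params.lam, params.w_pos, params.w_neg

    phase_col: list[str] = []
    sess_col: list[int] = []
    sess_in_phase_col: list[int] = []
    tidx_col: list[int] = []
    type_col: list[str] = []
    reinf_col: list[bool] = []
    probe_col: list[bool] = []
    preds: list[float] = []

    for phase_name, gsess, sess, sched in schedules:
        for tr in sched.trials:
            idx = idx_of[tr.trial_type]
            pred = float(V[idx].sum())
            delta = lam * (1.0 if tr.reinforced else 0.0) - pred
            if delta != 0.0:
                w = w_pos if delta > 0 else w_neg
                V[idx] += rate_of[tr.trial_type] * (w * delta)
            phase_col.append(phase_name)
            sess_col.append(gsess)
            sess_in_phase_col.append(sess)
            tidx_col.append(tr.trial_index)
            type_col.append(tr.trial_type)
            reinf_col.append(tr.reinforced)
            probe_col.append(tr.probe)
            preds.append(pred)

    records = pd.DataFrame(
        {
            "phase": phase_col,
            "session": np.array(sess_col, dtype=np.int64),
            "session_in_phase": np.array(sess_in_phase_col, dtype=np.int64),
            "trial_index": np.array(tidx_col, dtype=np.int64),
            "trial_type": type_col,
            "reinforced": np.array(reinf_col, dtype=bool),
            "probe": np.array(probe_col, dtype=bool),
            "prediction": np.array(preds),
        },
        columns=RECORD_COLUMNS,
    )
    state = AssociativeState(
        {u: float(V[i]) for u, i in unit_index.items() if V[i] != 0.0}
    )
    return SubjectTrajectory(design.experiment_id, group, pair_id, records, state)


def run_subject(
    design: DesignSpec,
    params: ModelParams,
    rep: RepresentationConfig | None = None,
    seed: int = 0,
    pair_id: int = 0,
    group: str = "agency",
) -> SubjectTrajectory:
    """Simulate one subject over a fresh schedule realization of ``design``."""
    rep = rep if rep is not None else default_representation(design.experiment_id)
    schedules = pair_schedules(design, seed, pair_id)
    return _simulate(design, schedules, params, rep, group, pair_id)


def run_yoked_groups(
    design: DesignSpec,
    agency_params: ModelParams,
    passive_params: ModelParams,
    n_pairs: int = 8,
    seed: int = 0,
    rep: RepresentationConfig | None = None,
    block_size: int = 2,
) -> tuple[list[SubjectTrajectory], dict[str, GroupSummary]]:
    """Simulate ``n_pairs`` master-yoked pairs of one design.

    Each pair shares one schedule realization; the two members differ
    only in parameters.  Returns all trajectories (agency then passive
    interleaved by pair) and a per-group summary.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rep = rep if rep is not None else default_representation(design.experiment_id)
    trajectories: list[SubjectTrajectory] = []
    for pair in range(n_pairs):
        schedules = pair_schedules(design, seed, pair)
        trajectories.append(
            _simulate(design, schedules, agency_params, rep, "agency", pair)
        )
        trajectories.append(
            _simulate(design, schedules, passive_params, rep, "passive", pair)
        )
    summaries = {
        g: _summarize(design, [t for t in trajectories if t.group == g], block_size)
        for g in ("agency", "passive")
    }
    return trajectories, summaries


def _summarize(
    design: DesignSpec, trajs: list[SubjectTrajectory], block_size: int
) -> GroupSummary:
    per_subject = []
    for t in trajs:
        blocks = session_block_means(t, block_size)
        blocks = blocks.assign(pair_id=t.pair_id)
        per_subject.append(blocks)
    table = (
        pd.concat(per_subject, ignore_index=True)
        .groupby(["block", "trial_type", "probe"], as_index=False)
        .agg(
            mean=("prediction", "mean"),
            sd=("prediction", "std"),
            n_subjects=("prediction", "size"),
        )
    )
    indices: dict[str, float] = {}
    if design.experiment_id == "exp4_patterning":
        for problem in ("negative", "positive"):
            vals = [patterning_index(t, problem) for t in trajs]
            indices[f"{problem}_patterning"] = float(np.mean(vals))
    else:
        vals = [competition_index(t, design) for t in trajs]
        indices["competition"] = float(np.mean(vals))
    first = trajs[0]
    return GroupSummary(
        design.experiment_id, first.group, len(trajs), block_size, table, indices
    )


def session_block_means(
    trajectory: SubjectTrajectory, block_size: int
) -> pd.DataFrame:
    """Average one subject's session x trial-type means over session blocks.

    Blocks are non-overlapping runs of ``block_size`` consecutive global
    sessions; a trailing partial block is kept and flagged.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    sm = trajectory.session_means()
    if sm.empty:
        return pd.DataFrame(
            columns=["block", "trial_type", "probe", "prediction",
                     "n_sessions", "partial"]
        )
    sm = sm.assign(block=(sm["session"] - 1) // block_size + 1)
    out = (
        sm.groupby(["block", "trial_type", "probe"], as_index=False)
        .agg(prediction=("prediction", "mean"), n_sessions=("session", "nunique"))
    )
    full = sm.groupby("block")["session"].nunique()
    out["partial"] = out["block"].map(full < block_size)
    return out


# --------------------------------------------------------------------------
# qualitative indices

#: sessions feeding each design's competition index, chosen to mirror
#: where the probe analyses are run: exp1 the last four probe sessions,
#: exp2 the final two session blocks of X(0)/Y(1) monitoring trials,
#: exp3 every probe session (13 onward)
def _competition_window(design: DesignSpec) -> tuple[str, int, int, bool]:
    """Return (phase, first_session, last_session, probes_only), global sessions."""
    if design.experiment_id == "exp1_blocking":
        last = design.n_sessions
        return ("compound", last - 3, last, True)
    if design.experiment_id == "exp2_competition":
        last = design.n_sessions
        return ("compound", last - 3, last, False)
    if design.experiment_id == "exp3_no_configural":
        pre = design.phases[0].n_sessions
        start = pre + design.phases[1].probe_start_session
        return ("compound", start, design.n_sessions, True)
    raise ValueError(
        f"design {design.experiment_id!r} has no competition index window"
    )


def competition_index(trajectory: SubjectTrajectory, design: DesignSpec) -> float:
    """Terminal Y-minus-X contrast: positive means competitive assignment.

    The index is the mean prediction on the design's X/Y assessment
    trials (probe trials for exp1/exp3; solo X(0) and Y(1) monitoring
    trials for exp2) over the design's terminal window.
    """
    if trajectory.experiment_id != design.experiment_id:
        raise ValueError("trajectory and design belong to different experiments")
    phase, lo, hi, probes_only = _competition_window(design)
    r = trajectory.records
    win = r[(r["session"] >= lo) & (r["session"] <= hi)]
    if probes_only:
        win = win[win["probe"]]
    win = win[win["trial_type"].isin(["X", "Y"])]
    if win.empty:
        raise ValueError(
            f"no X/Y assessment trials in sessions {lo}-{hi} of "
            f"{design.experiment_id}"
        )
    means = win.groupby("trial_type")["prediction"].mean()
    if "X" not in means or "Y" not in means:
        raise ValueError("assessment window lacks X or Y trials")
    return float(means["Y"] - means["X"])


#: exp4 is plotted in 3-session blocks; the index window is the last
#: four such blocks
_PATTERNING_BLOCK = 3
_PATTERNING_TERMINAL_BLOCKS = 4


def patterning_index(trajectory: SubjectTrajectory, problem: str) -> float:
    """Signed patterning discrimination over the terminal window.

    negative: mean elemental (A, X) prediction minus AX prediction;
    positive: BY prediction minus mean elemental (B, Y) prediction.
    Positive values mean the discrimination is solved in the right
    direction; an untrained subject scores 0.
    """
    if trajectory.experiment_id != "exp4_patterning":
        raise ValueError("patterning_index applies to exp4_patterning only")
    if problem not in ("negative", "positive"):
        raise ValueError("problem must be 'negative' or 'positive'")
    r = trajectory.records
    if r.empty:
        return 0.0
    last = int(r["session"].max())
    lo = last - _PATTERNING_BLOCK * _PATTERNING_TERMINAL_BLOCKS + 1
    win = r[r["session"] >= lo]
    means = win.groupby("trial_type")["prediction"].mean()
    if problem == "negative":
        elem = (means.get("A", 0.0) + means.get("X", 0.0)) / 2
        return float(elem - means.get("AX", 0.0))
    elem = (means.get("B", 0.0) + means.get("Y", 0.0)) / 2
    return float(means.get("BY", 0.0) - elem)
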