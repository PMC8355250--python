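"""Tidy-table export of schedules and trajectories."""

from __future__ import annotations

import pandas as pd

from .designs import SubjectSchedule
from .engine import SubjectTrajectory

SCHEDULE_COLUMNS = [
    "experiment", "pair", "group", "session", "trial_index",
    "trial_type", "cues", "reinforced", "probe",
]


def schedules_to_frame(
    assignments: list[tuple[str, int, SubjectSchedule]]
) -> pd.DataFrame:
    """Flatten (experiment, session, subject-schedule) triples to tidy rows."""
    rows = []
    for experiment, session, sub in assignments:
        for tr in sub.schedule.trials:
            rows.append(
                (
                    experiment, sub.pair_id, sub.group, session,
                    tr.trial_index, tr.trial_type,
                    "".join(sorted(tr.cues)), tr.reinforced, tr.probe,
                )
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def trajectory_to_frame(traj: SubjectTrajectory) -> pd.DataFrame:
    """Per-trial records of one simulated subject with identity columns."""
    df = traj.records.copy()
    df.insert(0, "experiment", traj.experiment_id)
    df.insert(1, "group", traj.group)
    df.insert(2, "pair_id", traj.pair_id)
    return df
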