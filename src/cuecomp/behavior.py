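"""Synthetic head-entry-count datasets from simulated associative strengths.

The measured behavior is goal-tracking: anticipatory head entries into
the sucrose magazine during the last 5 s of each 10-s cue.  A subject's
expected count on a trial is a saturating linear function of the
aggregate prediction for that trial's cues,

    rate = min(ceiling, baseline + gain * max(V, 0)),

with Poisson (optionally overdispersed negative-binomial) trial-level
noise.  Counts are then averaged within subject x session x trial type,
which is exactly the shape the analysis stage consumes: one response
value per subject, per cue, per session, for two gender-balanced groups
of yoked pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import DesignSpec
from .engine import run_yoked_groups
from .model import ModelParams, RepresentationConfig

__all__ = [
    "ResponseMapParams",
    "DATASET_COLUMNS",
    "expected_rate",
    "sample_trial_counts",
    "generate_dataset",
]

DATASET_COLUMNS = [
    "experiment", "subject_id", "group", "pair_id", "sex",
    "session", "trial_type", "probe", "mean_entries", "n_trials",
]


@dataclass(frozen=True)
class ResponseMapParams:
    """Learning-to-performance map and noise model.

    ``baseline_rate`` is the expected entries per 5-s window for an
    untrained cue, ``gain`` the additional entries per unit of
    associative strength, ``ceiling`` the saturation level of the
    measure.  ``noise`` is ``"poisson"`` or ``"overdispersed"``; the
    latter is negative-binomial with shape ``dispersion_k`` (variance
    rate + rate^2 / k).
    """

    baseline_rate: float = 0.5
    gain: float = 5.0
    ceiling: float = 6.0
    noise: str = "poisson"
    dispersion_k: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("baseline_rate and gain must be non-negative")
        if self.ceiling < self.baseline_rate:
            raise ValueError("ceiling must be >= baseline_rate")
        if self.noise not in ("poisson", "overdispersed"):
            raise ValueError("noise must be 'poisson' or 'overdispersed'")
        if self.dispersion_k <= 0:
            raise ValueError("dispersion_k must be positive")


def expected_rate(V_sum, map_params: ResponseMapParams):
    """Expected head entries for aggregate strength ``V_sum``.

    Monotone non-decreasing; inhibitory (negative) aggregate strength
    floors at the baseline approach rate.
    """
    v = np.maximum(np.asarray(V_sum, dtype=float), 0.0)
    return np.minimum(map_params.ceiling, map_params.baseline_rate + map_params.gain * v)


def sample_trial_counts(rate, map_params: ResponseMapParams, rng) -> np.ndarray:
    """Draw integer head-entry counts at the given expected rate(s)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(rng)
    if map_params.noise == "poisson":
        return rng.poisson(rate)
    # negative binomial via gamma-Poisson mixture; rate 0 stays 0
    k = map_params.dispersion_k
    lam = rng.gamma(shape=k, scale=np.where(rate > 0, rate / k, 0.0))
    return rng.poisson(lam)


def generate_dataset(
    design: DesignSpec,
    agency_params: ModelParams,
    passive_params: ModelParams,
    map_params: ResponseMapParams | None = None,
    n_pairs: int = 8,
    seed: int = 0,
    rep: RepresentationConfig | None = None,
    omission_prob: float = 0.0,
) -> pd.DataFrame:
    """Simulate a full master-yoked behavioral dataset.

    Runs ``n_pairs`` yoked pairs, samples a head-entry count for every
    trial from the subject's momentary prediction, and averages within
    subject x session x trial type.  Sex alternates across pairs and is
    matched within a pair (the groups are gender-balanced).  With
    ``omission_prob`` > 0, each trial is independently dropped for both
    members of a pair before averaging, emulating forgone trial offers.
    """
    map_params = map_params or ResponseMapParams()
    if not 0.0 <= omission_prob < 1.0:
        raise ValueError("omission_prob must lie in [0, 1)")
    trajectories, _ = run_yoked_groups(
        design, agency_params, passive_params, n_pairs=n_pairs, seed=seed, rep=rep
    )
    count_root = np.random.SeedSequence([int(seed), 2**20])
    count_seeds = count_root.spawn(len(trajectories))
    omit_root = np.random.SeedSequence([int(seed), 2**21])
    omit_seeds = omit_root.spawn(n_pairs)

    frames = []
    for traj, css in zip(trajectories, count_seeds):
        rng = np.random.default_rng(css)
        rec = traj.records
        counts = sample_trial_counts(
            expected_rate(rec["prediction"].to_numpy(), map_params),
            map_params, rng,
        )
        keep = np.ones(len(rec), dtype=bool)
        if omission_prob > 0:
            # identical omission draws for both members of the pair
            orng = np.random.default_rng(omit_seeds[traj.pair_id])
            keep = orng.random(len(rec)) >= omission_prob
        df = rec.loc[keep, ["session", "trial_type", "probe"]].copy()
        df["entries"] = counts[keep]
        agg = (
            df.groupby(["session", "trial_type", "probe"], as_index=False)
            .agg(mean_entries=("entries", "mean"), n_trials=("entries", "size"))
        )
        agg.insert(0, "experiment", traj.experiment_id)
        agg.insert(1, "subject_id", f"{traj.group[0]}{traj.pair_id:02d}")
        agg.insert(2, "group", traj.group)
        agg.insert(3, "pair_id", traj.pair_id)
        agg.insert(4, "sex", "F" if traj.pair_id % 2 == 0 else "M")
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out[DATASET_COLUMNS]
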