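"""Analysis stage: session means, contrasts, permutation tests, bias recovery.

Mirrors the comparison structure of a master-yoked conditioning study on
a tidy behavioral dataset (one response value per subject x session x
cue): within-subject cue contrasts with Cohen's d, a permutation
group x cue interaction test that respects the yoked pairing, Bonferroni
correction across a family of planned contrasts, and a grid-search
harness that recovers the positivity-bias ratio w_neg / w_pos from a
dataset by matching simulated group-mean learning curves.

The permutation tests replace the mixed ANOVA used with real subjects:
the cue contrast sign-flips per-subject cue differences, and the
interaction test swaps group labels within yoked pairs, which is exactly
the exchangeability the yoked design guarantees under the null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import ResponseMapParams, expected_rate
from .designs import DesignSpec
from .engine import run_subject, session_block_means
from .model import DEFAULT_ALPHA, ModelParams, RepresentationConfig, bias_params

__all__ = [
    "ContrastResult",
    "InteractionResult",
    "BiasRecoveryResult",
    "session_cue_means",
    "cue_contrast",
    "group_by_cue_interaction",
    "fit_bias_ratio",
    "bonferroni",
]

logger = logging.getLogger(__name__)

_REQUIRED = ["subject_id", "group", "pair_id", "session", "trial_type",
             "mean_entries"]


def _check_schema(dataset: pd.DataFrame) -> None:
    for col in _REQUIRED:
        if col not in dataset.columns:
            raise ValueError(f"dataset lacks required column {col!r}")


def session_cue_means(dataset: pd.DataFrame) -> pd.DataFrame:
    """One response value per subject x session x trial type.

    Idempotent on already-aggregated data.  When several rows share a
    key (e.g. trial-level input) they are averaged, weighted by
    ``n_trials`` when that column is present.  Subjects missing a
    session that others have are logged, not imputed.
    """
    _check_schema(dataset)
    keys = [c for c in ("experiment", "subject_id", "group", "pair_id", "sex",
                        "session", "trial_type", "probe") if c in dataset.columns]
    df = dataset.copy()
    if "n_trials" in df.columns:
        df["_w"] = df["n_trials"].astype(float)
    else:
        df["_w"] = 1.0
    df["_wx"] = df["_w"] * df["mean_entries"]
    out = df.groupby(keys, as_index=False)[["_w", "_wx"]].sum()
    out["mean_entries"] = out["_wx"] / out["_w"]
    if "n_trials" in dataset.columns:
        out["n_trials"] = out["_w"].astype(int)
    out = out.drop(columns=["_w", "_wx"])

    sessions = dataset["session"].unique()
    per_subject = dataset.groupby("subject_id")["session"].nunique()
    short = per_subject[per_subject < len(sessions)]
    for subject, n in short.items():
        logger.warning(
            "subject %s has %d of %d sessions; missing sessions left absent",
            subject, n, len(sessions),
        )
    return out


def _sign_flip_pvalue(
    diffs: np.ndarray, n_perm: int, seed, statistic="mean"
) -> tuple[float, float, int]:
    """Two-sided sign-flip permutation p for the mean of paired differences.

    Enumerates all 2^n sign patterns when that is no more work than
    ``n_perm`` random draws (then p = #{|T*| >= |T|} / 2^n, which
    includes the identity); otherwise Monte-Carlo with the add-one
    estimator p = (1 + #{|T*| >= |T|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    t_obs = float(diffs.mean())
    tol = 1e-12 * max(1.0, abs(t_obs))
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        t_perm = signs @ diffs / n
        p = float(np.mean(np.abs(t_perm) >= abs(t_obs) - tol))
        return t_obs, p, 2**n
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    t_perm = signs @ diffs / n
    hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - tol))
    return t_obs, (1 + hits) / (1 + n_perm), n_perm


@dataclass
class ContrastResult:
    """A within-subject cue contrast in one group over a session window."""

    cue_pair: tuple[str, str]
    group: str
    window: tuple[int, int]
    n_subjects: int
    mean_difference: float
    cohens_d: float  # NaN when the paired differences have zero variance
    permutation_p: float
    n_permutations: int
    degenerate_variance: bool = False


def _window_means(
    df: pd.DataFrame, cue: str, window: tuple[int, int]
) -> pd.Series:
    lo, hi = window
    sub = df[
        (df["trial_type"] == cue) & (df["session"] >= lo) & (df["session"] <= hi)
    ]
    return sub.groupby("subject_id")["mean_entries"].mean()


def cue_contrast(
    dataset: pd.DataFrame,
    cue_a: str,
    cue_b: str,
    group: str,
    window: tuple[int, int],
    n_perm: int = 5000,
    seed: int = 0,
) -> ContrastResult:
    """Paired contrast of responding to two cues within one group.

    The statistic is the mean over subjects of (cue_a - cue_b) window
    means; Cohen's d is computed on the paired differences (d_z) and the
    two-sided p by sign-flipping subject differences.  Antisymmetric in
    the cue pair: swapping the cues flips the difference and d, p is
    unchanged.
    """
    _check_schema(dataset)
    g = dataset[dataset["group"] == group]
    a = _window_means(g, cue_a, window)
    b = _window_means(g, cue_b, window)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError(
            f"no subjects with both {cue_a!r} and {cue_b!r} in sessions "
            f"{window[0]}-{window[1]} of group {group!r}"
        )
    diffs = (a[common] - b[common]).to_numpy()
    t_obs, p, n_used = _sign_flip_pvalue(diffs, n_perm, seed)
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    degenerate = sd == 0.0
    d = float("nan") if degenerate else t_obs / sd
    return ContrastResult(
        (cue_a, cue_b), group, tuple(window), int(diffs.size),
        t_obs, d, p, n_used, degenerate,
    )


@dataclass
class InteractionResult:
    """Permutation group x cue interaction over yoked pairs."""

    cue_pair: tuple[str, str]
    window: tuple[int, int]
    n_pairs: int
    statistic: float  # (agency mean [a-b]) - (passive mean [a-b])
    permutation_p: float
    n_permutations: int


def group_by_cue_interaction(
    dataset: pd.DataFrame,
    cue_a: str,
    cue_b: str,
    window: tuple[int, int],
    n_perm: int = 5000,
    seed: int = 0,
) -> InteractionResult:
    """Test whether the cue_a - cue_b difference differs between groups.

    The null is built by swapping group labels within yoked pairs, i.e.
    sign-flipping each pair's (agency diff - passive diff) term — the
    exchange the yoked design licenses under "agency has no effect".
    """
    _check_schema(dataset)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    per_group = {}
    for group in ("agency", "passive"):
        g = dataset[dataset["group"] == group]
        if g.empty:
            raise ValueError(f"dataset lacks group {group!r}")
        a = _window_means(g, cue_a, window)
        b = _window_means(g, cue_b, window)
        common = a.index.intersection(b.index)
        diffs = (a[common] - b[common])
        pair_of = g.drop_duplicates("subject_id").set_index("subject_id")["pair_id"]
        per_group[group] = diffs.groupby(pair_of[diffs.index]).mean()
    ag, pa = per_group["agency"], per_group["passive"]
    pairs = ag.index.intersection(pa.index)
    if len(pairs) < len(ag) or len(pairs) < len(pa):
        raise ValueError("unpaired subjects: every pair needs both members")
    if len(pairs) == 0:
        raise ValueError("no complete yoked pairs in the window")
    pair_terms = (ag[pairs] - pa[pairs]).to_numpy()
    t_obs, p, n_used = _sign_flip_pvalue(pair_terms, n_perm, seed)
    return InteractionResult(
        (cue_a, cue_b), tuple(window), len(pairs), t_obs, p, n_used
    )


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni-adjust a family of p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    return np.minimum(1.0, p * p.size)


@dataclass
class BiasRecoveryResult:
    """Grid-search recovery of the positivity-bias ratio w_neg / w_pos."""

    estimated_ratio: float
    objective: float
    grid: tuple[float, ...]
    objectives: tuple[float, ...]
    true_ratio: float | None = None


def fit_bias_ratio(
    dataset: pd.DataFrame,
    design: DesignSpec,
    grid,
    map_params: ResponseMapParams | None = None,
    n_sim_per_point: int = 2,
    seed: int = 0,
    block_size: int = 2,
    alpha: float = DEFAULT_ALPHA,
    rep: RepresentationConfig | None = None,
    true_ratio: float | None = None,
) -> BiasRecoveryResult:
    """Recover the bias ratio of the dataset's agency group by grid search.

    For each candidate ratio r the model is run with the parameters of
    the one-parameter bias family (:func:`cuecomp.model.bias_params`)
    over ``n_sim_per_point`` schedule realizations (shared across grid
    points, so candidates differ only in the parameter); per-trial
    predictions are pushed through the response map without noise,
    averaged into session-block x trial-type mean curves, and scored by
    squared error against the agency group's observed curve.  Returns
    the arg-min ratio.
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("grid of candidate ratios is empty")
    if any(not 0 < g <= 1 for g in grid):
        raise ValueError("candidate ratios must lie in (0, 1]")
    map_params = map_params or ResponseMapParams()
    _check_schema(dataset)
    target = (
        dataset[dataset["group"] == "agency"]
        .assign(block=lambda d: (d["session"] - 1) // block_size + 1)
        .groupby(["block", "trial_type"])["mean_entries"].mean()
    )

    objectives = []
    for r in grid:
        params = bias_params(r, alpha=alpha)
        curves = []
        for k in range(n_sim_per_point):
            traj = run_subject(design, params, rep=rep, seed=seed, pair_id=k)
            blocks = session_block_means(traj, block_size)
            blocks["rate"] = expected_rate(
                blocks["prediction"].to_numpy(), map_params
            )
            curves.append(blocks.groupby(["block", "trial_type"])["rate"].mean())
        sim = pd.concat(curves, axis=1).mean(axis=1)
        joined = pd.concat([target, sim], axis=1, join="inner")
        if joined.empty:
            raise ValueError("no overlapping session blocks between data and model")
        resid = joined.iloc[:, 0] - joined.iloc[:, 1]
        objectives.append(float(np.sum(resid**2)))
    best = int(np.argmin(objectives))
    return BiasRecoveryResult(
        grid[best], objectives[best], grid, tuple(objectives), true_ratio
    )
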