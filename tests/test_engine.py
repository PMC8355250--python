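"""Simulation over designs: yoking, aggregation, qualitative indices."""

import numpy as np
import pandas as pd
import pytest

import cuecomp as cc
from cuecomp.designs import DesignSpec, PhaseSpec, TrialType
from cuecomp.engine import RECORD_COLUMNS, SubjectTrajectory
from cuecomp.model import AssociativeState


def _fake_trajectory(experiment_id, rows):
    """rows: (session, trial_type, reinforced, probe, prediction)."""
    df = pd.DataFrame(
        [
            ("p", s, s, i, tt, r, pr, v)
            for i, (s, tt, r, pr, v) in enumerate(rows)
        ],
        columns=RECORD_COLUMNS,
    )
    return SubjectTrajectory(experiment_id, "agency", 0, df, AssociativeState())


class TestRunSubject:
    def test_zero_sessions_empty_trajectory(self):
        design = DesignSpec(
            "exp1_blocking",
            (PhaseSpec("pretraining", (TrialType("A", 48, 0),), n_sessions=0),),
        )
        traj = cc.run_subject(design, cc.agency_params(), seed=0)
        assert traj.records.empty

    def test_deterministic_given_seed(self, designs, default_params):
        ap, _ = default_params
        d = designs["exp2_competition"]
        t1 = cc.run_subject(d, ap, seed=5)
        t2 = cc.run_subject(d, ap, seed=5)
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_blocking_direction_under_preasymptotic_pretraining(
        self, designs, default_params
    ):
        """With agency params, X ends the compound phase weaker than Y."""
        ap, _ = default_params
        traj = cc.run_subject(designs["exp1_blocking"], ap, seed=2)
        assert traj.final_state.strength("A") < 1.0  # preasymptotic
        assert traj.final_state.strength("X") < traj.final_state.strength("Y")

    def test_asymptotic_pretraining_blocks_completely_in_both_groups(
        self, designs
    ):
        d = designs["exp1_blocking"]
        for params in (
            cc.agency_params(alpha=0.3),
            cc.passive_params(alpha=0.3),
        ):
            traj = cc.run_subject(d, params, seed=2)
            assert traj.final_state.strength("X") == pytest.approx(0.0, abs=1e-6)

    def test_trial_counts_match_schedule(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp1_blocking"], ap, seed=0)
        per_session = traj.records.groupby("session").size()
        assert (per_session.loc[1:14] == 96).all()
        assert (per_session.loc[15:22] == 96).all()  # compound before probes
        assert (per_session.loc[23:34] == 100).all()


class TestRunYokedGroups:
    def test_sixteen_trajectories_eight_shared_schedules(
        self, designs, default_params
    ):
        ap, pp = default_params
        trajs, _ = cc.run_yoked_groups(
            designs["exp3_no_configural"], ap, pp, n_pairs=8, seed=4
        )
        assert len(trajs) == 16
        by_pair = {}
        for t in trajs:
            by_pair.setdefault(t.pair_id, []).append(t)
        assert len(by_pair) == 8
        for pair_trajs in by_pair.values():
            a, p = pair_trajs
            events_a = a.records[["trial_type", "reinforced", "probe"]]
            events_p = p.records[["trial_type", "reinforced", "probe"]]
            pd.testing.assert_frame_equal(events_a, events_p)

    def test_equal_params_give_identical_summaries(self, designs):
        pp = cc.passive_params()
        _, summaries = cc.run_yoked_groups(
            designs["exp2_competition"], pp, pp, n_pairs=2, seed=1
        )
        pd.testing.assert_frame_equal(
            summaries["agency"].table, summaries["passive"].table
        )

    def test_yoking_invariance(self, designs, default_params):
        """Passive trajectories never depend on the agency parameters."""
        _, pp = default_params
        d = designs["exp1_blocking"]
        t1, _ = cc.run_yoked_groups(d, cc.agency_params(), pp, n_pairs=2, seed=9)
        t2, _ = cc.run_yoked_groups(
            d, cc.agency_params(w_neg=1.0), pp, n_pairs=2, seed=9
        )
        for a, b in zip(t1, t2):
            if a.group == "passive":
                pd.testing.assert_frame_equal(a.records, b.records)

    def test_n_pairs_must_be_positive(self, designs, default_params):
        ap, pp = default_params
        with pytest.raises(ValueError):
            cc.run_yoked_groups(designs["exp1_blocking"], ap, pp, n_pairs=0)


class TestSessionBlockMeans:
    def test_twenty_sessions_block_two_gives_ten_blocks(
        self, designs, default_params
    ):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp2_competition"], ap, seed=0)
        compound = traj.records[traj.records["phase"] == "compound"]
        traj.records = compound
        blocks = cc.session_block_means(traj, 2)
        assert blocks["block"].nunique() == 10
        assert not blocks["partial"].any()

    def test_block_one_is_identity(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp4_patterning"], ap, seed=0)
        blocks = cc.session_block_means(traj, 1)
        sm = traj.session_means()
        assert len(blocks) == len(sm)
        assert np.allclose(
            blocks.sort_values(["block", "trial_type"])["prediction"].to_numpy(),
            sm.sort_values(["session", "trial_type"])["prediction"].to_numpy(),
        )

    def test_partial_trailing_block_flagged(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp1_blocking"], ap, seed=0)
        blocks = cc.session_block_means(traj, 4)  # 34 sessions -> 8 full + 1 partial
        partial = blocks[blocks["partial"]]
        assert set(partial["block"]) == {9}

    def test_constant_series_preserved(self):
        traj = _fake_trajectory(
            "exp4_patterning",
            [(s, "A", True, False, 0.7) for s in range(1, 7)],
        )
        blocks = cc.session_block_means(traj, 3)
        assert np.allclose(blocks["prediction"], 0.7)

    def test_invalid_block_size(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp4_patterning"], ap, seed=0)
        with pytest.raises(ValueError):
            cc.session_block_means(traj, 0)


class TestCompetitionIndex:
    def test_identical_strengths_give_zero(self, designs):
        rows = []
        for s in (31, 32, 33, 34):
            rows += [(s, "X", False, True, 0.4), (s, "Y", False, True, 0.4)]
        traj = _fake_trajectory("exp1_blocking", rows)
        assert cc.competition_index(traj, designs["exp1_blocking"]) == 0.0

    def test_missing_probes_raise(self, designs):
        traj = _fake_trajectory("exp1_blocking", [(31, "A", True, False, 0.9)])
        with pytest.raises(ValueError, match="X/Y"):
            cc.competition_index(traj, designs["exp1_blocking"])

    def test_design_mismatch_raises(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp1_blocking"], ap, seed=0)
        with pytest.raises(ValueError):
            cc.competition_index(traj, designs["exp2_competition"])

    def test_exp4_has_no_competition_window(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp4_patterning"], ap, seed=0)
        with pytest.raises(ValueError):
            cc.competition_index(traj, designs["exp4_patterning"])


class TestPatterningIndex:
    def test_untrained_state_scores_zero(self):
        rows = [(s, tt, tt in ("A", "X", "BY"), False, 0.0)
                for s in range(31, 43) for tt in ("A", "X", "AX", "B", "Y", "BY")]
        traj = _fake_trajectory("exp4_patterning", rows)
        assert cc.patterning_index(traj, "negative") == 0.0
        assert cc.patterning_index(traj, "positive") == 0.0

    def test_wrong_design_raises(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp1_blocking"], ap, seed=0)
        with pytest.raises(ValueError):
            cc.patterning_index(traj, "negative")

    def test_unknown_problem_raises(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp4_patterning"], ap, seed=0)
        with pytest.raises(ValueError):
            cc.patterning_index(traj, "sideways")

    def test_solved_discriminations_score_positive(self, designs, default_params):
        ap, _ = default_params
        traj = cc.run_subject(designs["exp4_patterning"], ap, seed=0)
        assert cc.patterning_index(traj, "negative") > 0
        assert cc.patterning_index(traj, "positive") > 0
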