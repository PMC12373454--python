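"""Synthetic cohort generator: mixtures, calibration, end-to-end structure."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from schemagaze.board import EMPTY, Board
from schemagaze.cohort import (
    ScenarioConfig,
    _board_policy,
    calibrate_fixation_mixing,
    generate_cohort,
    generate_encoding_fixations,
    generate_retrieval_fixations,
    load_scenario,
    piece_count_pmf,
    sample_stimulus_board,
    schema_mixture,
)
from schemagaze.gaze import FixationMap, fixation_map
from schemagaze.policy import move_distribution
from schemagaze.retrieval import schema_regression


def test_piece_count_pmf_moments():
    pmf = piece_count_pmf(13.52, 5.97, 4, 31)
    ks = np.arange(4, 32)
    mean = pmf @ ks
    sd = np.sqrt(pmf @ (ks - mean) ** 2)
    assert mean == pytest.approx(13.52, abs=1e-4)
    assert sd == pytest.approx(5.97, abs=1e-4)
    assert pmf.sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def stim(weights):
    rng = np.random.default_rng(99)
    pmf = piece_count_pmf(13.52, 5.97, 4, 31)
    board = sample_stimulus_board(pmf, 4, _board_policy(weights), rng)
    return board, move_distribution(board, weights)


class TestEncodingFixations:
    def test_full_schema_mixing_tracks_model(self, stim, weights):
        # plain-mixture semantics (lambda_diffuse=1): at lam=1 the
        # empty-square allocation follows the model distribution exactly
        board, dist = stim
        cfg = ScenarioConfig()
        cfg.fixation.jitter_px = 0.0
        cfg.fixation.occupied_mass = 0.0
        cfg.fixation.lambda_diffuse = 1.0
        rng = np.random.default_rng(1)
        total = np.zeros(36)
        for _ in range(150):
            evs = generate_encoding_fixations(board, dist, cfg, rng, lam=1.0)
            total += fixation_map(evs, cfg.geometry).weights
        shares = total / total.sum()
        support = board.flat == EMPTY
        assert sps.pearsonr(shares[support], dist.probs[support])[0] > 0.97

    def test_zero_mixing_is_uncoupled(self, stim):
        board, dist = stim
        cfg = ScenarioConfig()
        cfg.fixation.occupied_mass = 0.0
        cfg.fixation.lambda_diffuse = 1.0
        rng = np.random.default_rng(2)
        total = np.zeros(36)
        for _ in range(150):
            evs = generate_encoding_fixations(board, dist, cfg, rng, lam=0.0)
            total += fixation_map(evs, cfg.geometry).weights
        support = board.flat == EMPTY
        r = sps.pearsonr(total[support], dist.probs[support])[0]
        assert abs(r) < 0.35  # no systematic coupling beyond noise

    def test_durations_fit_the_preview_window(self, stim):
        board, dist = stim
        cfg = ScenarioConfig(preview_s=8.0)
        rng = np.random.default_rng(3)
        for _ in range(30):
            evs = generate_encoding_fixations(board, dist, cfg, rng)
            assert sum(e.duration_ms for e in evs) <= 8000.0
            assert len(evs) >= 1


class TestRetrievalFixations:
    def test_pure_schema_mixture_recovers_unit_weight(self, stim):
        board, dist = stim
        cfg = ScenarioConfig()
        cfg.retrieval.pi_base, cfg.retrieval.pi_slope = 1.0, 0.0
        cfg.retrieval.pi_correct, cfg.retrieval.pi_max = 0.0, 1.0
        support = board.flat == EMPTY
        correct = int(np.flatnonzero(support)[2])
        # exact mixture map (no sampling noise): w_moveProb is exactly 1
        p = schema_mixture(dist, support, correct, 0.0, cfg.retrieval)
        res = schema_regression(FixationMap(p), board, dist, correct)
        assert res.w_move_prob == pytest.approx(1.0, abs=1e-9)

    def test_pure_episodic_mixture_recovers_correct_move(self, stim):
        board, dist = stim
        cfg = ScenarioConfig()
        cfg.retrieval.pi_base, cfg.retrieval.pi_slope = 0.0, 0.0
        cfg.retrieval.pi_correct, cfg.retrieval.pi_min = 1.0, 0.0
        support = board.flat == EMPTY
        correct = int(np.flatnonzero(support)[2])
        p = schema_mixture(dist, support, correct, 0.0, cfg.retrieval)
        res = schema_regression(FixationMap(p), board, dist, correct)
        assert res.w_correct_move == pytest.approx(1.0, abs=1e-9)

    def test_sampled_fixations_track_mixture(self, stim):
        board, dist = stim
        cfg = ScenarioConfig()
        support = board.flat == EMPTY
        correct = int(np.flatnonzero(support)[2])
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(60):
            evs = generate_retrieval_fixations(board, dist, correct, 0.0, cfg, rng)
            res = schema_regression(fixation_map(evs, cfg.geometry), board,
                                    dist, correct)
            if not res.flagged:
                vals.append(res.w_move_prob)
        assert np.mean(vals) == pytest.approx(cfg.retrieval.pi_base, abs=0.08)


class TestCalibration:
    def test_monotone_in_lambda(self):
        # non-decreasing in expectation; allow small simulation noise
        from schemagaze.cohort import _encoding_corr

        cfg = ScenarioConfig(design="exp2", n_blocks=4)
        rs = [_encoding_corr(cfg, lam, 8, 77) for lam in (0.1, 0.5, 0.9)]
        assert rs[2] > rs[0]
        assert rs[1] >= rs[0] - 0.02 and rs[2] >= rs[1] - 0.02

    def test_small_target_gives_small_lambda(self):
        # plain-mixture fixations (no central-bias floor): a small target
        # correlation needs only a small schema coupling
        cfg = ScenarioConfig(design="exp2", n_blocks=3)
        cfg.fixation.lambda_diffuse = 1.0
        lam, achieved = calibrate_fixation_mixing(cfg, 0.08, n_subjects=6,
                                                  tol=0.02)
        assert lam < 0.15
        assert achieved == pytest.approx(0.08, abs=0.02)

    def test_target_below_floor_errors(self):
        # the packaged candidate-set model has a central-bias floor on the
        # correlation; targets below it are rejected
        cfg = ScenarioConfig(design="exp2", n_blocks=3)
        with pytest.raises(ValueError):
            calibrate_fixation_mixing(cfg, 0.05, n_subjects=6, tol=0.02)

    def test_unattainable_target_errors(self):
        cfg = ScenarioConfig(design="exp2", n_blocks=2)
        with pytest.raises(ValueError):
            calibrate_fixation_mixing(cfg, 0.95, n_subjects=4)


class TestGenerateCohort:
    def test_structure_and_invariants(self, tiny_cohort):
        t = tiny_cohort.trials
        cfg_trials = 4 * 3 * 8
        assert len(t) == cfg_trials
        # z-scored measures standardized across the dataset
        assert t.move_logprob_z.mean() == pytest.approx(0.0, abs=1e-9)
        assert t.move_logprob_z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        # every trial has preview fixations within the window
        f = tiny_cohort.fixations
        per_phase = f.groupby(["subject", "block", "trial", "phase"]).duration_ms.sum()
        assert per_phase.loc[:, :, :, "preview"].max() <= 8000.0
        assert per_phase.loc[:, :, :, "preview"].count() == cfg_trials
        # exp2 condition multiset per block
        for _, g in t.groupby(["subject", "block"]):
            assert sorted(g.condition)[:4] == ["probable_predicted"] * 4
        # boards are valid stimuli
        for b in t.board:
            Board.from_string(b).validate(stimulus=True)

    def test_same_seed_reproduces_exactly(self):
        cfg = ScenarioConfig(design="exp2", n_subjects=2, n_blocks=2)
        cfg.fixation.lambda_enc = 0.25
        a = generate_cohort(cfg, seed=42)
        b = generate_cohort(cfg, seed=42)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.fixations, b.fixations)
        assert a.provenance["config_hash"] == b.provenance["config_hash"]

    def test_different_seeds_differ(self):
        cfg = ScenarioConfig(design="exp2", n_subjects=2, n_blocks=2)
        a = generate_cohort(cfg, seed=1)
        b = generate_cohort(cfg, seed=2)
        assert not a.trials.board.equals(b.trials.board)

    def test_null_response_model_gives_half_accuracy(self):
        cfg = ScenarioConfig(design="exp2", n_subjects=4, n_blocks=4)
        cfg.response.target_accuracy = None
        cfg.response.b0 = 0.0
        cfg.response.sigma_u = 0.0
        ds = generate_cohort(cfg, seed=8)
        acc = ds.trials.correct.mean()
        assert acc == pytest.approx(0.5, abs=2.5 * np.sqrt(0.25 / len(ds.trials)))

    def test_strong_probability_effect_is_monotone(self):
        cfg = ScenarioConfig(design="exp2", n_subjects=6, n_blocks=5)
        cfg.response.b_prob = 2.0
        cfg.response.sigma_u = 0.0
        ds = generate_cohort(cfg, seed=9)
        t = ds.trials
        quartile = pd.qcut(t.move_logprob_z, 4, labels=False)
        accs = t.groupby(quartile).correct.mean()
        assert accs.iloc[3] > accs.iloc[0] + 0.2

    def test_exp1_design_uses_four_conditions(self):
        cfg = ScenarioConfig(design="exp1", n_subjects=2, n_blocks=2,
                             preview_s=10.0)
        ds = generate_cohort(cfg, seed=10)
        labels = set(ds.trials.condition)
        assert labels == {
            "probable_predicted", "probable_unpredicted",
            "improbable_predicted", "improbable_unpredicted",
        }


def test_packaged_scenarios_load():
    for name in ("exp1_marginal", "exp2_marginal", "exp2_schema_pathway",
                 "exp2_confidence", "exp2_null", "full_calibrated"):
        cfg = load_scenario(name)
        assert cfg.name == name
        assert cfg.n_subjects in (37, 95)
    with pytest.raises(FileNotFoundError):
        load_scenario("no_such_scenario")
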