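"""Scenario-based synthetic cohorts with planted, calibratable effects.

Real participants cannot be re-run, so every analysis in this package is
validated by parameter recovery: a scenario plants the published effect
sizes as generative truth and the pipeline must recover them from the
simulated raw data (boards, fixation events, adaptively sampled moves,
responses).  A cohort is generated in passes that mirror the structure
of the real experiment and its analyses:

1. boards + encoding fixations + gaze-contingent move sampling, giving
   the per-move measures (log move probability, prediction accuracy);
2. measures are z-scored across the whole dataset;
3. a latent schema-use level per trial drives the retrieval fixation
   mixture; the retrieval maps are then *measured* with the same schema
   regression the analyses use, and the resulting index is z-scored;
4. responses (accuracy, clicked move, confidence, RT) are drawn from
   models whose coefficients apply to the z-scored measured predictors,
   exactly the quantities the statistical fits later standardize — so
   planted coefficients are recoverable without attenuation.

Encoding fixations mix the gameplay model's move distribution with a
uniform component; the mixing weight is calibrated by bisection so the
cohort reproduces a target mean fixation-probability correlation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, minimize
from scipy.special import expit

from .board import EMPTY, N_COLS, N_SQUARES, Board, BoardError, Move, self_play_snapshot
from .gaze import BoardGeometry, FixationEvent, FixationMap, fixation_map
from .policy import (
    MoveDistribution,
    PolicyWeights,
    default_weights,
    log_move_probability,
    move_distribution,
)
from .retrieval import schema_regression
from .sampler import Condition, condition_distribution, plan_block_conditions, zscore
from .gaze import prediction_distribution


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class FixationModelCfg:
    lambda_enc: float = 0.5          # schema mixing of predictive fixations
    lambda_subject_sd: float = 0.08  # between-subject spread of the mixing
    lambda_diffuse: float = 0.12     # weight of the diffuse mixture component
    candidate_frac: float = 0.25     # candidate squares per empty square
    center_sel_gain: float = 1.5     # central bias of candidate selection
    center_alloc_gain: float = 2.5   # central bias of time allocation
    occupied_mass: float = 0.30      # share of preview gaze on pieces
    jitter_px: float = 30.0          # gaussian scatter around square centers
    dur_median_ms: float = 250.0     # log-normal fixation durations
    dur_sigma: float = 0.40
    move_share: float = 0.55         # move-display gaze share on the move
    retrieval_window_s: float = 7.5


@dataclass
class ResponseModelCfg:
    target_accuracy: float | None = 0.55  # solves the intercept when set
    b0: float | None = None
    b_prob: float = 0.0
    b_pred: float = 0.0
    b_inter: float = 0.0
    b_w: float = 0.0
    sigma_u: float = 0.5
    guess_q0: float = 0.0   # schema weight of error guesses: expit(q0+q1*w_z)
    guess_q1: float = 1.0


@dataclass
class LinearOutcomeCfg:
    intercept: float = 6.0
    b_prob: float = 0.0
    b_pred: float = 0.0
    b_w: float = 0.0
    sigma_u: float = 0.9
    sigma_e: float = 1.5
    floor: float | None = None


@dataclass
class RetrievalGazeCfg:
    g_pred: float = 0.0    # latent schema use per SD of prediction accuracy
    g_prob: float = 0.0
    sigma_w: float = 1.0
    pi_correct: float = 0.22
    pi_base: float = 0.42  # schema share at w = 0
    pi_slope: float = 0.22
    pi_min: float = 0.02
    pi_max: float = 0.78


@dataclass
class ScenarioConfig:
    name: str = "custom"
    design: str = "exp2"
    n_subjects: int = 95
    n_blocks: int = 10
    trials_per_block: int = 8
    preview_s: float = 8.0
    move_s: float = 5.0
    piece_mean: float = 13.52
    piece_sd: float = 5.97
    piece_min: int = 4
    piece_max: int = 31
    seed: int = 0
    target_corr: float | None = None  # documentation of the calibration target
    geometry: BoardGeometry = field(default_factory=BoardGeometry)
    fixation: FixationModelCfg = field(default_factory=FixationModelCfg)
    response: ResponseModelCfg = field(default_factory=ResponseModelCfg)
    confidence: LinearOutcomeCfg = field(default_factory=LinearOutcomeCfg)
    rt: LinearOutcomeCfg = field(
        default_factory=lambda: LinearOutcomeCfg(
            intercept=7.34, sigma_u=1.2, sigma_e=2.0, floor=0.5
        )
    )
    retrieval: RetrievalGazeCfg = field(default_factory=RetrievalGazeCfg)

    @property
    def n_trials(self) -> int:
        return self.n_subjects * self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key, sub in (
            ("geometry", BoardGeometry),
            ("fixation", FixationModelCfg),
            ("response", ResponseModelCfg),
            ("confidence", LinearOutcomeCfg),
            ("rt", LinearOutcomeCfg),
            ("retrieval", RetrievalGazeCfg),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def available_scenarios() -> list[str]:
    root = resources.files("schemagaze.scenarios")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path) -> ScenarioConfig:
    """Load a packaged scenario by name, or any YAML file by path."""
    path = str(name_or_path)
    if not path.endswith((".yaml", ".yml")):
        ref = resources.files("schemagaze.scenarios") / f"{path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(
                f"unknown scenario {path!r}; available: {available_scenarios()}"
            )
        with resources.as_file(ref) as p:
            return ScenarioConfig.from_dict(yaml.safe_load(p.read_text()))
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Board piece counts: discretized truncated normal, moment-matched


def piece_count_pmf(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Probabilities over lo..hi matching the target mean and SD."""
    ks = np.arange(lo, hi + 1, dtype=float)

    def moments(par):
        mu, ls = par
        p = np.exp(-0.5 * ((ks - mu) / np.exp(ls)) ** 2)
        p = p / p.sum()
        m = p @ ks
        s = np.sqrt(p @ (ks - m) ** 2)
        return p, m, s

    def loss(par):
        _, m, s = moments(par)
        return (m - mean) ** 2 + (s - sd) ** 2

    res = minimize(loss, [mean, np.log(sd)], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    p, _, _ = moments(res.x)
    return p


# ---------------------------------------------------------------------------
# Fixation-event generators


def _draw_fixations(
    target_probs: np.ndarray,
    window_s: float,
    fix_cfg: FixationModelCfg,
    geom: BoardGeometry,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    """Sample fixation events whose targets follow ``target_probs`` (36,)."""
    window_ms = window_s * 1000.0
    durs = np.exp(
        np.log(fix_cfg.dur_median_ms)
        + fix_cfg.dur_sigma * rng.standard_normal(int(window_ms / 100) + 8)
    )
    keep = np.cumsum(durs) <= window_ms
    durs = durs[keep]
    if len(durs) == 0:
        durs = np.array([min(fix_cfg.dur_median_ms, window_ms)])
    onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    squares = rng.choice(N_SQUARES, size=len(durs), p=target_probs)
    centers = geom.centers[squares]
    pos = centers + rng.normal(0.0, fix_cfg.jitter_px, size=centers.shape)
    return [
        FixationEvent(float(o), float(d), float(x), float(y))
        for o, d, (x, y) in zip(onsets, durs, pos)
    ]


def generate_encoding_fixations(
    board: Board,
    model_dist: MoveDistribution,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    lam: float | None = None,
) -> list[FixationEvent]:
    """Preview-window fixations emulating candidate-move prediction.

    Predictive gaze concentrates on a small candidate set (about
    ``candidate_frac`` of the empty squares, at least two): candidates
    are drawn without replacement from a mixture of the model
    distribution (weight ``lam`` — the schema coupling) and a central
    fixation bias, and the viewing time among them is split by an
    exchangeable Dirichlet draw weighted toward central squares.  A
    ``lambda_diffuse`` share of the time instead follows the plain
    mixture lam*model + (1-lam)*uniform over all empty squares
    (``lambda_diffuse=1`` recovers that model exactly), and
    ``occupied_mass`` of the total goes to the pieces.
    """
    from .policy import CENTER_PROXIMITY

    fx = cfg.fixation
    lam = fx.lambda_enc if lam is None else lam
    support = board.flat == EMPTY
    empties = np.flatnonzero(support)
    n = len(empties)

    # candidate-set component
    k = min(max(2, int(round(fx.candidate_frac * n))), n)
    center = np.exp(fx.center_sel_gain * CENTER_PROXIMITY[support])
    sel = lam * model_dist.probs[support] + (1.0 - lam) * center / center.sum()
    cand = rng.choice(empties, size=k, replace=False, p=sel / sel.sum())
    alloc = rng.dirichlet(np.full(k, 2.0)) * np.exp(
        fx.center_alloc_gain * CENTER_PROXIMITY[cand]
    )
    p_cand = np.zeros(N_SQUARES)
    p_cand[cand] = alloc / alloc.sum()

    # diffuse mixture component
    p_diff = lam * model_dist.probs + (1.0 - lam) * support / n

    pred = (1.0 - fx.lambda_diffuse) * p_cand + fx.lambda_diffuse * p_diff
    occupied = ~support
    p = (1.0 - fx.occupied_mass) * pred
    if occupied.any():
        p = p + fx.occupied_mass * occupied / occupied.sum()
    p = p / p.sum()
    return _draw_fixations(p, cfg.preview_s, fx, cfg.geometry, rng)


def generate_move_fixations(
    board: Board,
    shown_square: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    """Move-display fixations: most gaze on the shown move, rest diffuse."""
    fx = cfg.fixation
    p = np.full(N_SQUARES, (1.0 - fx.move_share) / N_SQUARES)
    p[shown_square] += fx.move_share
    return _draw_fixations(p / p.sum(), cfg.move_s, fx, cfg.geometry, rng)


def schema_mixture(
    model_dist: MoveDistribution,
    support: np.ndarray,
    correct_square: int,
    w_lat: float,
    ret: RetrievalGazeCfg,
) -> np.ndarray:
    """Retrieval gaze target distribution for a latent schema level."""
    pi_s = float(np.clip(ret.pi_base + ret.pi_slope * w_lat, ret.pi_min, ret.pi_max))
    pi_c = ret.pi_correct
    pi_u = max(1.0 - pi_s - pi_c, 0.0)
    empty = support / support.sum()
    ind = np.zeros(N_SQUARES)
    ind[correct_square] = 1.0
    p = pi_u * empty + pi_s * model_dist.probs + pi_c * ind
    return p / p.sum()


def generate_retrieval_fixations(
    board: Board,
    model_dist: MoveDistribution,
    correct_square: int,
    w_lat: float,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> list[FixationEvent]:
    p = schema_mixture(
        model_dist, board.flat == EMPTY, correct_square, w_lat, cfg.retrieval
    )
    return _draw_fixations(
        p, cfg.fixation.retrieval_window_s, cfg.fixation, cfg.geometry, rng
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortDataset:
    trials: pd.DataFrame
    fixations: pd.DataFrame
    square_table: pd.DataFrame
    provenance: dict
    boards: dict = field(default_factory=dict)
    model_dists: dict = field(default_factory=dict)


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept making mean Bernoulli probability hit ``target`` exactly."""
    f = lambda b0: float(np.mean(expit(b0 + lp))) - target
    return brentq(f, -8.0, 8.0)


def _board_policy(weights: PolicyWeights):
    def policy(board: Board) -> MoveDistribution:
        return move_distribution(board, weights)

    return policy


def sample_stimulus_board(
    pmf: np.ndarray,
    lo: int,
    policy,
    rng: np.random.Generator,
    max_target_draws: int = 20,
) -> Board:
    """Draw a target piece count, then a win-free self-play snapshot."""
    for _ in range(max_target_draws):
        target = int(lo + rng.choice(len(pmf), p=pmf))
        try:
            return self_play_snapshot(policy, target, rng)
        except BoardError:
            continue
    raise BoardError("could not sample a stimulus board")


def generate_cohort(
    cfg: ScenarioConfig,
    seed: int | None = None,
    weights: PolicyWeights | None = None,
) -> CohortDataset:
    """Simulate a complete experiment for one scenario.

    Returns the trial table (with every derived measure filled in), the
    fixation-event table for all three phases, the square-level table
    used by the manipulation check, and provenance (scenario name,
    config hash, seed).
    """
    seed = cfg.seed if seed is None else seed
    weights = weights or default_weights()
    geom = cfg.geometry
    policy = _board_policy(weights)
    pmf = piece_count_pmf(cfg.piece_mean, cfg.piece_sd, cfg.piece_min, cfg.piece_max)

    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(cfg.n_subjects)
    master = np.random.default_rng(ss.spawn(1)[0])

    fx = cfg.fixation
    rows, fix_rows = [], []
    boards, model_dists = {}, {}
    enc_shares, move_maps, ret_keys = {}, {}, []
    subj_rngs = {}

    for si in range(cfg.n_subjects):
        rng = np.random.default_rng(subj_seeds[si])
        subj_rngs[si] = rng
        lam = float(np.clip(
            fx.lambda_enc + fx.lambda_subject_sd * rng.standard_normal(), 0.0, 0.98
        ))
        for blk in range(cfg.n_blocks):
            conds = plan_block_conditions(cfg.design, rng)
            for tri in range(cfg.trials_per_block):
                cond = conds[tri]
                board = sample_stimulus_board(pmf, cfg.piece_min, policy, rng)
                dist = move_distribution(board, weights)
                support = board.flat == EMPTY
                events = generate_encoding_fixations(board, dist, cfg, rng, lam=lam)
                prev_map = fixation_map(events, geom)
                pred = prediction_distribution(prev_map, board)
                samp = condition_distribution(dist, pred, cond)
                move_sq = samp.sample(rng)
                mv_events = generate_move_fixations(board, move_sq, cfg, rng)
                mv_map = fixation_map(mv_events, geom)

                key = (si, blk, tri)
                boards[key] = board
                model_dists[key] = dist
                enc_shares[key] = pred.probs
                move_maps[key] = mv_map
                rows.append(
                    {
                        "subject": si,
                        "block": blk,
                        "trial": tri,
                        "board": board.to_string(),
                        "condition": cond.label,
                        "move_row": move_sq // N_COLS,
                        "move_col": move_sq % N_COLS,
                        "move_logprob": log_move_probability(dist, move_sq),
                        "pred_acc": pred.prob(move_sq),
                        "n_empty": int(support.sum()),
                        "model_prob_correct": dist.prob(move_sq),
                        "fix_move_ms": float(mv_map.weights[move_sq]),
                        "flags": "|".join(pred.flags + samp.flags),
                    }
                )
                for ph, evs in (("preview", events), ("move", mv_events)):
                    for e in evs:
                        fix_rows.append((si, blk, tri, ph, e.onset_ms,
                                         e.duration_ms, e.x_px, e.y_px))

    trials = pd.DataFrame(rows)
    trials["move_logprob_z"] = zscore(trials["move_logprob"])
    trials["pred_acc_z"] = zscore(trials["pred_acc"])
    z_prob = trials["move_logprob_z"].to_numpy()
    z_pred = trials["pred_acc_z"].to_numpy()

    # Latent schema-use level and retrieval gaze, then the *measured* index.
    ret = cfg.retrieval
    w_lat = np.empty(len(trials))
    wp = np.empty(len(trials))
    wc = np.empty(len(trials))
    wflag = np.zeros(len(trials), dtype=bool)
    for i, row in enumerate(trials.itertuples()):
        key = (row.subject, row.block, row.trial)
        rng = subj_rngs[row.subject]
        w_lat[i] = (
            ret.g_pred * z_pred[i]
            + ret.g_prob * z_prob[i]
            + ret.sigma_w * rng.standard_normal()
        )
        move_sq = int(row.move_row) * N_COLS + int(row.move_col)
        evs = generate_retrieval_fixations(
            boards[key], model_dists[key], move_sq, w_lat[i], cfg, rng
        )
        for e in evs:
            fix_rows.append((row.subject, row.block, row.trial, "retrieval",
                             e.onset_ms, e.duration_ms, e.x_px, e.y_px))
        res = schema_regression(
            fixation_map(evs, geom), boards[key], model_dists[key], move_sq
        )
        wp[i], wc[i], wflag[i] = res.w_move_prob, res.w_correct_move, res.flagged
    trials["w_lat"] = w_lat
    trials["w_moveProb"] = wp
    trials["w_correctMove"] = wc
    trials["w_flag"] = wflag
    # z-score over identifiable (unflagged) trials only; flagged trials get
    # NaN and are excluded from every fit involving the schema index
    for col, vals in (("w_moveProb_z", wp), ("w_correctMove_z", wc)):
        z = np.full(len(trials), np.nan)
        ok = ~wflag & np.isfinite(vals)
        z[ok] = zscore(vals[ok])
        trials[col] = z
    w_z = np.nan_to_num(trials["w_moveProb_z"].to_numpy())  # 0 for flagged

    # Responses: accuracy, clicked square, confidence, RT.
    rcfg = cfg.response
    u = {s: rcfg.sigma_u * subj_rngs[s].standard_normal()
         for s in range(cfg.n_subjects)}
    subj_idx = trials["subject"].to_numpy()
    lp = (
        np.array([u[s] for s in subj_idx])
        + rcfg.b_prob * z_prob
        + rcfg.b_pred * z_pred
        + rcfg.b_inter * z_prob * z_pred
        + rcfg.b_w * w_z
    )
    if rcfg.b0 is not None:
        b0 = rcfg.b0
    elif rcfg.target_accuracy is not None:
        b0 = _solve_intercept(lp, rcfg.target_accuracy)
    else:
        b0 = 0.0
    p_correct = expit(b0 + lp)

    correct = np.empty(len(trials), dtype=int)
    resp_row = np.empty(len(trials), dtype=int)
    resp_col = np.empty(len(trials), dtype=int)
    sel_logp = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples()):
        rng = subj_rngs[row.subject]
        move_sq = int(row.move_row) * N_COLS + int(row.move_col)
        dist = model_dists[(row.subject, row.block, row.trial)]
        correct[i] = int(rng.random() < p_correct[i])
        if correct[i]:
            resp_sq = move_sq
        else:
            gamma = expit(rcfg.guess_q0 + rcfg.guess_q1 * w_z[i])
            support = dist.support.copy()
            support[move_sq] = False
            empty = support / support.sum()
            gp = gamma * np.where(support, dist.probs, 0.0) + (1 - gamma) * empty
            gp = gp / gp.sum()
            resp_sq = int(rng.choice(N_SQUARES, p=gp))
        resp_row[i], resp_col[i] = divmod(resp_sq, N_COLS)
        sel_logp[i] = np.log(dist.probs[resp_sq]) if dist.support[resp_sq] else np.nan

    trials["correct"] = correct
    trials["response_row"] = resp_row
    trials["response_col"] = resp_col
    trials["selected_logprob"] = sel_logp
    trials["selected_logprob_z"] = zscore(sel_logp)
    trials["fix_move_ms_z"] = zscore(trials["fix_move_ms"])

    for label, ocfg in (("confidence", cfg.confidence), ("rt_s", cfg.rt)):
        uo = {s: ocfg.sigma_u * subj_rngs[s].standard_normal()
              for s in range(cfg.n_subjects)}
        vals = (
            ocfg.intercept
            + np.array([uo[s] for s in subj_idx])
            + ocfg.b_prob * z_prob
            + ocfg.b_pred * z_pred
            + ocfg.b_w * w_z
            + ocfg.sigma_e * master.standard_normal(len(trials))
        )
        if ocfg.floor is not None:
            vals = np.maximum(vals, ocfg.floor)
        trials[label] = vals

    fixations = pd.DataFrame(
        fix_rows,
        columns=["subject", "block", "trial", "phase", "onset_ms",
                 "duration_ms", "x_px", "y_px"],
    )

    sq_rows = []
    for row in trials.itertuples():
        key = (row.subject, row.block, row.trial)
        support = boards[key].flat == EMPTY
        idx = np.flatnonzero(support)
        sq_rows.append(pd.DataFrame({
            "subject": row.subject, "block": row.block, "trial": row.trial,
            "square": idx,
            "fix_share": enc_shares[key][idx],
            "model_prob": model_dists[key].probs[idx],
        }))
    square_table = pd.concat(sq_rows, ignore_index=True)

    provenance = {
        "scenario": cfg.name,
        "design": cfg.design,
        "config_hash": cfg.config_hash(),
        "seed": int(seed),
        "intercept_b0": float(b0),
        "n_trials": len(trials),
    }
    return CohortDataset(trials, fixations, square_table, provenance,
                         boards, model_dists)


# ---------------------------------------------------------------------------
# Calibration


def _encoding_corr(
    cfg: ScenarioConfig, lam: float, n_subjects: int, seed: int
) -> float:
    """Mean per-subject fixation-probability correlation at mixing ``lam``."""
    from .stats import manipulation_check

    weights = default_weights()
    geom = cfg.geometry
    policy = _board_policy(weights)
    pmf = piece_count_pmf(cfg.piece_mean, cfg.piece_sd, cfg.piece_min, cfg.piece_max)
    ss = np.random.SeedSequence(seed)
    sq_rows = []
    for si, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        lam_s = float(np.clip(
            lam + cfg.fixation.lambda_subject_sd * rng.standard_normal(), 0.0, 0.98
        ))
        for t in range(cfg.n_blocks * cfg.trials_per_block):
            board = sample_stimulus_board(pmf, cfg.piece_min, policy, rng)
            dist = move_distribution(board, weights)
            events = generate_encoding_fixations(board, dist, cfg, rng, lam=lam_s)
            pred = prediction_distribution(fixation_map(events, geom), board)
            support = board.flat == EMPTY
            idx = np.flatnonzero(support)
            sq_rows.append(pd.DataFrame({
                "subject": si, "block": 0, "trial": t, "square": idx,
                "fix_share": pred.probs[idx], "model_prob": dist.probs[idx],
            }))
    table = pd.concat(sq_rows, ignore_index=True)
    return manipulation_check(table)["mean_r"]


def calibrate_fixation_mixing(
    cfg: ScenarioConfig,
    target_corr: float,
    n_subjects: int = 12,
    seed: int = 20240801,
    tol: float = 0.01,
    max_iter: int = 14,
) -> tuple[float, float]:
    """Bisection on the schema-mixing weight until the manipulation-check
    mean correlation is within ``tol`` of ``target_corr``.

    Returns (lambda, achieved correlation).  Raises if the target is
    outside what the fixation model can produce.
    """
    if not 0.0 < target_corr < 0.9:
        raise ValueError("target correlation must be in (0, 0.9)")
    lo, hi = 0.0, 0.98
    r_hi = _encoding_corr(cfg, hi, n_subjects, seed)
    if r_hi < target_corr - tol:
        raise ValueError(f"target {target_corr} unattainable (max ~{r_hi:.3f})")
    r_lo = _encoding_corr(cfg, lo, n_subjects, seed)
    if r_lo > target_corr + tol:
        raise ValueError(
            f"target {target_corr} below the fixation model's floor "
            f"(~{r_lo:.3f} at zero schema coupling)"
        )
    lam, achieved = hi, r_hi
    for _ in range(max_iter):
        lam = 0.5 * (lo + hi)
        achieved = _encoding_corr(cfg, lam, n_subjects, seed)
        if abs(achieved - target_corr) <= tol:
            break
        if achieved < target_corr:
            lo = lam
        else:
            hi = lam
    return lam, achieved
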