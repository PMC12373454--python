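"""Schema-use index from retrieval-phase eye movements.

When a board is re-presented at retrieval, the fixation map on its empty
squares (normalized to sum to 1) is decomposed by ordinary least squares
into two components: the gameplay model's move-probability map (schema
use — searching likely moves) and an indicator on the correct move
(direct episodic retrieval).  The coefficients are w_moveProb and
w_correctMove.  Because the correct move is included as its own
regressor, fixating the correct square does not inflate w_moveProb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .board import EMPTY, Board
from .gaze import FixationMap
from .policy import MoveDistribution


@dataclass
class SchemaRegressionResult:
    w_move_prob: float
    w_correct_move: float
    intercept: float
    rss: float
    flagged: bool = False


def schema_regression(
    retrieval_map: FixationMap,
    board: Board,
    model_dist: MoveDistribution,
    correct_square: int,
    include_intercept: bool = True,
    cond_threshold: float = 1e8,
    collinearity_threshold: float = 0.9,
) -> SchemaRegressionResult:
    """OLS of the normalized empty-square retrieval map on the two regressors.

    The outcome is the retrieval fixation map restricted to empty squares
    and renormalized to sum to 1; regressors are the model's move
    probabilities over those squares (including the correct one) and the
    correct-move indicator, entered raw, plus an intercept.

    The decomposition is unidentifiable when the model concentrates its
    probability on the correct move itself (the two regressors are then
    nearly the same vector); such trials are flagged — coefficients are
    still returned, but downstream fits exclude them.
    """
    support = board.flat == EMPTY
    n = int(support.sum())
    k = 2 + int(include_intercept)
    if n < k + 1:
        raise ValueError(f"{n} empty squares cannot support {k} regressors")
    w = np.where(support, retrieval_map.weights, 0.0)[support]
    tot = w.sum()
    flagged = False
    if tot <= 0:
        return SchemaRegressionResult(np.nan, np.nan, np.nan, np.nan, flagged=True)
    if board.flat[correct_square] != EMPTY:
        raise ValueError("correct move must be an empty square")
    y = w / tot
    x_prob = model_dist.probs[support]
    x_corr = (np.flatnonzero(support) == correct_square).astype(float)
    cols = [x_prob, x_corr]
    if include_intercept:
        cols.append(np.ones(n))
    X = np.column_stack(cols)
    if np.linalg.cond(X) > cond_threshold:
        flagged = True
    if x_prob.std() > 0 and x_corr.std() > 0:
        r = float(np.corrcoef(x_prob, x_corr)[0, 1])
        if abs(r) > collinearity_threshold:
            flagged = True
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return SchemaRegressionResult(
        float(beta[0]),
        float(beta[1]),
        float(beta[2]) if include_intercept else 0.0,
        float(resid @ resid),
        flagged=flagged,
    )


def batch_schema_index(
    trials: pd.DataFrame,
    retrieval_maps: dict,
    boards: dict,
    model_dists: dict,
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Append w_moveProb / w_correctMove / w_flag columns per trial.

    The dict arguments are keyed by (subject, block, trial).  Trials with
    an empty retrieval map get NaN coefficients and w_flag = True so the
    statistical fits can exclude them.
    """
    wp, wc, fl = [], [], []
    for row in trials.itertuples():
        key = (row.subject, row.block, row.trial)
        board = boards[key]
        sq = int(row.move_row) * 9 + int(row.move_col)
        res = schema_regression(
            retrieval_maps[key], board, model_dists[key], sq,
            include_intercept=include_intercept,
        )
        wp.append(res.w_move_prob)
        wc.append(res.w_correct_move)
        fl.append(res.flagged)
    out = trials.copy()
    out["w_moveProb"] = wp
    out["w_correctMove"] = wc
    out["w_flag"] = fl
    return out
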