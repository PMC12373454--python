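"""Derived per-trial measures from raw trial + fixation tables.

This is the measurement layer shared by the synthetic-cohort generator,
the CLI ``measure`` command and the analyses: it rebuilds boards and
gameplay-model distributions, soft-assigns fixations into per-phase
maps, and derives

* ``move_logprob`` — natural-log model probability of the shown move;
* ``pred_acc`` — empty-square fixation share on the shown move during
  the preview window;
* ``w_moveProb`` / ``w_correctMove`` — the retrieval-gaze schema
  regression coefficients;
* ``selected_logprob`` — log model probability of the clicked response;
* ``fix_move_ms`` — soft-assigned fixation time on the move during the
  5-s move display;

plus z-scored versions standardized across all moves of the dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .board import EMPTY, N_COLS, Board
from .gaze import BoardGeometry, FixationMap, events_from_frame, fixation_map
from .policy import MoveDistribution, PolicyWeights, move_distribution
from .retrieval import schema_regression
from .sampler import zscore


def _maps_by_trial(fixations: pd.DataFrame, geom: BoardGeometry) -> dict:
    out = {}
    for (subj, block, trial, phase), g in fixations.groupby(
        ["subject", "block", "trial", "phase"], sort=False
    ):
        out[(subj, block, trial, phase)] = fixation_map(events_from_frame(g), geom)
    return out


def measure_trials(
    trials: pd.DataFrame,
    fixations: pd.DataFrame,
    geom: BoardGeometry,
    weights: PolicyWeights,
    include_intercept: bool = True,
    zscore_ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append all derived-measure columns; also return the square-level table.

    The square-level table has one row per (trial, empty square) with the
    preview fixation share and the model move probability, and feeds the
    manipulation check.
    """
    geom = geom or BoardGeometry()
    out = trials.copy().reset_index(drop=True)
    maps = _maps_by_trial(fixations, geom)
    zero = FixationMap(np.zeros(36), empty_input=True)

    cols: dict[str, list] = {
        k: []
        for k in (
            "n_empty", "move_logprob", "pred_acc", "model_prob_correct",
            "fix_move_ms", "w_moveProb", "w_correctMove", "w_flag",
            "selected_logprob", "pred_flag",
        )
    }
    sq_rows = []
    for row in out.itertuples():
        key = (row.subject, row.block, row.trial)
        board = Board.from_string(row.board)
        dist = move_distribution(board, weights)
        support = board.flat == EMPTY
        move_sq = int(row.move_row) * N_COLS + int(row.move_col)

        prev_map = maps.get(key + ("preview",), zero)
        w = np.where(support, prev_map.weights, 0.0)
        tot = w.sum()
        if tot > 0:
            shares = w / tot
            cols["pred_flag"].append(False)
        else:
            shares = support / support.sum()
            cols["pred_flag"].append(True)
        cols["n_empty"].append(int(support.sum()))
        cols["move_logprob"].append(float(np.log(dist.probs[move_sq])))
        cols["pred_acc"].append(float(shares[move_sq]))
        cols["model_prob_correct"].append(float(dist.probs[move_sq]))
        mv_map = maps.get(key + ("move",), zero)
        cols["fix_move_ms"].append(float(mv_map.weights[move_sq]))

        ret_map = maps.get(key + ("retrieval",), zero)
        res = schema_regression(
            ret_map, board, dist, move_sq, include_intercept=include_intercept
        )
        cols["w_moveProb"].append(res.w_move_prob)
        cols["w_correctMove"].append(res.w_correct_move)
        cols["w_flag"].append(res.flagged)

        if hasattr(row, "response_row") and row.response_row >= 0:
            resp_sq = int(row.response_row) * N_COLS + int(row.response_col)
            cols["selected_logprob"].append(float(np.log(dist.probs[resp_sq]))
                                            if support[resp_sq] else np.nan)
        else:
            cols["selected_logprob"].append(np.nan)

        idx = np.flatnonzero(support)
        sq_rows.append(
            pd.DataFrame(
                {
                    "subject": row.subject,
                    "block": row.block,
                    "trial": row.trial,
                    "square": idx,
                    "fix_share": shares[idx],
                    "model_prob": dist.probs[idx],
                }
            )
        )

    for k, v in cols.items():
        out[k] = v

    out["move_logprob_z"] = zscore(out["move_logprob"], ddof=zscore_ddof)
    out["pred_acc_z"] = zscore(out["pred_acc"], ddof=zscore_ddof)
    wflag = out["w_flag"].to_numpy(dtype=bool)
    for col in ("w_moveProb", "w_correctMove", "selected_logprob", "fix_move_ms"):
        vals = out[col].to_numpy(dtype=float)
        okmask = np.isfinite(vals)
        if col.startswith("w_"):
            okmask &= ~wflag
        z = np.full(len(vals), np.nan)
        if okmask.sum() >= 2 and np.nanstd(vals[okmask], ddof=zscore_ddof) > 0:
            z[okmask] = zscore(vals[okmask], ddof=zscore_ddof)
        out[col + "_z"] = z

    return out, pd.concat(sq_rows, ignore_index=True)
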