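"""Linear myopic feature-based move policy.

The policy scores each legal move by a handful of one-ply gameplay
features — counts of 4-in-a-row lines through the move that the move
advances (own pieces) or blocks (opponent pieces), plus proximity to the
board center — and turns the scores into a softmax probability
distribution over empty squares.  It is a deliberately myopic stand-in
for full tree-search gameplay models: it evaluates single moves, never
plans ahead.

Weights can be fit by maximum conditional likelihood on recorded
(board, move) pairs; the packaged defaults were fit on self-play of a
hand-tuned teacher policy and shipped as a flat text config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .board import (
    BLACK,
    EMPTY,
    LINE_SQUARES,
    N_COLS,
    N_ROWS,
    N_SQUARES,
    SQUARE_LINE_INCIDENCE,
    Board,
    BoardError,
    Move,
)

FEATURE_NAMES = ("own2", "own3", "own4", "opp2", "opp3", "center")

# Negative Euclidean distance (in square units) from each square to the
# geometric board center (row 1.5, col 4.0).
_rows, _cols = np.divmod(np.arange(N_SQUARES), N_COLS)
CENTER_PROXIMITY = -np.hypot(_rows - (N_ROWS - 1) / 2.0, _cols - (N_COLS - 1) / 2.0)


class PolicyError(ValueError):
    pass


@dataclass
class PolicyWeights:
    """One weight per feature in FEATURE_NAMES order; temperature fixed at 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.shape != (len(FEATURE_NAMES),) or not np.all(
            np.isfinite(self.values)
        ):
            raise PolicyError("weights must be 6 finite values")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, w in zip(FEATURE_NAMES, self.values):
                fh.write(f"{name}\t{float(w)!r}\n")

    @classmethod
    def from_file(cls, path) -> "PolicyWeights":
        vals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, w = line.split("\t")
                vals[name] = float(w)
        return cls(np.array([vals[n] for n in FEATURE_NAMES]))


@dataclass
class MoveDistribution:
    """Probability of the next move for every square of a board.

    ``probs`` is a length-36 row-major vector that is zero on occupied
    squares; ``support`` marks the empty squares; ``n`` is their count.
    ``flags`` records degenerate-case conventions applied upstream
    (e.g. uniform-input inversion, zero-product fallback).
    """

    probs: np.ndarray
    support: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float).reshape(N_SQUARES)
        self.support = np.asarray(self.support, dtype=bool).reshape(N_SQUARES)
        if self.probs.min() < -1e-12:
            raise PolicyError("negative probability")
        if self.probs[~self.support].any():
            raise PolicyError("probability outside support")
        tot = self.probs.sum()
        if abs(tot - 1.0) > 1e-9:
            raise PolicyError(f"probabilities sum to {tot}, not 1")

    @property
    def n(self) -> int:
        return int(self.support.sum())

    def prob(self, square: int) -> float:
        return float(self.probs[square])

    def sample(self, rng: np.random.Generator) -> int:
        cum = np.cumsum(self.probs)
        return int(min(np.searchsorted(cum, rng.random() * cum[-1], side="right"),
                       N_SQUARES - 1))


def _line_counts(board: Board, player: int) -> tuple[np.ndarray, np.ndarray]:
    flat = board.flat
    own = (flat[LINE_SQUARES] == player).sum(axis=1).astype(float)
    opp = ((flat[LINE_SQUARES] != EMPTY) & (flat[LINE_SQUARES] != player)).sum(
        axis=1
    ).astype(float)
    return own, opp


def feature_matrix(board: Board, player: int | None = None) -> np.ndarray:
    """(36, 6) feature matrix for all candidate moves of ``player``.

    Rows of occupied squares are zero and must be masked by the caller.
    Features per empty square s, over the 4-in-a-row lines through s:
      own2/own3/own4 — lines that after the move hold exactly 2/3/4 of the
        mover's pieces and none of the opponent's (own4 = immediate win);
      opp2/opp3 — lines holding exactly 2/3 opponent pieces and no own
        piece, which the move blocks;
      center — negative distance to the board center, in square units.
    """
    if player is None:
        player = board.to_move
    own, opp = _line_counts(board, player)
    M = SQUARE_LINE_INCIDENCE  # (36, n_lines)
    feats = np.zeros((N_SQUARES, len(FEATURE_NAMES)))
    for j, k in enumerate((2, 3, 4)):
        feats[:, j] = M @ ((own == k - 1) & (opp == 0)).astype(float)
    for j, k in enumerate((2, 3), start=3):
        feats[:, j] = M @ ((opp == k) & (own == 0)).astype(float)
    feats[:, 5] = CENTER_PROXIMITY
    feats[board.flat != EMPTY] = 0.0
    return feats


def extract_features(board: Board, move: Move) -> np.ndarray:
    """Feature vector for one legal move."""
    if board.cells[move.row, move.col] != EMPTY:
        raise PolicyError(f"illegal move ({move.row}, {move.col})")
    return feature_matrix(board, move.player)[move.square]


def move_distribution(
    board: Board, weights: PolicyWeights, player: int | None = None
) -> MoveDistribution:
    """Softmax policy: P(m) ∝ exp(wᵀ f(m)) over the empty squares."""
    support = board.flat == EMPTY
    if not support.any():
        raise PolicyError("no legal moves")
    scores = feature_matrix(board, player) @ weights.values
    ex = np.exp(scores - scores[support].max())
    ex[~support] = 0.0
    return MoveDistribution(ex / ex.sum(), support)


def log_move_probability(dist: MoveDistribution, square: int) -> float:
    """Natural log of P(move); the per-move schema-consistency measure."""
    if not dist.support[square]:
        raise PolicyError(f"square {square} not in the distribution support")
    return float(np.log(dist.probs[square]))


def fit_weights(
    game_records: list[tuple[Board, Move]],
    init: PolicyWeights | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PolicyWeights:
    """Maximum conditional likelihood fit of the softmax policy.

    The objective is the conditional logit log-likelihood of the observed
    moves given their boards; it is concave, so a quasi-Newton ascent from
    zero (or ``init``) converges to the global optimum.
    """
    if len(game_records) < 100:
        raise PolicyError("need at least 100 (board, move) records")
    feats, chosen, supports = [], [], []
    for board, move in game_records:
        feats.append(feature_matrix(board, move.player))
        chosen.append(move.square)
        supports.append(board.flat == EMPTY)
    F = np.stack(feats)  # (T, 36, 6)
    S = np.stack(supports)  # (T, 36)
    chosen = np.array(chosen)

    def negll(w):
        scores = F @ w
        scores = np.where(S, scores, -np.inf)
        lse = logsumexp(scores, axis=1)
        ll = scores[np.arange(len(chosen)), chosen] - lse
        if not np.all(np.isfinite(ll)):
            raise PolicyError("non-finite likelihood")
        # gradient: f(chosen) - E_p[f]
        p = np.exp(scores - lse[:, None])
        p = np.where(S, p, 0.0)
        grad = F[np.arange(len(chosen)), chosen] - np.einsum("ts,tsk->tk", p, F)
        return -ll.sum(), -grad.sum(axis=0)

    x0 = np.zeros(len(FEATURE_NAMES)) if init is None else init.values.copy()
    res = minimize(
        negll, x0, jac=True, method="BFGS", options={"gtol": tol, "maxiter": max_iter}
    )
    return PolicyWeights(res.x)


_DEFAULT_WEIGHTS_RESOURCE = "default_weights.txt"


def default_weights() -> PolicyWeights:
    """The packaged gameplay-model weights (fit on teacher self-play)."""
    ref = resources.files("schemagaze.data") / _DEFAULT_WEIGHTS_RESOURCE
    with resources.as_file(ref) as path:
        return PolicyWeights.from_file(path)


def load_game_records(path) -> list[tuple[Board, Move]]:
    """JSON-lines reader: one {"board": str, "row": r, "col": c} per line."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            board = Board.from_string(rec["board"])
            records.append(
                (board, Move(rec["row"], rec["col"], board.to_move))
            )
    return records


def save_game_records(path, records) -> None:
    with open(path, "w") as fh:
        for board, move in records:
            fh.write(
                json.dumps(
                    {"board": board.to_string(), "row": move.row, "col": move.col}
                )
                + "\n"
            )
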