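"""Fit and package the default gameplay-model weights.

A hand-tuned teacher policy (moderate win-seeking, strong blocking)
plays games against itself; every (board, move) decision is recorded,
and the packaged weights are the maximum conditional-likelihood fit of
the linear myopic policy to those decisions.  The fitted weights are
written to ``src/schemagaze/data/default_weights.txt`` (the versioned
config every downstream measure uses) and a parameter-recovery summary
to ``results/policy_training.json``.

Run from the repository root:  python analysis/01_train_policy.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from schemagaze.board import BLACK, WHITE, Board, Move, check_win
from schemagaze.policy import (
    FEATURE_NAMES,
    PolicyWeights,
    fit_weights,
    move_distribution,
)

TEACHER = PolicyWeights([0.4, 1.0, 3.0, 0.6, 3.5, 0.3])
N_GAMES = 250
SEED = 20240801


def self_play_records(weights, n_games, rng):
    records = []
    for _ in range(n_games):
        board = Board()
        for ply in range(36):
            player = BLACK if ply % 2 == 0 else WHITE
            dist = move_distribution(board, weights)
            sq = dist.sample(rng)
            records.append((board, Move(sq // 9, sq % 9, player)))
            board = board.apply(Move(sq // 9, sq % 9, player))
            if check_win(board, player):
                break
    return records


def main():
    rng = np.random.default_rng(SEED)
    records = self_play_records(TEACHER, N_GAMES, rng)
    print(f"collected {len(records)} teacher decisions from {N_GAMES} games")
    fitted = fit_weights(records)
    out = Path(__file__).resolve().parents[1] / "src/schemagaze/data/default_weights.txt"
    fitted.to_file(out)
    print(f"wrote {out}")
    summary = {
        "n_records": len(records),
        "teacher": dict(zip(FEATURE_NAMES, TEACHER.values.tolist())),
        "fitted": dict(zip(FEATURE_NAMES, fitted.values.tolist())),
        "max_abs_error": float(np.abs(fitted.values - TEACHER.values).max()),
    }
    res = Path(__file__).resolve().parents[1] / "results/policy_training.json"
    res.parent.mkdir(exist_ok=True)
    res.write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
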