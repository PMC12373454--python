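"""Board representation and rules for 4-in-a-row on a 4 x 9 grid.

The game is a tic-tac-toe extension: two players alternately place a piece
on any empty square of a 4-row by 9-column board, and the first player to
connect four of their pieces in a row (horizontally, vertically, or
diagonally) wins.  There is no gravity/drop rule.

Coordinates are 0-based and row-major with row 0 at the top.  Boards
serialize to a 36-character row-major string of ``.`` (empty), ``b``
(black) and ``w`` (white).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

N_ROWS = 4
N_COLS = 9
N_SQUARES = N_ROWS * N_COLS

EMPTY, BLACK, WHITE = 0, 1, 2
_CHARS = {EMPTY: ".", BLACK: "b", WHITE: "w"}
_VALS = {v: k for k, v in _CHARS.items()}


class BoardError(ValueError):
    """Raised for invalid boards, moves, or unreachable snapshots."""


@dataclass(frozen=True)
class Move:
    """A piece placement at (row, col) by ``player`` (BLACK or WHITE)."""

    row: int
    col: int
    player: int

    @property
    def square(self) -> int:
        return self.row * N_COLS + self.col


@dataclass
class Board:
    """4x9 grid of {EMPTY, BLACK, WHITE} plus the player to move.

    Black moves first; by convention ``to_move`` is derived from the piece
    counts unless set explicitly.
    """

    cells: np.ndarray = field(
        default_factory=lambda: np.zeros((N_ROWS, N_COLS), dtype=np.int8)
    )

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8).reshape(N_ROWS, N_COLS)

    @property
    def n_pieces(self) -> int:
        return int((self.cells != EMPTY).sum())

    @property
    def to_move(self) -> int:
        n_black = int((self.cells == BLACK).sum())
        n_white = int((self.cells == WHITE).sum())
        return BLACK if n_black == n_white else WHITE

    @property
    def flat(self) -> np.ndarray:
        return self.cells.reshape(-1)

    def copy(self) -> "Board":
        return Board(self.cells.copy())

    def apply(self, move: Move) -> "Board":
        if self.cells[move.row, move.col] != EMPTY:
            raise BoardError(f"square ({move.row}, {move.col}) is occupied")
        out = self.copy()
        out.cells[move.row, move.col] = move.player
        return out

    def to_string(self) -> str:
        return "".join(_CHARS[int(v)] for v in self.flat)

    @classmethod
    def from_string(cls, s: str) -> "Board":
        s = s.strip()
        if len(s) != N_SQUARES or any(c not in _VALS for c in s):
            raise BoardError(f"bad board string: {s!r}")
        return cls(np.array([_VALS[c] for c in s], dtype=np.int8))

    def validate(self, stimulus: bool = False) -> None:
        """Check board invariants; ``stimulus`` adds the encoding-board rules
        (4-31 pieces, no completed line)."""
        n_black = int((self.cells == BLACK).sum())
        n_white = int((self.cells == WHITE).sum())
        if abs(n_black - n_white) > 1:
            raise BoardError("piece counts differ by more than 1")
        if stimulus:
            if not 4 <= self.n_pieces <= 31:
                raise BoardError("stimulus boards must hold 4-31 pieces")
            if check_win(self, BLACK) or check_win(self, WHITE):
                raise BoardError("stimulus boards must not contain a win")


def legal_moves(board: Board) -> list[tuple[int, int]]:
    """All empty squares as (row, col) pairs in row-major order."""
    rows, cols = np.nonzero(board.cells == EMPTY)
    return list(zip(rows.tolist(), cols.tolist()))


def _enumerate_lines() -> list[tuple[tuple[int, int], ...]]:
    lines = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        for r in range(N_ROWS):
            for c in range(N_COLS):
                cells = tuple((r + i * dr, c + i * dc) for i in range(4))
                if all(0 <= rr < N_ROWS and 0 <= cc < N_COLS for rr, cc in cells):
                    lines.append(cells)
    return lines


_LINES: list[tuple[tuple[int, int], ...]] = _enumerate_lines()

# (n_lines, 4) flat square indices and a (36, n_lines) incidence matrix,
# used heavily by the policy's feature extraction.
LINE_SQUARES: np.ndarray = np.array(
    [[r * N_COLS + c for r, c in line] for line in _LINES], dtype=np.intp
)
SQUARE_LINE_INCIDENCE: np.ndarray = np.zeros((N_SQUARES, len(_LINES)), dtype=np.float64)
for _j, _line in enumerate(_LINES):
    for _r, _c in _line:
        SQUARE_LINE_INCIDENCE[_r * N_COLS + _c, _j] = 1.0


def winning_lines() -> list[tuple[tuple[int, int], ...]]:
    """Every length-4 contiguous line on the grid, each exactly once."""
    return list(_LINES)


def check_win(board: Board, player: int) -> bool:
    """True iff some length-4 line is entirely ``player``'s color."""
    flat = board.flat
    return bool(np.any(np.all(flat[LINE_SQUARES] == player, axis=1)))


def self_play_snapshot(
    policy,
    target_pieces: int,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> Board:
    """A mid-game board reached by alternating sampled policy moves.

    ``policy`` is a callable Board -> MoveDistribution (anything with a
    ``sample(rng)`` method returning a square index).  Play starts from the
    empty board and stops once ``target_pieces`` pieces are down; attempts
    where a player completes a line earlier are retried with fresh draws.
    """
    if not 4 <= target_pieces <= 31:
        raise BoardError("target_pieces must be in [4, 31]")
    for _ in range(max_retries):
        board = Board()
        won = False
        for ply in range(target_pieces):
            player = BLACK if ply % 2 == 0 else WHITE
            dist = policy(board)
            sq = dist.sample(rng)
            board = board.apply(Move(sq // N_COLS, sq % N_COLS, player))
            if check_win(board, player):
                won = True
                break
        if not won:
            return board
    raise BoardError(
        f"could not reach {target_pieces} pieces without a win in "
        f"{max_retries} attempts"
    )


def iter_jsonl(path) -> Iterator[Board]:
    """Read boards from a JSON-lines fixture file of board strings."""
    import json

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Board.from_string(json.loads(line)["board"])
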