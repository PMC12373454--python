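"""Fixation smoothing: soft assignment of gaze to board squares.

A fixation at pixel position x_F with duration t_F contributes to every
square i a weight

    t_F * exp(-||x_F - x_i||^2 / scale) / sum_j exp(-||x_F - x_j||^2 / scale)

with distances in pixels and scale = 25 by default, so each fixation's
total contribution is exactly its duration.  With 180-px squares the
smoothing only matters near square boundaries; elsewhere it reduces to
hard nearest-square assignment.  Summing over all fixations in a trial
phase yields a per-square fixation-time map, from which the prediction
distribution (empty-square shares) and prediction accuracy (share on the
shown move) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .board import EMPTY, N_COLS, N_ROWS, N_SQUARES, Board
from .policy import MoveDistribution

PHASES = ("preview", "move", "retrieval")


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: onset (ms from phase start), duration (ms), gaze x/y (px)."""

    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError("fixation duration must be positive")
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValueError("fixation position must be finite")


@dataclass
class BoardGeometry:
    """Pixel layout of the board on screen.

    The default centers a 9x4-square board of 180-px squares on a
    1920x1080 display, putting the top-left square corner at (150, 180).
    """

    screen_w: int = 1920
    screen_h: int = 1080
    square_px: float = 180.0
    origin_x: float = 150.0
    origin_y: float = 180.0
    smoothing_scale: float = 25.0  # divisor of squared pixel distance

    @property
    def centers(self) -> np.ndarray:
        """(36, 2) pixel coordinates of square centers, row-major."""
        rows, cols = np.divmod(np.arange(N_SQUARES), N_COLS)
        cx = self.origin_x + (cols + 0.5) * self.square_px
        cy = self.origin_y + (rows + 0.5) * self.square_px
        return np.column_stack([cx, cy])

    def square_center(self, square: int) -> tuple[float, float]:
        cx, cy = self.centers[square]
        return float(cx), float(cy)


@dataclass
class FixationMap:
    """Per-square soft-assigned fixation time (ms)."""

    weights: np.ndarray
    empty_input: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(N_SQUARES)

    @property
    def total_ms(self) -> float:
        return float(self.weights.sum())


def assign_fixation(fix: FixationEvent, geom: BoardGeometry) -> np.ndarray:
    """Soft-assign one fixation's duration over the 36 squares."""
    d2 = np.sum((geom.centers - [fix.x_px, fix.y_px]) ** 2, axis=1)
    return fix.duration_ms * softmax(-d2 / geom.smoothing_scale)


def fixation_map(
    fixations: list[FixationEvent], geom: BoardGeometry
) -> FixationMap:
    """Sum of soft assignments over a trial phase's fixations."""
    if not fixations:
        return FixationMap(np.zeros(N_SQUARES), empty_input=True)
    pos = np.array([[f.x_px, f.y_px] for f in fixations])
    dur = np.array([f.duration_ms for f in fixations])
    d2 = ((pos[:, None, :] - geom.centers[None, :, :]) ** 2).sum(axis=2)
    w = softmax(-d2 / geom.smoothing_scale, axis=1) * dur[:, None]
    return FixationMap(w.sum(axis=0))


def prediction_distribution(fmap: FixationMap, board: Board) -> MoveDistribution:
    """Empty-square fixation shares, normalized to sum to one.

    If no fixation mass fell on empty squares the participant made no
    usable prediction; the uniform distribution is returned with a
    ``no-prediction`` flag so downstream sampling never stalls.
    """
    support = board.flat == EMPTY
    w = np.where(support, fmap.weights, 0.0)
    tot = w.sum()
    if tot <= 0:
        probs = support / support.sum()
        return MoveDistribution(probs, support, flags=("no-prediction",))
    return MoveDistribution(w / tot, support)


def prediction_accuracy(fmap: FixationMap, board: Board, shown_square: int) -> float:
    """Duration-weighted share of empty-square fixations on the shown move."""
    if board.flat[shown_square] != EMPTY:
        raise ValueError("shown move must be an empty square")
    return prediction_distribution(fmap, board).prob(shown_square)


# ---------------------------------------------------------------------------
# Fixation table I/O

FIXATION_COLUMNS = [
    "subject",
    "block",
    "trial",
    "phase",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
]


def read_fixation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        raise ValueError(f"unknown phases: {sorted(df.loc[bad, 'phase'].unique())}")
    return df


def write_fixation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FIXATION_COLUMNS)


def events_from_frame(df: pd.DataFrame) -> list[FixationEvent]:
    return [
        FixationEvent(r.onset_ms, r.duration_ms, r.x_px, r.y_px)
        for r in df.itertuples()
    ]


def read_asc_fixations(path, eye: str = "R") -> list[FixationEvent]:
    """Minimal EyeLink ASC reader: EFIX lines only.

    EFIX <eye> <start> <end> <duration> <x> <y> <pupil>; onsets are re-based
    to the first event.  Blinks, saccades and messages are ignored.
    """
    events = []
    t0 = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 7 and parts[0] == "EFIX" and parts[1] == eye:
                start, _end, dur, x, y = (float(p) for p in parts[2:7])
                if t0 is None:
                    t0 = start
                events.append(FixationEvent(start - t0, dur, x, y))
    return events
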