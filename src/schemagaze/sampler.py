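"""Gaze-contingent adaptive move generation.

At the end of each preview window two distributions over the empty
squares are available: the gameplay model's move-probability
distribution and the participant's prediction distribution (normalized
empty-square fixation shares).  Either can be *inverted*,

    P(m)  ->  (max_i P(i) - P(m)) / sum_i (max_i P(i) - P(i)),

which makes the most probable/predicted squares the least likely while
leaving the remaining squares roughly equally likely.  The condition's
two (possibly inverted) distributions are then multiplied and
renormalized, and the shown move is sampled from the product.  Exp. 1
uses all four probable x predicted cells (2 moves each per 8-trial
block); Exp. 2 keeps only the two probable conditions (4 + 4).

The per-move measures are the natural-log model probability of the shown
move and the prediction accuracy (empty-square fixation share on it),
z-scored across all moves of an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .policy import MoveDistribution


@dataclass(frozen=True)
class Condition:
    probable: bool
    predicted: bool

    @property
    def label(self) -> str:
        return ("probable" if self.probable else "improbable") + "_" + (
            "predicted" if self.predicted else "unpredicted"
        )

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        prob, pred = label.split("_")
        return cls(prob == "probable", pred == "predicted")


EXP1_CONDITIONS = tuple(
    Condition(p, q) for p in (True, False) for q in (True, False)
)
EXP2_CONDITIONS = (Condition(True, True), Condition(True, False))


def invert_distribution(dist: MoveDistribution) -> MoveDistribution:
    """(max P - P) / sum(max P - P) over the support.

    An exactly-uniform input makes the formula 0/0; by convention the
    uniform distribution is returned unchanged, flagged ``uniform-inversion``.
    """
    s = dist.support
    p = dist.probs
    inv = np.where(s, p[s].max() - p, 0.0)
    tot = inv.sum()
    if tot <= 0:
        probs = s / s.sum()
        return MoveDistribution(probs, s, flags=dist.flags + ("uniform-inversion",))
    return MoveDistribution(inv / tot, s, flags=dist.flags)


def combine_distributions(
    p_probability: MoveDistribution, p_prediction: MoveDistribution
) -> MoveDistribution:
    """Normalized elementwise product of the two distributions.

    If the supports are disjoint in mass the product is identically zero;
    the sampler then falls back to the move-probability distribution so a
    move can always be shown (flagged ``zero-product``).
    """
    if not np.array_equal(p_probability.support, p_prediction.support):
        raise ValueError("distributions have mismatched supports")
    flags = tuple(dict.fromkeys(p_probability.flags + p_prediction.flags))
    prod = p_probability.probs * p_prediction.probs
    tot = prod.sum()
    if tot <= 0:
        return MoveDistribution(
            p_probability.probs, p_probability.support, flags=flags + ("zero-product",)
        )
    return MoveDistribution(prod / tot, p_probability.support, flags=flags)


def condition_distribution(
    model_dist: MoveDistribution, pred_dist: MoveDistribution, cond: Condition
) -> MoveDistribution:
    """The sampling distribution for one of the four experimental cells."""
    p = model_dist if cond.probable else invert_distribution(model_dist)
    q = pred_dist if cond.predicted else invert_distribution(pred_dist)
    return combine_distributions(p, q)


def sample_move(dist: MoveDistribution, rng: np.random.Generator) -> int:
    """Draw the shown move (square index) from the condition distribution."""
    return dist.sample(rng)


def plan_block_conditions(design: str, rng: np.random.Generator) -> list[Condition]:
    """Condition sequence for one 8-trial block, randomly permuted.

    exp1: two moves from each of the four cells; exp2: four each from the
    two probable cells.
    """
    if design == "exp1":
        conds = [c for c in EXP1_CONDITIONS for _ in range(2)]
    elif design == "exp2":
        conds = [c for c in EXP2_CONDITIONS for _ in range(4)]
    else:
        raise ValueError(f"unknown design {design!r}")
    order = rng.permutation(len(conds))
    return [conds[i] for i in order]


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def zscore_measures(
    trials: pd.DataFrame,
    columns: tuple[str, ...] = ("move_logprob", "pred_acc"),
    ddof: int = 1,
) -> pd.DataFrame:
    """Append z-scored measure columns, standardized across all moves.

    Standardization is within an experiment dataset, pooling participants
    and trials; the sample-SD convention (ddof=1) is the default.
    """
    out = trials.copy()
    for col in columns:
        out[col + "_z"] = zscore(out[col].to_numpy(), ddof=ddof)
    return out


TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "board",
    "condition",
    "move_row",
    "move_col",
    "move_logprob",
    "pred_acc",
    "response_row",
    "response_col",
    "correct",
    "confidence",
    "rt_s",
    "flags",
]


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["flags"] = df["flags"].fillna("")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
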