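"""Iowa Gambling Task environment: payoff schedules and trial-level data.

The IGT presents four decks of cards. Decks A and B pay a constant win of
100 per draw but are disadvantageous (net -250 per 10 draws); decks C and D
pay 50 per draw and are advantageous (net +250 per 10 draws). Decks A and C
deliver frequent small losses (5 per 10-draw block), decks B and D a single
large loss per block. Trial-level data are stored long-format with columns
``participant, trial, choice, win, loss``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Initial credit shown to participants in the computerized task. Recorded
#: for completeness; it plays no role in the model equations.
INITIAL_CREDIT = 2000

DECK_NAMES = ("A", "B", "C", "D")

# Fixed per-block loss layout of the traditional scheme (Bechara et al. 1994
# dialect). Keys are deck indices 1..4; values map within-block draw position
# (1..10) to the loss incurred at that position. Any conforming variant must
# satisfy the block-sum invariants enforced by build_traditional_schedule.
_BLOCK_LOSSES = {
    1: {3: -150, 5: -300, 7: -200, 9: -250, 10: -350},  # A: 5 losses, -1250
    2: {9: -1250},                                      # B: 1 loss,  -1250
    3: {3: -50, 5: -50, 7: -50, 9: -50, 10: -50},       # C: 5 losses, -250
    4: {10: -250},                                      # D: 1 loss,   -250
}
_BLOCK_WINS = {1: 100, 2: 100, 3: 50, 4: 50}


class ScheduleError(ValueError):
    """Invalid payoff-schedule construction or access."""


@dataclass(frozen=True)
class PayoffSchedule:
    """Deterministic win/loss sequences per deck, indexed by draw position.

    Attributes
    ----------
    wins, losses : dict
        Map deck index (1..4) to an integer array of length ``max_draws``;
        wins are >= 0, losses <= 0.
    max_draws : int
        Number of scheduled draws per deck.
    """

    wins: dict = field(repr=False)
    losses: dict = field(repr=False)
    max_draws: int = 0

    def deal(self, deck: int, position: int) -> tuple[int, int]:
        """Return the scheduled ``(win, loss)`` for a deck's position-th draw."""
        if deck not in (1, 2, 3, 4):
            raise ScheduleError(f"deck must be in 1..4, got {deck}")
        if not 1 <= position <= self.max_draws:
            raise ScheduleError(
                f"position {position} out of range 1..{self.max_draws}"
            )
        return int(self.wins[deck][position - 1]), int(self.losses[deck][position - 1])


def build_traditional_schedule(max_draws: int = 200) -> PayoffSchedule:
    """Build the traditional fixed IGT payoff schedule.

    The schedule is defined in 10-draw blocks which repeat cyclically, so any
    multiple of 10 draws can be dealt from a single deck. Wins are 100 for
    decks A/B and 50 for C/D at every position; each block nets -250 for A/B
    and +250 for C/D.

    Parameters
    ----------
    max_draws : int
        Draws per deck; must be a positive multiple of 10.
    """
    if max_draws < 10 or max_draws % 10 != 0:
        raise ScheduleError(
            f"max_draws must be a positive multiple of 10, got {max_draws}"
        )
    n_blocks = max_draws // 10
    wins, losses = {}, {}
    for deck in (1, 2, 3, 4):
        block_loss = np.zeros(10, dtype=int)
        for pos, loss in _BLOCK_LOSSES[deck].items():
            block_loss[pos - 1] = loss
        wins[deck] = np.full(max_draws, _BLOCK_WINS[deck], dtype=int)
        losses[deck] = np.tile(block_loss, n_blocks)
    return PayoffSchedule(wins=wins, losses=losses, max_draws=max_draws)


def deal(schedule: PayoffSchedule, deck: int, position: int) -> tuple[int, int]:
    """Functional alias for :meth:`PayoffSchedule.deal`."""
    return schedule.deal(deck, position)


class TrialValidationError(ValueError):
    """Trial-level data violates the dataset contract."""


REQUIRED_COLUMNS = ["participant", "trial", "choice", "win", "loss"]


@dataclass
class IGTDataset:
    """Long-format trial records for N participants x T trials.

    ``trials`` has columns participant, trial (1-based, contiguous per
    participant), choice (deck index 1..4), win (>= 0), loss (<= 0).
    """

    trials: pd.DataFrame

    def __post_init__(self):
        self.trials = validate_trials(self.trials)

    @property
    def participants(self) -> np.ndarray:
        return self.trials["participant"].unique()

    @property
    def n_participants(self) -> int:
        return int(self.trials["participant"].nunique())

    @property
    def n_trials(self) -> int:
        return int(self.trials.groupby("participant")["trial"].size().iloc[0])

    def net_outcomes(self) -> pd.Series:
        """Net outcome X = W + L per trial."""
        return self.trials["win"] + self.trials["loss"]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (choices, nets) as (N, T) integer/float arrays.

        Rows follow the order of first appearance of each participant.
        Choices are 0-based deck indices.
        """
        df = self.trials.sort_values(["participant", "trial"], kind="stable")
        order = self.trials["participant"].drop_duplicates().tolist()
        n, t = len(order), self.n_trials
        idx = {p: i for i, p in enumerate(order)}
        rows = df["participant"].map(idx).to_numpy()
        cols = df["trial"].to_numpy() - 1
        choices = np.zeros((n, t), dtype=np.int64)
        nets = np.zeros((n, t))
        choices[rows, cols] = df["choice"].to_numpy() - 1
        nets[rows, cols] = (df["win"] + df["loss"]).to_numpy()
        return choices, nets


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table, naming offending rows on error."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise TrialValidationError("empty dataset: no trial rows")
    df = df[REQUIRED_COLUMNS].copy()
    bad_choice = ~df["choice"].isin([1, 2, 3, 4])
    if bad_choice.any():
        row = df.index[bad_choice][0]
        raise TrialValidationError(
            f"invalid deck index {df.loc[row, 'choice']} at row {row}"
        )
    if (df["win"] < 0).any():
        row = df.index[df["win"] < 0][0]
        raise TrialValidationError(f"negative win at row {row}")
    if (df["loss"] > 0).any():
        row = df.index[df["loss"] > 0][0]
        raise TrialValidationError(f"positive loss at row {row}")
    counts = df.groupby("participant")["trial"].agg(["size", "min", "max"])
    if counts["size"].nunique() != 1:
        raise TrialValidationError(
            "participants differ in trial counts: "
            f"{dict(counts['size'].items())}"
        )
    bad = counts[(counts["min"] != 1) | (counts["max"] != counts["size"])]
    if len(bad):
        raise TrialValidationError(
            f"non-contiguous trial numbering for participant {bad.index[0]}"
        )
    for pid, grp in df.groupby("participant"):
        if grp["trial"].duplicated().any():
            raise TrialValidationError(
                f"duplicated trial index for participant {pid}"
            )
    return df.reset_index(drop=True)


def read_trials(path) -> IGTDataset:
    """Read a trial CSV (columns participant,trial,choice,win,loss)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrialValidationError(f"empty trial file: {path}") from exc
    return IGTDataset(df)


def write_trials(dataset: IGTDataset, path) -> None:
    """Write a dataset to CSV; ``read_trials(write_trials(d)) == d``."""
    dataset.trials.to_csv(path, index=False)
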