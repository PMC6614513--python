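"""Factor levels and condition-cell bookkeeping for the 2x2x2 task.

The session crosses three within-subject factors: the Beneficiary of the
trial's payoff (self vs. a close other), the Payoff magnitude (high vs.
low), and the perceptual Difficulty (easy vs. difficult motion coherence).
A *cell* is one combination, identified by the tuple
``(beneficiary, payoff, difficulty)``.
"""

from __future__ import annotations

import itertools

import pandas as pd

BENEFICIARY = ("self", "other")
PAYOFF = ("high", "low")
DIFFICULTY = ("easy", "difficult")
DIRECTIONS = ("left", "right")

FACTORS = {
    "beneficiary": BENEFICIARY,
    "payoff": PAYOFF,
    "difficulty": DIFFICULTY,
}

#: Canonical cell order: self/other x high/low x easy/difficult.
CELLS: tuple[tuple[str, str, str], ...] = tuple(
    itertools.product(BENEFICIARY, PAYOFF, DIFFICULTY)
)

CELL_COLUMNS = ("beneficiary", "payoff", "difficulty")


def cell_index(frame: pd.DataFrame) -> pd.Series:
    """Zero-based canonical cell index for each row of a trial table."""
    lookup = {cell: i for i, cell in enumerate(CELLS)}
    keys = list(zip(frame["beneficiary"], frame["payoff"], frame["difficulty"]))
    return pd.Series([lookup[k] for k in keys], index=frame.index)


def cell_label(cell: tuple[str, str, str]) -> str:
    return "/".join(cell)
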