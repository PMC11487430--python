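"""The 6x6 character matrix of a row/column P300 speller.

Stimulus codes follow the BCI2000 convention: codes 1-6 flash the six rows
(top to bottom), codes 7-12 flash the six columns (left to right).  Each
character therefore lies at the intersection of exactly one row code and one
column code, and each code intensifies exactly six cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
N_ROWS = 6
N_COLS = 6
ROW_CODES = tuple(range(1, 7))
COL_CODES = tuple(range(7, 13))
ALL_CODES = ROW_CODES + COL_CODES

#: Classic speller layout: the alphabet followed by digits and an underscore.
DEFAULT_GRID = (
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
)


class SpellerError(ValueError):
    """Raised for invalid speller layouts or characters not in the matrix."""


@dataclass(frozen=True)
class SpellerMatrix:
    """A 6x6 grid of characters addressed by row/column stimulus codes."""

    grid: tuple[str, ...] = field(default=DEFAULT_GRID)

    def __post_init__(self) -> None:
        rows = tuple(str(r) for r in self.grid)
        if len(rows) != N_ROWS or any(len(r) != N_COLS for r in rows):
            raise SpellerError("speller grid must be 6 rows of 6 characters")
        chars = "".join(rows)
        if len(set(chars)) != N_ROWS * N_COLS:
            raise SpellerError("speller grid must contain 36 distinct characters")
        object.__setattr__(self, "grid", rows)

    def cell(self, row_code: int, col_code: int) -> str:
        """Character at the intersection of a row code (1-6) and column code (7-12)."""
        if row_code not in ROW_CODES:
            raise SpellerError(f"row code must be 1-6, got {row_code}")
        if col_code not in COL_CODES:
            raise SpellerError(f"column code must be 7-12, got {col_code}")
        return self.grid[row_code - 1][col_code - 7]

    def char_to_codes(self, char: str) -> tuple[int, int]:
        """The (row_code, col_code) pair whose flashes are targets for ``char``."""
        for i, row in enumerate(self.grid):
            j = row.find(char)
            if j >= 0:
                return i + 1, j + 7
        raise SpellerError(f"character {char!r} is not in the speller matrix")

    def target_codes(self, text: str) -> list[tuple[int, int]]:
        """Per spelled character, the two stimulus codes that are targets."""
        return [self.char_to_codes(c) for c in text]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"grid": list(self.grid)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpellerMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(grid=tuple(payload["grid"]))


def is_target_code(code: int, char: str, matrix: SpellerMatrix) -> bool:
    """Whether flashing ``code`` intensifies the cell containing ``char``."""
    row, col = matrix.char_to_codes(char)
    return code in (row, col)
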