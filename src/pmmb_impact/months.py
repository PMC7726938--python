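"""Whole calendar months ("YYYY-MM"): the model's unit of time.

The projection is a step function over calendar months with no pro-rating,
so a minimal integer-indexed month value is all that is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering


@total_ordering
@dataclass(frozen=True)
class Month:
    year: int
    month: int

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")

    @classmethod
    def parse(cls, text: str | "Month") -> "Month":
        if isinstance(text, Month):
            return text
        y, _, m = str(text).strip().partition("-")
        return cls(int(y), int(m))

    @property
    def index(self) -> int:
        """Months since year 0 (ordinal for arithmetic and comparison)."""
        return self.year * 12 + self.month - 1

    @classmethod
    def from_index(cls, idx: int) -> "Month":
        return cls(idx // 12, idx % 12 + 1)

    def __add__(self, n: int) -> "Month":
        return Month.from_index(self.index + n)

    def __lt__(self, other: "Month") -> bool:
        return self.index < other.index

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of months from ``start`` to ``end``."""
    if end < start:
        raise ValueError(f"month range end {end} precedes start {start}")
    return [Month.from_index(i) for i in range(start.index, end.index + 1)]
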