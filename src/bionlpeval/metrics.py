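"""Score rows, F-score arithmetic and report formatting."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ScoreRow",
    "ScoreReport",
    "compute_fscore",
    "round_half_away",
]


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compute_fscore(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (percentages); 0 when both are 0."""
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


@dataclass
class ScoreRow:
    """Counts and derived recall/precision/F for one category.

    recall = 100 * recall_matched / gold_count (0 when gold_count = 0);
    precision analogous over answer_count.  A row with 0 answers reports
    precision 0 (display convention).
    """

    category: str
    gold_count: int = 0
    answer_count: int = 0
    recall_matched: int = 0
    precision_matched: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.recall_matched <= max(self.gold_count, 0)):
            raise ValueError(f"{self.category}: recall_matched out of range")
        if not (0 <= self.precision_matched <= max(self.answer_count, 0)):
            raise ValueError(f"{self.category}: precision_matched out of range")

    @property
    def recall(self) -> float:
        return 100.0 * self.recall_matched / self.gold_count if self.gold_count else 0.0

    @property
    def precision(self) -> float:
        return (
            100.0 * self.precision_matched / self.answer_count
            if self.answer_count
            else 0.0
        )

    @property
    def fscore(self) -> float:
        return compute_fscore(self.recall, self.precision)

    def add(self, other: "ScoreRow") -> None:
        self.gold_count += other.gold_count
        self.answer_count += other.answer_count
        self.recall_matched += other.recall_matched
        self.precision_matched += other.precision_matched

    def triple(self, decimals: int = 2) -> str:
        """Format as ``RR.RR/PP.PP/FF.FF``."""
        return "/".join(
            f"{round_half_away(v, decimals):.{decimals}f}"
            for v in (self.recall, self.precision, self.fscore)
        )

    def as_dict(self, decimals: int = 2) -> dict:
        return {
            "category": self.category,
            "gold": self.gold_count,
            "answer": self.answer_count,
            "recall_matched": self.recall_matched,
            "precision_matched": self.precision_matched,
            "recall": round_half_away(self.recall, decimals),
            "precision": round_half_away(self.precision, decimals),
            "fscore": round_half_away(self.fscore, decimals),
        }


@dataclass
class ScoreReport:
    """An ordered set of score rows plus a mode descriptor."""

    mode: str
    rows: dict[str, ScoreRow] = field(default_factory=dict)
    decimals: int = 2

    def row(self, category: str) -> ScoreRow:
        if category not in self.rows:
            self.rows[category] = ScoreRow(category)
        return self.rows[category]

    def __getitem__(self, category: str) -> ScoreRow:
        return self.rows[category]

    def to_tsv(self) -> str:
        lines = [f"# mode: {self.mode}"]
        lines.append(
            "category\tgold\tanswer\trecall_matched\tprecision_matched\tR/P/F"
        )
        for row in self.rows.values():
            lines.append(
                f"{row.category}\t{row.gold_count}\t{row.answer_count}\t"
                f"{row.recall_matched}\t{row.precision_matched}\t"
                f"{row.triple(self.decimals)}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "rows": [row.as_dict(self.decimals) for row in self.rows.values()],
        }
        return json.dumps(payload, indent=2) + "\n"
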