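"""Questionnaire codebook: item identifiers, labels, polarity and response scales.

The default codebook describes a hospitalization PREM questionnaire: 19
experience items rated on a 1–5 frequency scale (never … always) plus one
overall-satisfaction item on a 1–5 quality scale (very poor … excellent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import ValidationError
from .reference import EXPERIENCE_ITEMS

SATISFACTION_ITEM = "satisfaction"

FREQUENCY_SCALE = {1: "never", 2: "rarely", 3: "sometimes", 4: "often", 5: "always"}
QUALITY_SCALE = {1: "very poor", 2: "poor", 3: "sufficient", 4: "good", 5: "excellent"}

_EXPERIENCE_LABELS = {
    "kind_reception": "Kind reception",
    "fear_anxiety_doctors": "Fear and anxiety management - doctors",
    "fear_anxiety_nurses": "Fear and anxiety management - nurses",
    "pain_management": "Pain management",
    "talk_in_front_doctors": "Talk in front of the patient as if he were not present - doctors",
    "talk_in_front_nurses": "Talk in front of the patient as if he were not present - nurses",
    "talk_in_front_other_staff": "Talk in front of the patient as if he were not present - other staff",
    "respect_dignity_doctors": "Respect and dignity - doctors",
    "respect_dignity_nurses": "Respect and dignity - nurses",
    "respect_dignity_other_staff": "Respect and dignity - other staff",
    "involvement": "Involvement",
    "clarity_answers_doctors": "Clarity of answers - doctors",
    "clarity_answers_nurses": "Clarity of answers - nurses",
    "information_caregivers": "Information to caregivers",
    "teamwork": "Teamwork",
    "silence": "Silence",
    "cleaning": "Cleaning",
    "discharge_selfcare": "Clarity of answers in discharge - selfcare",
    "discharge_therapy": "Clarity of answers in discharge - therapy",
}


@dataclass(frozen=True)
class CodebookItem:
    """One questionnaire item.

    ``polarity`` records whether a higher response means a better experience
    (``direct``) or a worse one (``reverse``).  It is descriptive metadata:
    responses are never recoded automatically.
    """

    item_id: str
    label: str
    polarity: str = "direct"
    scale_labels: dict[int, str] = field(default_factory=lambda: dict(FREQUENCY_SCALE))

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be non-empty")
        if self.polarity not in ("direct", "reverse"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if sorted(self.scale_labels) != [1, 2, 3, 4, 5]:
            raise ValidationError(f"item {self.item_id!r} needs exactly 5 scale labels (1..5)")


@dataclass(frozen=True)
class ItemCodebook:
    """Ordered collection of :class:`CodebookItem` with unique identifiers."""

    entries: tuple[CodebookItem, ...]

    def __post_init__(self) -> None:
        ids = [e.item_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate item_ids in codebook")

    def __iter__(self) -> Iterator[CodebookItem]:
        return iter(self.entries)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.item_ids

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(e.item_id for e in self.entries)

    @property
    def experience_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.item_ids if i != SATISFACTION_ITEM)

    def __getitem__(self, item_id: str) -> CodebookItem:
        for e in self.entries:
            if e.item_id == item_id:
                return e
        raise KeyError(item_id)

    def decode_label(self, item_id: str, text: str) -> int:
        """Map a response label (case-insensitive) to its 1–5 value."""
        labels = {v.lower(): k for k, v in self[item_id].scale_labels.items()}
        try:
            return labels[text.strip().lower()]
        except KeyError:
            raise ValidationError(f"unrecognized response {text!r} for item {item_id!r}") from None

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "item_id": e.item_id,
                "label": e.label,
                "polarity": e.polarity,
                "scale_labels": {str(k): v for k, v in e.scale_labels.items()},
            }
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemCodebook":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(
                CodebookItem(
                    item_id=d["item_id"],
                    label=d["label"],
                    polarity=d.get("polarity", "direct"),
                    scale_labels={int(k): v for k, v in d["scale_labels"].items()},
                )
                for d in payload
            )
        )


def default_codebook() -> ItemCodebook:
    """The 19 experience items plus the overall-satisfaction item."""
    entries = [CodebookItem(i, _EXPERIENCE_LABELS[i]) for i in EXPERIENCE_ITEMS]
    entries.append(
        CodebookItem(
            SATISFACTION_ITEM,
            "Overall, how would you rate the care you received in the department?",
            scale_labels=dict(QUALITY_SCALE),
        )
    )
    return ItemCodebook(tuple(entries))
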