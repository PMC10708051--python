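"""Analytical Eco-Scale (AES) greenness scoring.

The Eco-Scale rates an analytical procedure by subtracting penalty points
(PPs) from an ideal score of 100.  Penalties accrue for reagent amounts,
reagent hazards (GHS pictograms weighted by signal word), instrument energy
consumption, occupational exposure and waste production/treatment.  Scores
above 75 denote an excellent green analysis, above 50 an acceptable one.

The calculator accepts either rule-derived penalty points (via
:func:`hazard_pp` / :func:`amount_pp`) or directly asserted ones, since
published ledgers often state per-item PPs as outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "CATEGORIES",
    "PenaltyItem",
    "PenaltyLedger",
    "aes_score",
    "hazard_pp",
    "amount_pp",
    "load_ledger",
    "merge_ledgers",
    "format_ledger_table",
]

CATEGORIES = (
    "reagent_amount",
    "reagent_hazard",
    "instrument_energy",
    "occupational",
    "waste_production",
    "waste_treatment",
)

_SIGNAL_MULTIPLIER = {"none": 0, "warning": 1, "danger": 2}


@dataclass(frozen=True)
class PenaltyItem:
    """One ledger entry: category, free-text description, penalty points."""

    category: str
    description: str
    pp: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if not isinstance(self.pp, int) or isinstance(self.pp, bool):
            raise ValueError("penalty points must be an integer")
        if self.pp < 0:
            raise ValueError("penalty points must be non-negative")


@dataclass
class PenaltyLedger:
    """Itemized penalty points for one analytical method."""

    items: list[PenaltyItem] = field(default_factory=list)
    method: str = ""

    def __post_init__(self) -> None:
        seen_instruments = set()
        for item in self.items:
            if item.category == "instrument_energy":
                if item.description in seen_instruments:
                    raise ValueError(
                        f"duplicate instrument_energy entry: {item.description!r}"
                    )
                seen_instruments.add(item.description)

    def total_pp(self) -> int:
        return sum(item.pp for item in self.items)

    def subtotal(self, category: str) -> int:
        return sum(item.pp for item in self.items if item.category == category)


def aes_score(ledger: PenaltyLedger) -> dict:
    """Eco-Scale score: ``max(100 - total PPs, 0)`` with classification.

    Classification: score > 75 "excellent", > 50 "acceptable", otherwise
    "inadequate".
    """
    total = ledger.total_pp()
    score = max(100 - total, 0)
    if score > 75:
        classification = "excellent"
    elif score > 50:
        classification = "acceptable"
    else:
        classification = "inadequate"
    return {"total_pp": total, "score": score, "classification": classification}


def hazard_pp(pictogram_count: int, signal_word: str) -> int:
    """Reagent-hazard penalty: GHS pictogram count x signal-word multiplier
    (none 0, warning 1, danger 2)."""
    if pictogram_count < 0:
        raise ValueError("pictogram count must be non-negative")
    if signal_word not in _SIGNAL_MULTIPLIER:
        raise ValueError(f"signal word must be one of {sorted(_SIGNAL_MULTIPLIER)}")
    return pictogram_count * _SIGNAL_MULTIPLIER[signal_word]


def amount_pp(volume_ml_per_sample: float) -> int:
    """Reagent/solvent-amount penalty from the per-sample volume band:
    < 1 mL -> 1 PP, 1-10 mL -> 2 PPs, > 10 mL -> 3 PPs."""
    if volume_ml_per_sample < 0:
        raise ValueError("volume must be non-negative")
    if volume_ml_per_sample < 1.0:
        return 1
    if volume_ml_per_sample <= 10.0:
        return 2
    return 3


def load_ledger(path: str | Path) -> PenaltyLedger:
    """Load a penalty ledger from YAML or JSON.

    Expected structure: ``{method: str, items: [{category, description, pp}]}``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "items" not in raw:
        raise ValueError(f"{path}: ledger must be a mapping with an 'items' list")
    items = [
        PenaltyItem(
            category=entry["category"],
            description=entry.get("description", ""),
            pp=int(entry["pp"]),
        )
        for entry in raw["items"]
    ]
    return PenaltyLedger(items=items, method=str(raw.get("method", "")))


def merge_ledgers(*ledgers: PenaltyLedger, method: str = "") -> PenaltyLedger:
    """Concatenate ledgers; total PPs are additive by construction."""
    items: list[PenaltyItem] = []
    for ledger in ledgers:
        items.extend(ledger.items)
    return PenaltyLedger(items=items, method=method or "; ".join(
        l.method for l in ledgers if l.method
    ))


def format_ledger_table(ledger: PenaltyLedger) -> str:
    """Plain-text table with per-category subtotals, total and score."""
    lines = [f"Eco-Scale ledger: {ledger.method}".rstrip(": "), "-" * 46]
    for category in CATEGORIES:
        items = [i for i in ledger.items if i.category == category]
        if not items:
            continue
        lines.append(category.replace("_", " "))
        for item in items:
            lines.append(f"  {item.description:<38} {item.pp:>3}")
        lines.append(f"  {'subtotal':<38} {ledger.subtotal(category):>3}")
    result = aes_score(ledger)
    lines.append("-" * 46)
    lines.append(f"  {'Total PPs':<38} {result['total_pp']:>3}")
    lines.append(f"  {'Eco-Scale score':<38} {result['score']:>3}")
    lines.append(f"  {'Classification':<38} {result['classification']}")
    return "\n".join(lines)
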