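"""Amino-acid composition accounting and query-vs-reference deltas."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "CATEGORIES",
    "CompositionDelta",
    "aa_counts",
    "composition_delta",
    "composition_report",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES: dict[str, str] = {
    "negative": "DE",
    "positive": "KRH",
    "hydrophobic": "AVLIMFW",
    "glycine": "G",
}


@dataclass
class CompositionDelta:
    query_id: str
    reference_id: str
    delta: dict[str, int]
    category_deltas: dict[str, int]

    def __neg__(self) -> "CompositionDelta":
        return CompositionDelta(
            query_id=self.reference_id,
            reference_id=self.query_id,
            delta={aa: -v for aa, v in self.delta.items()},
            category_deltas={k: -v for k, v in self.category_deltas.items()},
        )


def aa_counts(sequence: str) -> dict[str, int]:
    """Per-residue counts over the 20-letter alphabet ('X' counted separately).

    Raises ValueError naming the position of the first non-alphabet
    character.  Case-insensitive.
    """
    counts = {aa: 0 for aa in AMINO_ACIDS}
    counts["X"] = 0
    for pos, ch in enumerate(sequence.upper(), start=1):
        if ch not in counts:
            raise ValueError(f"invalid amino-acid character {ch!r} at position {pos}")
        counts[ch] += 1
    return counts


def composition_delta(
    query_seq: str,
    reference_seq: str,
    query_id: str = "query",
    reference_id: str = "reference",
) -> CompositionDelta:
    """Per-amino-acid count differences, query minus reference."""
    if not query_seq or not reference_seq:
        raise ValueError("both sequences must be non-empty")
    cq = aa_counts(query_seq)
    cr = aa_counts(reference_seq)
    delta = {aa: cq[aa] - cr[aa] for aa in cq}
    category_deltas = {
        name: sum(delta[aa] for aa in members)
        for name, members in CATEGORIES.items()
    }
    return CompositionDelta(query_id, reference_id, delta, category_deltas)


def composition_report(deltas: list[CompositionDelta]) -> pd.DataFrame:
    """Tabular per-amino-acid signed counts, one column pair per delta.

    Rows ordered by one-letter code; the 'direction' annotation marks each
    signed count as an increase, decrease, or unchanged relative to the
    reference.
    """
    if not deltas:
        raise ValueError("at least one composition delta is required")
    rows = []
    for aa in sorted(AMINO_ACIDS):
        row: dict[str, object] = {"aa": aa}
        for d in deltas:
            label = f"{d.query_id}-{d.reference_id}"
            value = d.delta[aa]
            row[label] = value
            row[f"{label}:direction"] = (
                "increase" if value > 0 else "decrease" if value < 0 else "unchanged"
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("aa")
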