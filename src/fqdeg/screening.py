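"""Derivative screening: percent-change statistics, environmental red lines,
ranking, and the soil nutrient survey summary.

Candidate derivatives of a parent antibiotic are compared against the parent
on predicted biodegradability (composite and per-receptor), genotoxicity
(pLOEC), bioconcentration (logK_ow, red line at logK_ow > 5 per the
Stockholm Convention persistence definition) and photodegradability
(log t_1/2).  All changes are raw signed percentages of the parent value,
reported at 2 decimals (round half up).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DerivativeRecord",
    "property_change",
    "screen_bioconcentration",
    "rank_derivatives",
    "summarize_survey",
    "BIOCONCENTRATION_RED_LINE",
]

#: logK_ow threshold above which a chemical counts as bioaccumulative.
BIOCONCENTRATION_RED_LINE = 5.0

#: Property columns compared derivative-vs-parent.
CHANGE_PROPERTIES = ("cv", "g1gkq", "g1ob0", "g5m0k", "ploec", "logkow", "logt12")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def property_change(new: float, reference: float, ndigits: int = 2) -> float:
    """Signed percent change ``100 * (new - reference) / reference``."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    if not (np.isfinite(new) and np.isfinite(reference)):
        raise ValueError("non-finite input to property_change")
    return round_half_up(100.0 * (new - reference) / reference, ndigits)


def screen_bioconcentration(logkow: float) -> bool:
    """True (pass) iff logK_ow <= 5; fail only strictly above the red line."""
    if not np.isfinite(logkow):
        raise ValueError("logK_ow must be finite")
    return not (logkow > BIOCONCENTRATION_RED_LINE)


@dataclass(frozen=True)
class DerivativeRecord:
    """Predicted properties of one compound (parent or derivative)."""

    name: str
    site: Optional[int]       # substitution site (1 or 2); None for the parent
    group: Optional[str]      # substituent label, e.g. 'NH2'
    cv: float                 # composite biodegradability value
    g1gkq: float              # per-receptor predicted activities
    g1ob0: float
    g5m0k: float
    ploec: float              # genotoxicity
    logkow: float             # bioconcentration
    logt12: float             # photodegradability (log half-life)
    is_parent: bool = False

    def __post_init__(self):
        vals = (self.cv, self.g1gkq, self.g1ob0, self.g5m0k,
                self.ploec, self.logkow, self.logt12)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite prediction in record {self.name!r}")


def rank_derivatives(records: Sequence[DerivativeRecord]) -> pd.DataFrame:
    """Per-derivative percent changes vs the parent, flags and ranking.

    Exactly one record must be flagged as parent.  The output has one row
    per derivative (the parent is excluded), change columns for every
    property, the bioconcentration red-line flag, and is sorted by composite
    change descending with name as the tie-break.
    """
    parents = [r for r in records if r.is_parent]
    if len(parents) != 1:
        raise ValueError(f"need exactly one parent record, found {len(parents)}")
    parent = parents[0]
    rows = []
    for r in records:
        if r.is_parent:
            continue
        row = {"name": r.name, "site": r.site, "group": r.group}
        for prop in CHANGE_PROPERTIES:
            row[prop] = getattr(r, prop)
            row[f"{prop}_change"] = property_change(getattr(r, prop), getattr(parent, prop))
        row["bioconcentration_ok"] = screen_bioconcentration(r.logkow)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["cv_change", "name"], ascending=[False, True],
                           ignore_index=True)


def summarize_survey(table: pd.DataFrame, rounding: int = 2,
                     elements: Sequence[str] = ("c", "n", "p"),
                     addition_levels: Optional[dict] = None) -> dict:
    """Arithmetic means of nutrient contents (g/kg), rounded half-up.

    ``addition_levels`` (amounts of each element to add in the downstream
    simulation recipe) is configuration passed through untouched, never
    derived from the means.
    """
    if len(table) == 0:
        raise ValueError("empty survey table")
    missing = [e for e in elements if e not in table.columns]
    if missing:
        raise ValueError(f"survey table lacks columns {missing}")
    if (table[list(elements)] < 0).any().any():
        raise ValueError("nutrient contents must be non-negative")
    means = {e: round_half_up(float(table[e].mean()), rounding) for e in elements}
    return {
        "n_sites": int(len(table)),
        "means_g_per_kg": means,
        "addition_levels": dict(addition_levels) if addition_levels else None,
    }
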