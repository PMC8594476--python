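"""Set-intersection censuses and percentage arithmetic.

Descriptive reporting over site memberships (catalogs, replication
tiers, disease lists): exact counts for every requested set
combination in upset style, and percentages that always carry their
numerator and denominator.
"""

from __future__ import annotations

import dataclasses
import itertools
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``.

    Half-up (not banker's) rounding matches how printed percentages are
    conventionally reported.
    """
    if denominator == 0:
        raise ValueError("percent() denominator must be > 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class IntersectionCensus:
    """Counts over named boolean site memberships.

    ``set_sizes`` maps set name -> size; ``exact_counts`` maps a
    frozenset of member-set names (the exact combination a site belongs
    to) -> count; ``total`` is the universe size.
    """

    set_names: list
    set_sizes: dict
    exact_counts: dict
    total: int

    def count(self, include=(), exclude=()) -> int:
        """Sites in every set of ``include`` and none of ``exclude``."""
        include, exclude = set(include), set(exclude)
        unknown = (include | exclude) - set(self.set_names)
        if unknown:
            raise KeyError(f"unknown set name(s): {sorted(unknown)}")
        return sum(
            n
            for combo, n in self.exact_counts.items()
            if include <= combo and not (exclude & combo)
        )

    def union(self, names) -> int:
        names = set(names)
        unknown = names - set(self.set_names)
        if unknown:
            raise KeyError(f"unknown set name(s): {sorted(unknown)}")
        return sum(
            n for combo, n in self.exact_counts.items() if combo & names
        )

    def percentage(self, include=(), exclude=(), of=None, decimals=1) -> dict:
        """Percentage of ``count(include, exclude)`` over a denominator
        (the universe by default, or another count spec)."""
        num = self.count(include, exclude)
        den = self.total if of is None else self.count(*of)
        return {
            "numerator": num,
            "denominator": den,
            "percent": percent(num, den, decimals),
            "decimals": decimals,
        }

    def upset_table(self) -> pd.DataFrame:
        rows = []
        for combo in sorted(
            self.exact_counts, key=lambda c: (-len(c), sorted(c))
        ):
            rows.append(
                {
                    **{name: name in combo for name in self.set_names},
                    "count": self.exact_counts[combo],
                }
            )
        return pd.DataFrame(rows)


def census(memberships: pd.DataFrame, sets: list | None = None) -> IntersectionCensus:
    """Build an :class:`IntersectionCensus` from boolean membership
    columns (one row per site).

    ``sets`` selects and orders the membership columns; unknown names
    raise.  Counts are exact-combination counts, so they satisfy
    inclusion-exclusion by construction.
    """
    if sets is None:
        sets = [c for c in memberships.columns if memberships[c].dtype == bool]
    unknown = [s for s in sets if s not in memberships.columns]
    if unknown:
        raise KeyError(f"unknown set name(s): {unknown}")
    m = memberships[sets].astype(bool)
    combos: dict[frozenset, int] = {}
    if len(m):
        grouped = m.groupby(sets, observed=True).size()
        for key, n in grouped.items():
            key = (key,) if len(sets) == 1 else key
            combo = frozenset(s for s, flag in zip(sets, key) if flag)
            combos[combo] = combos.get(combo, 0) + int(n)
    # make every combination explicit (zero counts included) when small
    if len(sets) <= 6:
        for r in range(len(sets) + 1):
            for combo in itertools.combinations(sets, r):
                combos.setdefault(frozenset(combo), 0)
    sizes = {s: int(m[s].sum()) for s in sets}
    return IntersectionCensus(
        set_names=list(sets),
        set_sizes=sizes,
        exact_counts=combos,
        total=int(len(m)),
    )
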