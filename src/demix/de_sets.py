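"""Cross-population DE set logic.

A gene belongs to a population's exclusive set when it is called DE there
and in no other population; the set is split by the sign of the
gene-by-population effect into over- and underexpressed members. This is
the operation behind statements like "445 genes overexpressed exclusively
in the stem-cell-enriched fraction".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mixture import DECalls

__all__ = ["ExclusiveDESets", "exclusive_de_sets"]


@dataclass
class ExclusiveDESets:
    population: str
    up: set[str]
    down: set[str]


def exclusive_de_sets(
    calls: list[DECalls], effects: pd.DataFrame
) -> dict[str, ExclusiveDESets]:
    """Per population: genes DE there and nowhere else, split by sign.

    ``effects`` is the gene x population effect table the calls were made
    from; it supplies the gene universe and the signs. Call sets must be
    subsets of that universe.
    """
    universe = set(effects.index)
    for c in calls:
        stray = set(c.de_genes) - universe
        if stray:
            raise ValueError(
                f"call set {c.population!r} contains genes outside the effect "
                f"table: {sorted(stray)[:5]}"
            )
    de_by_pop = {c.population: set(c.de_genes) for c in calls}
    out: dict[str, ExclusiveDESets] = {}
    for c in calls:
        others: set[str] = set()
        for q, s in de_by_pop.items():
            if q != c.population:
                others |= s
        exclusive = set(c.de_genes) - others
        up = {g for g in exclusive if c.de_genes[g] > 0}
        down = {g for g in exclusive if c.de_genes[g] < 0}
        out[c.population] = ExclusiveDESets(population=c.population, up=up, down=down)
    return out
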