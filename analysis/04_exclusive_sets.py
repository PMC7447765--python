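"""Exclusive up/down DE sets per population.

Genes called DE in exactly one population, split by the sign of their
interaction effect — the population-specific expression signatures.
Reads results/lmm/ and results/de/, writes results/de/exclusive_*.tsv.
"""

from pathlib import Path

import pandas as pd

from demix.de_sets import exclusive_de_sets
from demix.io import read_effect_table
from demix.mixture import DECalls

EFFECTS = Path("results/lmm/effects.tsv")
CALLS = Path("results/de/de_calls.tsv")
OUT = Path("results/de")


def main() -> None:
    effects = read_effect_table(EFFECTS)
    table = pd.read_csv(CALLS, sep="\t")
    calls = []
    for pop in effects.columns:
        sub = table[table["population"] == pop]
        calls.append(DECalls(population=pop, threshold=0.8,
                             de_genes=dict(zip(sub["gene_id"], sub["sign"])),
                             fdr=None, effect_cutoff=0.0))
    for pop, s in exclusive_de_sets(calls, effects).items():
        safe = pop.replace("/", "_")
        rows = [{"gene_id": g, "direction": "up"} for g in sorted(s.up)]
        rows += [{"gene_id": g, "direction": "down"} for g in sorted(s.down)]
        pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
            OUT / f"exclusive_{safe}.tsv", sep="\t", index=False
        )
        print(f"{pop}: {len(s.up)} exclusively up, {len(s.down)} exclusively down")


if __name__ == "__main__":
    main()
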