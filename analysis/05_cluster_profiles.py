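"""Cluster DE genes into 8 expression-pattern groups.

Standardizes each DE gene's profile across the four populations and cuts a
Ward dendrogram at the third level of splitting (2^3 = 8 clusters), the
structure used for heatmap display and per-cluster enrichment. Reads
results/lmm/ and results/de/, writes results/clusters/.
"""

from pathlib import Path

import pandas as pd

from demix.clustering import cluster_de_profiles
from demix.io import read_effect_table

EFFECTS = Path("results/lmm/effects.tsv")
CALLS = Path("results/de/de_calls.tsv")
OUT = Path("results/clusters")


def main() -> None:
    effects = read_effect_table(EFFECTS)
    de_genes = sorted(set(pd.read_csv(CALLS, sep="\t")["gene_id"]))
    assignment = cluster_de_profiles(effects.loc[de_genes], n_levels=3)
    OUT.mkdir(parents=True, exist_ok=True)
    assignment.labels.to_csv(OUT / "clusters.tsv", sep="\t", index_label="gene_id")
    assignment.standardized_profiles.loc[assignment.leaf_order].to_csv(
        OUT / "heatmap_matrix.tsv", sep="\t", index_label="gene_id"
    )
    print(f"{len(de_genes)} DE genes into {assignment.n_clusters} clusters")
    for c, n in assignment.sizes().items():
        print(f"  cluster {c}: {n} genes")


if __name__ == "__main__":
    main()
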