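"""Hypergeometric over-representation analysis with BH-FDR control.

Given a gene set (a cluster, an exclusive up/down set), a gene universe and
a term -> genes annotation map, each term is tested for over-representation
with the hypergeometric upper tail P(X >= k), where k is the overlap, K the
term size, n the set size and N the universe size. P-values are adjusted by
Benjamini-Hochberg across the tested terms and flagged at the FDR cutoff
(0.05 by default). Only over-representation is tested; depletion is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationMap", "enrich", "read_annotation_tsv", "read_gmt"]


@dataclass
class AnnotationMap:
    """term id -> gene id set, with optional human-readable term names."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise ValueError(f"empty annotation terms: {empty[:5]}")

    def restricted_to(self, universe: set[str]) -> "AnnotationMap":
        terms = {t: g & universe for t, g in self.terms.items()}
        return AnnotationMap(
            terms={t: g for t, g in terms.items() if g}, names=dict(self.names)
        )


def enrich(
    gene_set,
    universe,
    annotations: AnnotationMap,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``gene_set`` in each annotation term.

    Returns one row per tested term with the overlap k, set size n, term
    size K, universe size N, hypergeometric upper-tail p-value, BH-adjusted
    FDR and a significance flag at the cutoff, sorted by p-value.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene_set members outside the universe: {sorted(stray)[:10]}")
    ann = annotations.restricted_to(universe)
    N, n = len(universe), len(gene_set)
    rows = []
    for term, members in sorted(ann.terms.items()):
        K = len(members)
        k = len(members & gene_set)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": ann.names.get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(
            columns=["term_id", "term_name", "k", "n", "K", "N", "p_value", "fdr", "significant"]
        )
    _, fdr, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < fdr_cutoff
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def read_annotation_tsv(path: str | Path, names_path: str | Path | None = None) -> AnnotationMap:
    """Read a 2-column term_id<TAB>gene_id file, optionally with a
    term_id<TAB>term_name sidecar."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], dtype=str)
    terms: dict[str, set[str]] = {}
    for t, g in zip(df["term_id"], df["gene_id"]):
        terms.setdefault(t, set()).add(g)
    names: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "name"], dtype=str)
        names = dict(zip(nd["term_id"], nd["name"]))
    return AnnotationMap(terms=terms, names=names)


def read_gmt(path: str | Path) -> AnnotationMap:
    """Read GMT: term<TAB>description<TAB>gene1<TAB>gene2..."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            terms[term] = set(genes)
            names[term] = desc or term
    return AnnotationMap(terms=terms, names=names)
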