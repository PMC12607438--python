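"""Hypergeometric term enrichment and PPI hub analysis.

Enrichment is the standard one-sided (upper tail) hypergeometric test
of a query gene set against term annotations over a declared universe,
BH-corrected within each namespace.  No DAG propagation or topology:
annotations are taken as supplied (real GO/KEGG/STRING content is user
input, never fetched).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

ENRICH_COLS = ["term_id", "term_name", "namespace", "k", "K", "n", "N", "p", "q"]
PPI_COLS = ["gene_a", "gene_b", "confidence"]


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    need = ["term_id", "term_name", "namespace", "gene_id"]
    missing = [c for c in need if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if annotation.empty:
        raise ValueError("annotation has no rows (empty term sets not allowed)")
    return annotation


def hypergeom_enrich(query_genes, annotation: pd.DataFrame,
                     universe=None) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query_genes``.

    The universe defaults to every gene present in the annotation map.
    Terms with zero overlap are skipped; q is BH within namespace.
    """
    annotation = validate_annotation(annotation)
    if universe is None:
        universe = set(annotation["gene_id"])
    else:
        universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:5]}")
    n = len(query)
    N = len(universe)
    rows = []
    for (term, name, ns), sub in annotation.groupby(
            ["term_id", "term_name", "namespace"], sort=True):
        members = set(sub["gene_id"]) & universe
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, name, ns, k, K, n, N, min(max(p, 0.0), 1.0), 1.0))
    out = pd.DataFrame(rows, columns=ENRICH_COLS)
    for ns, idx in out.groupby("namespace").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out.sort_values(["namespace", "p", "term_id"],
                           kind="mergesort").reset_index(drop=True)


def ppi_filter_and_hubs(edges: pd.DataFrame, min_conf: float = 0.40,
                        top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confidence-filter a PPI edge table and rank hub genes by degree.

    Edges are undirected; self-loops are dropped; the >= min_conf
    filter is inclusive.  Hubs are the ``top_n`` genes by degree, ties
    broken by name.
    """
    missing = [c for c in PPI_COLS if c not in edges.columns]
    if missing:
        raise ValueError(f"PPI table missing columns {missing}")
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise ValueError("confidences must lie in [0, 1]")
    kept = edges[(edges["confidence"] >= min_conf)
                 & (edges["gene_a"] != edges["gene_b"])].copy()
    # canonical undirected orientation + dedup
    lo = kept[["gene_a", "gene_b"]].min(axis=1)
    hi = kept[["gene_a", "gene_b"]].max(axis=1)
    kept["gene_a"], kept["gene_b"] = lo, hi
    kept = (kept.drop_duplicates(subset=["gene_a", "gene_b"])
            .sort_values(["gene_a", "gene_b"], kind="mergesort")
            .reset_index(drop=True))
    deg = pd.concat([kept["gene_a"], kept["gene_b"]]).value_counts()
    hub_rows = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    hubs = pd.DataFrame(hub_rows, columns=["gene", "degree"])
    return kept, hubs


def pathway_gene_table(enrichment: pd.DataFrame, annotation: pd.DataFrame,
                       query_genes) -> pd.DataFrame:
    """Long-format (term, gene, q) table for Sankey-style reporting:
    one row per enriched term per overlapping query gene, sorted by q
    then term."""
    query = set(query_genes)
    members = annotation.groupby("term_id")["gene_id"].agg(set)
    rows = []
    for rec in enrichment.itertuples(index=False):
        for g in sorted(members.get(rec.term_id, set()) & query):
            rows.append((rec.term_id, g, rec.q))
    out = pd.DataFrame(rows, columns=["term_id", "gene_id", "q"])
    return out.sort_values(["q", "term_id", "gene_id"],
                           kind="mergesort").reset_index(drop=True)
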