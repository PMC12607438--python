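"""Correlation-filtered ceRNA triad assembly and core-network selection.

The sponge logic: a circRNA that sequesters a miRNA shows expression
negatively correlated with the free miRNA, the miRNA is negatively
correlated with its mRNA target, and sponge and target co-vary
positively.  Candidate pairs are restricted to differentially
expressed features with predicted binding, then filtered by Pearson
correlation on log2(CPM+1) profiles with sign-specific thresholds
(r <= r_neg_max for circRNA-miRNA and miRNA-mRNA edges, r >= r_pos_min
for circRNA-mRNA edges, all with p <= corr_p_max, raw p by design).
Triads are the joins of the three edge classes over a shared miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexpr
from .io import group_samples

EDGE_COLS = ["node_a", "node_b", "r", "p", "n"]
TRIAD_COLS = ["circ_id", "mir_id", "mrna_id",
              "r_circ_mir", "p_circ_mir", "r_mir_mrna", "p_mir_mrna",
              "r_circ_mrna", "p_circ_mrna"]


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-distribution p-value.

    Requires length >= 3, finite values, and non-constant vectors (a
    constant profile has no defined correlation and raises rather than
    returning a silent 0).  For r = +-1 the p-value underflows to the
    smallest positive float.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    tiny = np.finfo(float).tiny
    if abs(r) == 1.0:
        return r, tiny, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(max(min(p, 1.0), tiny)), n


def log_cpm_profiles(matrix: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """log2(CPM+1) on TMM-normalized libraries, restricted to samples."""
    sub = matrix[samples]
    return np.log2(diffexpr.cpm(sub) + 1.0)


def _correlate_pairs(candidates, prof_a, prof_b):
    rows = []
    for a, b in candidates:
        xa = prof_a.loc[a].to_numpy()
        xb = prof_b.loc[b].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue  # degenerate profile cannot support an edge
        r, p, n = pearson(xa, xb)
        rows.append((a, b, r, p, n))
    return pd.DataFrame(rows, columns=EDGE_COLS)


def build_pairs(de_tables: dict, target_pairs: pd.DataFrame, expression: dict,
                design: pd.DataFrame, contrast, config):
    """Correlation-filtered edge tables for one contrast.

    ``de_tables``/``expression`` map layer -> DE table / count matrix;
    ``target_pairs`` is the predicted-binding table.  Returns the three
    edge DataFrames (circ-mir, mir-mrna, circ-mrna).  Empty DE tables
    yield empty edge tables.
    """
    de_ids = {layer: set(t.loc[t["call"] != "ns", "feature_id"])
              for layer, t in de_tables.items()}
    if config.correlation_samples == "all":
        samples = list(design["sample_id"])
    else:
        samples = group_samples(design, contrast[0]) + group_samples(design, contrast[1])

    prof = {layer: log_cpm_profiles(m, samples) for layer, m in expression.items()}

    tp = target_pairs
    circ_mir_cand = sorted({
        (row.target_id, row.mirna_id)
        for row in tp[tp["target_kind"] == "circRNA"].itertuples(index=False)
        if row.target_id in de_ids["circRNA"] and row.mirna_id in de_ids["miRNA"]
    })
    mir_mrna_cand = sorted({
        (row.mirna_id, row.target_id)
        for row in tp[tp["target_kind"] == "utr3"].itertuples(index=False)
        if row.mirna_id in de_ids["miRNA"] and row.target_id in de_ids["mRNA"]
    })
    # circ-mRNA candidates must share at least one predicted miRNA
    mirs_of_circ: dict[str, set] = {}
    for c, m in circ_mir_cand:
        mirs_of_circ.setdefault(c, set()).add(m)
    mrnas_of_mir: dict[str, set] = {}
    for m, g in mir_mrna_cand:
        mrnas_of_mir.setdefault(m, set()).add(g)
    circ_mrna_cand = sorted({
        (c, g)
        for c, mirs in mirs_of_circ.items()
        for m in mirs
        for g in mrnas_of_mir.get(m, ())
    })

    circ_mir = _correlate_pairs(circ_mir_cand, prof["circRNA"], prof["miRNA"])
    mir_mrna = _correlate_pairs(mir_mrna_cand, prof["miRNA"], prof["mRNA"])
    circ_mrna = _correlate_pairs(circ_mrna_cand, prof["circRNA"], prof["mRNA"])

    def _neg(df):
        return df[(df["r"] <= config.r_neg_max) & (df["p"] <= config.corr_p_max)]

    def _pos(df):
        return df[(df["r"] >= config.r_pos_min) & (df["p"] <= config.corr_p_max)]

    return (_neg(circ_mir).reset_index(drop=True),
            _neg(mir_mrna).reset_index(drop=True),
            _pos(circ_mrna).reset_index(drop=True))


def assemble_triads(circ_mir: pd.DataFrame, mir_mrna: pd.DataFrame,
                    circ_mrna: pd.DataFrame) -> pd.DataFrame:
    """Join the three edge classes into circRNA-miRNA-mRNA triads.

    A triad is emitted iff its circ-mir and mir-mrna edges share the
    miRNA and the circ-mrna support edge exists.  Output is
    deduplicated and sorted by (circ, mir, mrna).
    """
    pos = {(row.node_a, row.node_b): (row.r, row.p)
           for row in circ_mrna.itertuples(index=False)}
    by_mir: dict[str, list] = {}
    for row in mir_mrna.itertuples(index=False):
        by_mir.setdefault(row.node_a, []).append(row)
    rows = []
    for cm in circ_mir.itertuples(index=False):
        for mg in by_mir.get(cm.node_b, ()):
            support = pos.get((cm.node_a, mg.node_b))
            if support is not None:
                rows.append((cm.node_a, cm.node_b, mg.node_b,
                             cm.r, cm.p, mg.r, mg.p, support[0], support[1]))
    out = pd.DataFrame(rows, columns=TRIAD_COLS).drop_duplicates(
        subset=["circ_id", "mir_id", "mrna_id"])
    return out.sort_values(["circ_id", "mir_id", "mrna_id"],
                           kind="mergesort").reset_index(drop=True)


def dem_deg_network(de_mirnas: pd.DataFrame, de_genes: pd.DataFrame,
                    target_pairs: pd.DataFrame, expression: dict,
                    design: pd.DataFrame, contrast, config,
                    gene_whitelist=None) -> pd.DataFrame:
    """Bipartite DEM-DEG network: binding + negative correlation,
    optionally restricted to a gene whitelist (None = unrestricted)."""
    de_tables = {"miRNA": de_mirnas, "mRNA": de_genes,
                 "circRNA": pd.DataFrame(columns=["feature_id", "call"])}
    expr = dict(expression)
    if "circRNA" not in expr:
        expr["circRNA"] = expr["mRNA"].iloc[:0]
    _, mir_mrna, _ = build_pairs(de_tables, target_pairs, expr, design, contrast, config)
    if gene_whitelist is not None:
        mir_mrna = mir_mrna[mir_mrna["node_b"].isin(set(gene_whitelist))]
    return mir_mrna.reset_index(drop=True)


@dataclass
class CoreNetwork:
    """Top-k-miRNA core: the selected miRNAs, their induced triads,
    and which comparison each triad came from."""

    mirnas: list
    triads: pd.DataFrame          # TRIAD_COLS + comparison
    top_by_comparison: dict       # comparison -> ranked top-k list


def mirna_degrees(triads: pd.DataFrame) -> pd.Series:
    """Relationship-pair count per miRNA: distinct circ-mir plus
    mir-mrna pairs over the triad set."""
    sponge = triads[["circ_id", "mir_id"]].drop_duplicates()
    target = triads[["mir_id", "mrna_id"]].drop_duplicates()
    deg = sponge["mir_id"].value_counts().add(
        target["mir_id"].value_counts(), fill_value=0)
    return deg.astype(int)


def select_core(triads_by_comparison: dict, k: int = 10) -> CoreNetwork:
    """Intersection of per-comparison top-k miRNAs by interaction-pair
    degree, with the triads they induce.

    Ranking key per comparison: (-degree, miRNA id); ties therefore
    resolve alphabetically, deterministically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(triads_by_comparison) < 2:
        raise ValueError("core selection needs >= 2 comparisons")
    top: dict = {}
    for name, triads in triads_by_comparison.items():
        deg = mirna_degrees(triads)
        ranked = sorted(deg.index, key=lambda m: (-deg[m], m))
        top[name] = ranked[:k]
    core = set.intersection(*(set(v) for v in top.values()))
    frames = []
    for name, triads in triads_by_comparison.items():
        sub = triads[triads["mir_id"].isin(core)].copy()
        sub["comparison"] = name
        frames.append(sub)
    merged = (pd.concat(frames, ignore_index=True)
              if frames else pd.DataFrame(columns=TRIAD_COLS + ["comparison"]))
    merged = merged.sort_values(["comparison", "circ_id", "mir_id", "mrna_id"],
                                kind="mergesort").reset_index(drop=True)
    return CoreNetwork(sorted(core), merged, top)


def integrate_networks(core_a: CoreNetwork, core_b: CoreNetwork,
                       gene_whitelist) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-comparison integrated network.

    Keeps triads whose (miRNA, mRNA) combination occurs in both cores
    and whose mRNA is in the whitelist; returns the triple table and
    the flattened, deduplicated interaction-pair list (each triad
    contributes its circ-mir and mir-mrna pairs).
    """
    wl = set(gene_whitelist)

    def _keys(core):
        return {(r.mir_id, r.mrna_id) for r in core.triads.itertuples(index=False)
                if r.mrna_id in wl}

    shared = _keys(core_a) & _keys(core_b)
    both = pd.concat([core_a.triads, core_b.triads], ignore_index=True)
    mask = np.fromiter(((r.mir_id, r.mrna_id) in shared
                        for r in both.itertuples(index=False)),
                       dtype=bool, count=len(both))
    keep = both[mask]
    triples = (keep[["circ_id", "mir_id", "mrna_id"]]
               .drop_duplicates()
               .sort_values(["circ_id", "mir_id", "mrna_id"], kind="mergesort")
               .reset_index(drop=True))
    pair_rows = sorted(
        {(r.circ_id, "circRNA", "sponges", r.mir_id, "miRNA")
         for r in triples.itertuples(index=False)}
        | {(r.mir_id, "miRNA", "targets", r.mrna_id, "mRNA")
           for r in triples.itertuples(index=False)}
    )
    pairs = pd.DataFrame(pair_rows, columns=["source", "source_kind", "relation",
                                             "target", "target_kind"])
    return triples, pairs
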