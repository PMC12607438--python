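"""TSV / FASTA / network readers and writers.

All tabular interchange is tab-separated UTF-8 with a mandatory header
row.  Output rows are deterministically sorted so identical runs diff
clean.  Sequences are held internally as upper-case RNA (T normalised
to U); FASTA I/O goes through Biopython.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

RNA_ALPHABET = frozenset("ACGUN")
SEQUENCE_KINDS = ("miRNA", "utr3", "circRNA")
FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence: a miRNA, an mRNA 3'UTR, or a circRNA."""

    id: str
    seq: str
    kind: str  # miRNA | utr3 | circRNA

    def __post_init__(self):
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.seq)


def normalize_rna(seq: str) -> str:
    """Upper-case and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------- design


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if list(design.columns[:2]) != ["sample_id", "group"]:
        raise ValueError("design needs columns: sample_id, group")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    if (design["group"].astype(str).str.len() == 0).any():
        raise ValueError("empty group name in design")
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t", dtype=str))


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design).to_csv(path, sep="\t", index=False)


def group_samples(design: pd.DataFrame, group: str) -> list[str]:
    sel = design.loc[design["group"] == group, "sample_id"]
    if sel.empty:
        raise KeyError(f"unknown group {group!r}")
    return list(sel)


# ---------------------------------------------------------------- counts


def read_counts(path: str | Path, design: pd.DataFrame) -> pd.DataFrame:
    """Read a counts TSV (feature_id + one column per sample).

    Returns a features x samples integer DataFrame with columns ordered
    as in the design.  Duplicated features, negative or non-integer
    counts, and samples missing from the file are errors.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        raise ValueError("first counts column must be 'feature_id'")
    df = df.set_index("feature_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r}")
    missing = [s for s in design["sample_id"] if s not in df.columns]
    if missing:
        raise ValueError(f"counts file missing sample columns {missing}")
    df = df[list(design["sample_id"])]
    values = df.to_numpy()
    if not ((values == values.astype(int)) & (values >= 0)).all():
        raise ValueError("counts must be non-negative integers")
    return df.astype(int)


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


# ----------------------------------------------------------------- fasta


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_rna(str(rec.seq)), kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


# --------------------------------------------------------------- tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump: sorted rows, fixed float format."""
    out = df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------- networks

#: SIF relation tokens by (source kind, target kind)
RELATIONS = {
    ("circRNA", "miRNA"): "sponges",
    ("miRNA", "mRNA"): "targets",
    ("mRNA", "mRNA"): "ppi",
}

EDGE_COLUMNS = ["source", "source_kind", "relation", "target", "target_kind"]


def edge_frame(edges: Iterable[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Build an edge table from (source, source_kind, target, target_kind)."""
    rows = []
    for src, skind, tgt, tkind in edges:
        rel = RELATIONS.get((skind, tkind))
        if rel is None:
            raise ValueError(f"no relation for {skind} -> {tkind}")
        rows.append((src, skind, rel, tgt, tkind))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def write_network(edges: pd.DataFrame, path: str | Path, dialect: str = "sif") -> None:
    """Export an edge table as Cytoscape SIF, GraphML or plain TSV.

    Edges must carry ``source/source_kind/relation/target/target_kind``
    columns.  Rows are written sorted by (source, target) in every
    dialect.
    """
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns {missing}")
    ordered = edges.sort_values(["source", "target"], kind="mergesort")
    if dialect == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for row in ordered.itertuples(index=False):
                fh.write(f"{row.source}\t{row.relation}\t{row.target}\n")
    elif dialect == "tsv":
        ordered.reset_index(drop=True).to_csv(path, sep="\t", index=False)
    elif dialect == "graphml":
        g = nx.DiGraph()
        for row in ordered.itertuples(index=False):
            g.add_node(row.source, kind=row.source_kind)
            g.add_node(row.target, kind=row.target_kind)
            g.add_edge(row.source, row.target, relation=row.relation)
        # write via a buffer so line endings are ours
        buf = _io.BytesIO()
        nx.write_graphml(g, buf)
        Path(path).write_bytes(buf.getvalue())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
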