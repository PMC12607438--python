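"""Synthetic multi-omic study generator with planted sponge axes.

Emulates the structure of a grouped whole-transcriptome ovary study:
four groups (by default named Som, Stm, Sad, Ud: juvenile,
pre-pubertal, adult, and a second-breed adult group) x three
replicates, negative-binomial counts for three RNA layers, miRNA /
3'UTR / circRNA sequences, and a truth table recording every planted
effect so downstream recovery is measurable without any download.

A planted ceRNA axis is a (circRNA, miRNA, mRNA) triple in which the
circRNA and mRNA share a group-level expression profile, the miRNA
carries the opposite profile (sponging lowers free miRNA where its
sponge is high), and the sequences contain a genuine 8mer seed site
plus a 3'-supplementary block for both the circRNA-miRNA and the
miRNA-mRNA interaction.  Decoy sequences are scrubbed of 7mer-or-better
sites for planted miRNAs, so planted binding is real signal and decoy
binding can arise only from chance 6mers.

Counts are NB(mean mu, var mu + phi mu^2) with
``mu = baseline_f * 2**effect(f, group) * libfactor_s``; library-size
factors are log-uniform in [0.7, 1.4].  miRNAs are 20-24 nt with a
5'-U probability of 0.8 (22 nt modal length); circRNAs are 200-2000 nt
(within the 200-20,000 nt range typical of exonic circRNAs), 3'UTRs
200-600 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import SequenceRecord, write_counts, write_design, write_fasta, write_table
from .targets import revcomp, COMPLEMENT

LAYER_PREFIX = {"circRNA": "circRNA_", "miRNA": "miR-", "mRNA": "gene_"}

DEFAULT_GROUP_NAMES = ("Som", "Stm", "Sad", "Ud")


@dataclass
class SimulationParams:
    """Study-design parameters of the generator (the defaults ARE the
    simulated study conditions; see docs/methods.md)."""

    n_mrna: int = 300
    n_circ: int = 80
    n_mir: int = 60
    n_axes: int = 10
    effect_size: float = 3.0          # log2 units
    dispersion: float = 0.05
    baseline_mean: float = 200.0
    decoy_de_fraction: float = 0.15   # extra non-axis DE features per layer
    lib_factor_range: tuple = (0.7, 1.4)
    mir_first_u_prob: float = 0.8
    mir_length_range: tuple = (20, 24)
    utr_length_range: tuple = (200, 600)
    circ_length_range: tuple = (200, 2000)


@dataclass
class PlantedAxis:
    circ_id: str
    mir_id: str
    mrna_id: str
    effect_size: float


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery, with no hidden state."""

    axes: list            # list[PlantedAxis]
    effects: pd.DataFrame  # layer, feature_id, group, effect_log2
    feature_ids: dict      # layer -> list of ids
    dispersion: float
    baseline_mean: float
    library_sizes: pd.Series   # sample_id -> positive factor
    baselines: pd.DataFrame    # layer, feature_id, baseline

    def effect(self, layer: str, feature_id: str, group: str) -> float:
        sel = self.effects[(self.effects["layer"] == layer)
                           & (self.effects["feature_id"] == feature_id)
                           & (self.effects["group"] == group)]
        return 0.0 if sel.empty else float(sel["effect_log2"].iloc[0])

    def true_log2fc(self, layer: str, feature_id: str, contrast) -> float:
        a, b = contrast
        return self.effect(layer, feature_id, b) - self.effect(layer, feature_id, a)

    def axis_triples(self) -> set:
        return {(ax.circ_id, ax.mir_id, ax.mrna_id) for ax in self.axes}


def simulate_design(n_groups: int = 4, reps: int = 3, seed: int = 0,
                    group_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Deterministic sample-to-group design table.

    Default names follow Group{i} / Group{i}_r{j}; pass ``group_names``
    (e.g. Som/Stm/Sad/Ud) to mirror a real study layout.  ``seed`` is
    accepted for interface symmetry; the table is seed-independent.
    """
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    if reps < 2:
        raise ValueError("need >= 2 replicates per group")
    if group_names is None:
        group_names = [f"Group{i + 1}" for i in range(n_groups)]
    elif len(group_names) != n_groups:
        raise ValueError("group_names length must equal n_groups")
    rows = [(f"{g}_r{j + 1}", g) for g in group_names for j in range(reps)]
    return pd.DataFrame(rows, columns=["sample_id", "group"])


def _feature_ids(layer: str, n: int) -> list[str]:
    return [f"{LAYER_PREFIX[layer]}{i + 1:04d}" for i in range(n)]


def _alternating_profile(groups: list[str], effect: float, phase: int) -> dict:
    """Group-effect profile that is up in every other group.

    phase 0: up in groups 1,3,... (0-based odd); phase 1: the others.
    Guarantees a full +-effect contrast between any two adjacent groups
    and perfect between-group anti-correlation between phases.
    """
    return {g: (effect if (i % 2 == (1 - phase)) else 0.0) for i, g in enumerate(groups)}


def simulate_counts(design: pd.DataFrame, params: SimulationParams, seed: int):
    """NB count matrices for the three layers plus the truth table.

    Returns ``(matrices, truth)`` where ``matrices`` maps layer name to
    a features x samples integer DataFrame ordered as in the design.
    """
    if params.dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    lo, hi = params.lib_factor_range
    if lo <= 0:
        raise ValueError("degenerate library-size factor")
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(design["group"]))
    samples = list(design["sample_id"])
    group_of = dict(zip(design["sample_id"], design["group"]))

    lib = pd.Series(np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples))),
                    index=samples)

    sizes = {"circRNA": params.n_circ, "miRNA": params.n_mir, "mRNA": params.n_mrna}
    ids = {layer: _feature_ids(layer, n) for layer, n in sizes.items()}

    # planted axes use the first features of each layer
    axes = [PlantedAxis(ids["circRNA"][k], ids["miRNA"][k], ids["mRNA"][k],
                        params.effect_size)
            for k in range(params.n_axes)]

    effect_rows = []
    effects = {layer: {} for layer in sizes}
    for k in range(params.n_axes):
        sponge_profile = _alternating_profile(groups, params.effect_size, phase=0)
        mir_profile = _alternating_profile(groups, params.effect_size, phase=1)
        effects["circRNA"][ids["circRNA"][k]] = sponge_profile
        effects["mRNA"][ids["mRNA"][k]] = sponge_profile
        effects["miRNA"][ids["miRNA"][k]] = mir_profile

    # decoy DE features: random group subsets, unrelated to any axis
    for layer, n in sizes.items():
        pool = ids[layer][params.n_axes:]
        n_decoy = int(round(params.decoy_de_fraction * len(pool)))
        chosen = rng.choice(len(pool), size=n_decoy, replace=False)
        for idx in np.sort(chosen):
            up = rng.integers(1, 2 ** len(groups) - 1)  # non-trivial subset mask
            profile = {g: (params.effect_size if (up >> i) & 1 else 0.0)
                       for i, g in enumerate(groups)}
            effects[layer][pool[idx]] = profile

    for layer in sizes:
        for fid, profile in effects[layer].items():
            for g, e in profile.items():
                if e != 0.0:
                    effect_rows.append((layer, fid, g, e))

    baseline_rows = []
    matrices = {}
    for layer, n in sizes.items():
        base = np.exp(rng.uniform(np.log(params.baseline_mean / 3),
                                  np.log(params.baseline_mean * 3), n))
        baseline_rows += [(layer, fid, b) for fid, b in zip(ids[layer], base)]
        eff = np.zeros((n, len(samples)))
        for i, fid in enumerate(ids[layer]):
            profile = effects[layer].get(fid)
            if profile:
                eff[i] = [profile.get(group_of[s], 0.0) for s in samples]
        mu = base[:, None] * 2.0 ** eff * lib.to_numpy()[None, :]
        phi = params.dispersion
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        matrices[layer] = pd.DataFrame(counts, index=ids[layer], columns=samples)

    truth = SyntheticTruth(
        axes=axes,
        effects=pd.DataFrame(effect_rows,
                             columns=["layer", "feature_id", "group", "effect_log2"]),
        feature_ids=ids,
        dispersion=params.dispersion,
        baseline_mean=params.baseline_mean,
        library_sizes=lib,
        baselines=pd.DataFrame(baseline_rows, columns=["layer", "feature_id", "baseline"]),
    )
    return matrices, truth


# ------------------------------------------------------------- sequences

_BASES = "ACGU"


def random_mirna(rng: np.random.Generator, first_u_prob: float = 0.8,
                 length_range: tuple = (20, 24)) -> str:
    """One random miRNA sequence with the observed 5'-U bias."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    first = "U" if rng.random() < first_u_prob else _BASES[rng.integers(0, 3)]
    rest = "".join(_BASES[i] for i in rng.integers(0, 4, length - 1))
    return first + rest


def _gc_count(s: str) -> int:
    return sum(1 for b in s if b in "GC")


def _planted_mirna(rng: np.random.Generator, params: SimulationParams,
                   used_seeds: set) -> str:
    """Planted miRNAs additionally need binding-competent composition:
    >= 3 G/C in the seed (pos 2-8) and in the 3'-supplementary region
    (pos 12-17), and a seed distinct from other planted miRNAs."""
    while True:
        seq = random_mirna(rng, params.mir_first_u_prob, params.mir_length_range)
        seed = seq[1:8]
        if _gc_count(seed) >= 3 and _gc_count(seq[11:17]) >= 3 and seed not in used_seeds:
            used_seeds.add(seed)
            return seq


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _scrub(seq: str, planted_mirs: list[str], rng: np.random.Generator) -> str:
    """Mutate away every 7mer-or-better site for the planted miRNAs."""
    chars = list(seq)
    for _ in range(50):
        dirty = False
        s = "".join(chars)
        for mir in planted_mirs:
            core = revcomp(mir[1:7])
            m8c = COMPLEMENT[mir[7]]
            start = s.find(core)
            while start != -1:
                has_m8 = start > 0 and s[start - 1] == m8c
                has_a1 = start + 6 < len(s) and s[start + 6] == "A"
                if has_m8 or has_a1:
                    pos = start + int(rng.integers(0, 6))
                    old = chars[pos]
                    chars[pos] = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                    dirty = True
                start = s.find(core, start + 1)
        if not dirty:
            return "".join(chars)
    raise RuntimeError("could not scrub planted sites")  # pragma: no cover


def _plant_site(seq: str, mir: str, rng: np.random.Generator) -> str:
    """Overwrite a window of ``seq`` with a full planted site:
    3'-supplementary block (revcomp of miRNA pos 12-17), 2-nt spacer,
    m8 complement, seed 6mer core match, and the A1 adenosine."""
    block = revcomp(mir[11:17])
    spacer = _random_rna(rng, 2)
    site = block + spacer + COMPLEMENT[mir[7]] + revcomp(mir[1:7]) + "A"
    pos = int(rng.integers(30, len(seq) - len(site) - 30))
    return seq[:pos] + site + seq[pos + len(site):]


def simulate_sequences(truth: SyntheticTruth, seed: int,
                       params: SimulationParams | None = None) -> list[SequenceRecord]:
    """Sequences for every feature in the truth table.

    Planted axis partners carry a genuine 8mer + 3'-supplementary site;
    every other sequence is scrubbed of 7mer-or-better sites for the
    planted miRNAs.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    planted_mirs = {ax.mir_id for ax in truth.axes}

    mir_seqs: dict[str, str] = {}
    used_seeds: set = set()
    for mid in truth.feature_ids["miRNA"]:
        if mid in planted_mirs:
            mir_seqs[mid] = _planted_mirna(rng, params, used_seeds)
        else:
            mir_seqs[mid] = random_mirna(rng, params.mir_first_u_prob,
                                         params.mir_length_range)
    planted_list = [mir_seqs[ax.mir_id] for ax in truth.axes]

    partner = {}
    for ax in truth.axes:
        partner[ax.mrna_id] = mir_seqs[ax.mir_id]
        partner[ax.circ_id] = mir_seqs[ax.mir_id]

    records = [SequenceRecord(mid, s, "miRNA") for mid, s in mir_seqs.items()]
    lo_u, hi_u = params.utr_length_range
    for gid in truth.feature_ids["mRNA"]:
        seq = _scrub(_random_rna(rng, int(rng.integers(lo_u, hi_u + 1))),
                     planted_list, rng)
        if gid in partner:
            seq = _plant_site(seq, partner[gid], rng)
        records.append(SequenceRecord(gid, seq, "utr3"))
    lo_c, hi_c = params.circ_length_range
    for cid in truth.feature_ids["circRNA"]:
        length = int(np.exp(rng.uniform(np.log(lo_c), np.log(hi_c))))
        seq = _scrub(_random_rna(rng, length), planted_list, rng)
        if cid in partner:
            seq = _plant_site(seq, partner[cid], rng)
        records.append(SequenceRecord(cid, seq, "circRNA"))
    return records


def permute_layer_samples(matrices: dict, seed: int) -> dict:
    """Independent per-layer permutation of sample columns: the joint
    null for cross-layer inference.

    Each layer's columns are shuffled with its own permutation, which
    destroys both the group alignment of every layer and all
    cross-layer correlation while preserving each layer's marginal
    count distribution.  A triad finder run on these matrices should
    report (almost) nothing.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for layer in sorted(matrices):
        m = matrices[layer]
        perm = rng.permutation(np.asarray(m.columns))
        out[layer] = m[perm].set_axis(m.columns, axis=1)
    return out


# ----------------------------------------------- annotations / PPI decoys


def simulate_annotations(gene_ids: Sequence[str], seed: int, n_terms: int = 20,
                         enriched_genes: Sequence[str] = ()) -> pd.DataFrame:
    """Synthetic term->gene annotation table (GO/KEGG stand-in).

    Random term memberships over the supplied universe; if
    ``enriched_genes`` is given, the first term contains all of them
    (a guaranteed enrichable term for end-to-end runs).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    rows = []
    for t in range(n_terms):
        term = f"TERM_{t + 1:03d}"
        ns = "BP" if t % 2 == 0 else "pathway"
        size = int(rng.integers(10, min(31, len(gene_ids))))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        if t == 0:
            members |= set(enriched_genes)
        for g in sorted(members):
            rows.append((term, f"synthetic term {t + 1}", ns, g))
    return pd.DataFrame(rows, columns=["term_id", "term_name", "namespace", "gene_id"])


def simulate_ppi(gene_ids: Sequence[str], seed: int, n_edges: int = 150) -> pd.DataFrame:
    """Synthetic PPI edge table with uniform confidences."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    rows = set()
    while len(rows) < min(n_edges, len(gene_ids) * (len(gene_ids) - 1) // 2):
        i, j = rng.integers(0, len(gene_ids), 2)
        if i == j:
            continue
        a, b = sorted((gene_ids[i], gene_ids[j]))
        rows.add((a, b))
    conf = rng.uniform(0, 1, len(rows))
    out = pd.DataFrame(sorted(rows), columns=["gene_a", "gene_b"])
    out["confidence"] = np.round(conf, 3)
    return out


# --------------------------------------------------------------- truth IO


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axes = pd.DataFrame([(a.circ_id, a.mir_id, a.mrna_id, a.effect_size)
                         for a in truth.axes],
                        columns=["circ_id", "mir_id", "mrna_id", "effect_size"])
    write_table(axes, out / "axes.tsv")
    write_table(truth.effects, out / "effects.tsv")
    write_table(truth.baselines, out / "baselines.tsv")
    lib = truth.library_sizes.rename("factor").rename_axis("sample_id").reset_index()
    write_table(lib, out / "library_factors.tsv")
    meta = {
        "dispersion": float(truth.dispersion),
        "baseline_mean": float(truth.baseline_mean),
        "feature_ids": {k: list(v) for k, v in truth.feature_ids.items()},
    }
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_truth(in_dir: str | Path) -> SyntheticTruth:
    d = Path(in_dir)
    axes_df = pd.read_csv(d / "axes.tsv", sep="\t")
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    lib = pd.read_csv(d / "library_factors.tsv", sep="\t").set_index("sample_id")["factor"]
    return SyntheticTruth(
        axes=[PlantedAxis(*row) for row in axes_df.itertuples(index=False)],
        effects=pd.read_csv(d / "effects.tsv", sep="\t"),
        feature_ids=meta["feature_ids"],
        dispersion=meta["dispersion"],
        baseline_mean=meta["baseline_mean"],
        library_sizes=lib,
        baselines=pd.read_csv(d / "baselines.tsv", sep="\t"),
    )


def emit_dataset(out_dir: str | Path, design: pd.DataFrame, matrices: dict,
                 sequences: list[SequenceRecord], truth: SyntheticTruth) -> None:
    """Write the full synthetic dataset (design, counts, FASTA, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_design(design, out / "design.tsv")
    for layer, m in matrices.items():
        write_counts(m, out / f"counts_{layer}.tsv")
    for kind in ("miRNA", "utr3", "circRNA"):
        write_fasta([r for r in sequences if r.kind == kind], out / f"{kind}.fasta")
    write_truth(truth, out / "truth")
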