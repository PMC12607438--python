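"""End-to-end pipeline: simulate/load -> DE -> targets -> correlation
network -> core/integration -> enrichment/PPI, with deterministic
artifacts under one run directory and a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import diffexpr, enrichment, network, simulate, targets
from .config import RunConfig, stage_seed
from .io import (edge_frame, read_counts, read_design, read_fasta, read_table,
                 write_network, write_table)

log = logging.getLogger("cernanet")

DEFAULT_CONTRASTS = (("Som", "Stm"), ("Sad", "Ud"))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _load_or_simulate(config: RunConfig, out: Path):
    if config.design_path is not None:
        design = read_design(config.design_path)
        matrices = {layer: read_counts(path, design)
                    for layer, path in config.counts_paths.items()}
        seqs = []
        for kind, path in config.fasta_paths.items():
            seqs.extend(read_fasta(path, kind))
        return design, matrices, seqs, None
    params = simulate.SimulationParams()
    design = simulate.simulate_design(4, 3, stage_seed(config.rng_seed, "design"),
                                      group_names=simulate.DEFAULT_GROUP_NAMES)
    matrices, truth = simulate.simulate_counts(
        design, params, stage_seed(config.rng_seed, "counts"))
    seqs = simulate.simulate_sequences(
        truth, stage_seed(config.rng_seed, "sequences"), params)
    simulate.emit_dataset(out / "data", design, matrices, seqs, truth)
    return design, matrices, seqs, truth


def _contrast_tag(contrast) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written as
    ``summary.json``).  Identical config + seed => byte-identical
    outputs.  Any stage failure raises :class:`StageError` naming the
    stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.rng_seed, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return deco

    @stage("inputs")
    def _inputs():
        return _load_or_simulate(config, out)

    design, matrices, seqs, truth = _inputs
    contrasts = [tuple(c) for c in (config.contrasts or DEFAULT_CONTRASTS)]
    summary["contrasts"] = [list(c) for c in contrasts]

    @stage("de")
    def _de():
        (out / "de").mkdir(exist_ok=True)
        tables = {}
        for contrast in contrasts:
            per_layer = {}
            for layer, m in matrices.items():
                t = diffexpr.call_de(m, design, contrast, layer, config)
                write_table(t, out / "de" / f"{layer}_{_contrast_tag(contrast)}.tsv")
                per_layer[layer] = t
            tables[contrast] = per_layer
        return tables

    de_tables = _de
    for contrast in contrasts:
        summary["stages"][f"de_{_contrast_tag(contrast)}"] = {
            layer: int((t["call"] != "ns").sum())
            for layer, t in de_tables[contrast].items()
        }

    @stage("targets")
    def _targets():
        (out / "targets").mkdir(exist_ok=True)
        mirnas = [s for s in seqs if s.kind == "miRNA"]
        tgts = [s for s in seqs if s.kind in ("utr3", "circRNA")]
        pairs = targets.pairs_frame(targets.predict_pairs(mirnas, tgts, config))
        write_table(pairs, out / "targets" / "pairs.tsv")
        return pairs

    pairs = _targets
    summary["stages"]["target_pairs"] = int(len(pairs))

    triads_by_comparison = {}
    for contrast in contrasts:
        tag = _contrast_tag(contrast)

        @stage(f"network_{tag}")
        def _net(contrast=contrast, tag=tag):
            cdir = out / "correlations" / tag
            cdir.mkdir(parents=True, exist_ok=True)
            circ_mir, mir_mrna, circ_mrna = network.build_pairs(
                de_tables[contrast], pairs, matrices, design, contrast, config)
            write_table(circ_mir, cdir / "circ_mir.tsv")
            write_table(mir_mrna, cdir / "mir_mrna.tsv")
            write_table(circ_mrna, cdir / "circ_mrna.tsv")
            triads = network.assemble_triads(circ_mir, mir_mrna, circ_mrna)
            ndir = out / "network" / tag
            ndir.mkdir(parents=True, exist_ok=True)
            write_table(triads, ndir / "triads.tsv")
            edges = edge_frame(
                [(r.circ_id, "circRNA", r.mir_id, "miRNA")
                 for r in triads.itertuples(index=False)]
                + [(r.mir_id, "miRNA", r.mrna_id, "mRNA")
                   for r in triads.itertuples(index=False)]
            ).drop_duplicates()
            write_network(edges, ndir / "network.sif", "sif")
            write_network(edges, ndir / "network.tsv", "tsv")
            return triads

        triads = _net
        triads_by_comparison[tag] = triads
        summary["stages"][f"triads_{tag}"] = int(len(triads))

    whitelist = None
    if config.whitelist_path:
        whitelist = set(read_table(config.whitelist_path)["gene_id"])

    if len(contrasts) >= 2:
        @stage("core")
        def _core():
            core = network.select_core(triads_by_comparison, config.top_k_mirnas)
            cdir = out / "network" / "core"
            cdir.mkdir(parents=True, exist_ok=True)
            write_table(core.triads, cdir / "core_triads.tsv")
            tags = list(triads_by_comparison)
            half = {t: network.CoreNetwork(
                core.mirnas,
                core.triads[core.triads["comparison"] == t],
                {t: core.top_by_comparison[t]}) for t in tags}
            wl = whitelist if whitelist is not None else set(
                pd.concat([t["mrna_id"] for t in triads_by_comparison.values()],
                          ignore_index=True)) if triads_by_comparison else set()
            triples, ipairs = network.integrate_networks(half[tags[0]], half[tags[1]], wl)
            write_table(triples, cdir / "integrated_triples.tsv")
            write_network(ipairs, cdir / "integrated.sif", "sif")
            return core, triples, ipairs

        core, triples, ipairs = _core
        summary["stages"]["core_mirnas"] = len(core.mirnas)
        summary["stages"]["integrated_triples"] = int(len(triples))
        summary["stages"]["integrated_pairs"] = int(len(ipairs))

    if config.annotation_path:
        @stage("enrichment")
        def _enrich():
            ann = enrichment.validate_annotation(read_table(config.annotation_path))
            genes = set()
            for t in triads_by_comparison.values():
                genes |= set(t["mrna_id"])
            genes &= set(ann["gene_id"])
            edir = out / "enrichment"
            edir.mkdir(exist_ok=True)
            if genes:
                enr = enrichment.hypergeom_enrich(genes, ann)
                write_table(enr, edir / "enrichment.tsv")
                write_table(enrichment.pathway_gene_table(enr, ann, genes),
                            edir / "pathway_genes.tsv")
            else:
                enr = pd.DataFrame(columns=enrichment.ENRICH_COLS)
                write_table(enr, edir / "enrichment.tsv")
            return enr

        summary["stages"]["enriched_terms"] = int(len(_enrich))

    if config.ppi_path:
        @stage("ppi")
        def _ppi():
            edges = read_table(config.ppi_path)
            kept, hubs = enrichment.ppi_filter_and_hubs(edges, config.ppi_conf_min)
            pdir = out / "ppi"
            pdir.mkdir(exist_ok=True)
            write_table(kept, pdir / "edges.tsv")
            write_table(hubs, pdir / "hubs.tsv")
            return kept, hubs

        kept, hubs = _ppi
        summary["stages"]["ppi_edges"] = int(len(kept))
        summary["stages"]["ppi_hubs"] = list(hubs["gene"])

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
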