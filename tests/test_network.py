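import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernanet import diffexpr
from cernanet.config import RunConfig
from cernanet.network import (CoreNetwork, TRIAD_COLS, assemble_triads,
                              build_pairs, dem_deg_network, integrate_networks,
                              log_cpm_profiles, mirna_degrees, pearson,
                              select_core)
from cernanet.simulate import permute_layer_samples
from cernanet.targets import pairs_frame, predict_pairs


def _edges(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p", "n"])


def _triads(rows):
    return pd.DataFrame(
        [(c, m, g, -0.9, 0.01, -0.9, 0.01, 0.9, 0.01) for c, m, g in rows],
        columns=TRIAD_COLS)


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p, n = pearson([1, 2, 3], [6, 4, 2])
        assert r == -1.0
        assert p == np.finfo(float).tiny
        assert n == 3

    def test_hand_computed_value(self):
        r, p, n = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        # p from t = r sqrt((n-2)/(1-r^2)) on 2 df, vs reference t tail
        t = 0.6 * np.sqrt(2 / 0.64)
        assert p == pytest.approx(2 * stats.t.sf(t, 2))

    def test_matches_scipy_reference(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r, p, n = pearson(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_explicit_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_short_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson([1, 2, np.nan], [3, 4, 5])


class TestAssembleTriads:
    def test_single_complete_triad(self):
        tri = assemble_triads(
            _edges([("c1", "m1", -0.9, 0.01, 6)]),
            _edges([("m1", "g1", -0.8, 0.02, 6)]),
            _edges([("c1", "g1", 0.85, 0.01, 6)]))
        assert len(tri) == 1
        row = tri.iloc[0]
        assert (row.circ_id, row.mir_id, row.mrna_id) == ("c1", "m1", "g1")
        assert row.r_mir_mrna == -0.8

    def test_missing_positive_edge_blocks_triad(self):
        tri = assemble_triads(
            _edges([("c1", "m1", -0.9, 0.01, 6)]),
            _edges([("m1", "g1", -0.8, 0.02, 6)]),
            _edges([]))
        assert tri.empty

    def test_matches_brute_force_triple_loop(self, rng):
        circ = [f"c{i}" for i in range(5)]
        mirs = [f"m{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(5)]
        cm = _edges([(c, m, -0.9, 0.01, 6) for c in circ for m in mirs
                     if rng.random() < 0.4])
        mg = _edges([(m, g, -0.9, 0.01, 6) for m in mirs for g in genes
                     if rng.random() < 0.4])
        cg = _edges([(c, g, 0.9, 0.01, 6) for c in circ for g in genes
                     if rng.random() < 0.4])
        got = {(r.circ_id, r.mir_id, r.mrna_id)
               for r in assemble_triads(cm, mg, cg).itertuples(index=False)}
        cm_set = {(a, b) for a, b in cm[["node_a", "node_b"]].itertuples(index=False)}
        mg_set = {(a, b) for a, b in mg[["node_a", "node_b"]].itertuples(index=False)}
        cg_set = {(a, b) for a, b in cg[["node_a", "node_b"]].itertuples(index=False)}
        expected = {(c, m, g) for c in circ for m in mirs for g in genes
                    if (c, m) in cm_set and (m, g) in mg_set and (c, g) in cg_set}
        assert got == expected


@pytest.fixture(scope="module")
def pipeline_state(dataset, design, config):
    matrices, truth, sequences = dataset
    de = {layer: diffexpr.call_de(matrices[layer], design, ("Sad", "Ud"),
                                  layer, config)
          for layer in matrices}
    mirnas = [s for s in sequences if s.kind == "miRNA"]
    targets = [s for s in sequences if s.kind != "miRNA"]
    pairs = pairs_frame(predict_pairs(mirnas, targets, config))
    return matrices, truth, de, pairs


class TestBuildPairs:
    def test_planted_axis_survives_all_three_filters(self, pipeline_state,
                                                     design, config):
        matrices, truth, de, pairs = pipeline_state
        cm, mg, cg = build_pairs(de, pairs, matrices, design, ("Sad", "Ud"), config)
        tri = assemble_triads(cm, mg, cg)
        found = {(r.circ_id, r.mir_id, r.mrna_id)
                 for r in tri.itertuples(index=False)}
        recall = len(found & truth.axis_triples()) / len(truth.axes)
        assert recall >= 0.75

    def test_unattainable_negative_threshold_gives_no_edges(self, pipeline_state,
                                                            design, config):
        matrices, _, de, pairs = pipeline_state
        cfg = RunConfig(**(config.__dict__ | {"r_neg_max": -1.01}))
        cm, mg, _ = build_pairs(de, pairs, matrices, design, ("Sad", "Ud"), cfg)
        assert cm.empty and mg.empty

    def test_sign_constraints_hold(self, pipeline_state, design, config):
        matrices, _, de, pairs = pipeline_state
        cm, mg, cg = build_pairs(de, pairs, matrices, design, ("Sad", "Ud"), config)
        assert (cm["r"] <= config.r_neg_max).all()
        assert (mg["r"] <= config.r_neg_max).all()
        assert (cg["r"] >= config.r_pos_min).all()
        for df in (cm, mg, cg):
            assert (df["p"] <= config.corr_p_max).all()

    def test_permuted_samples_give_near_null_edge_rate(self, pipeline_state,
                                                       design):
        """After independent per-layer sample permutation, candidate
        pairs pass p <= 0.05 at roughly the nominal rate."""
        matrices, _, de, pairs = pipeline_state
        hits = trials = 0
        for seed in range(8):
            permuted = permute_layer_samples(matrices, seed)
            samples = [s for s in design["sample_id"]
                       if design.set_index("sample_id").loc[s, "group"]
                       in ("Sad", "Ud")]
            prof = {layer: log_cpm_profiles(m, samples)
                    for layer, m in permuted.items()}
            for row in pairs.itertuples(index=False):
                layer = "circRNA" if row.target_kind == "circRNA" else "mRNA"
                x = prof["miRNA"].loc[row.mirna_id].to_numpy()
                y = prof[layer].loc[row.target_id].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                trials += 1
                hits += pearson(x, y)[1] <= 0.05
        assert trials > 200
        assert hits / trials <= 0.085  # nominal 0.05 plus sampling noise


class TestDemDegNetwork:
    def test_whitelist_none_is_unrestricted(self, dataset, design, config):
        matrices, truth, sequences = dataset
        de_mir = diffexpr.call_de(matrices["miRNA"], design, ("Sad", "Ud"),
                                  "miRNA", config)
        de_gene = diffexpr.call_de(matrices["mRNA"], design, ("Sad", "Ud"),
                                   "mRNA", config)
        mirnas = [s for s in sequences if s.kind == "miRNA"]
        utrs = [s for s in sequences if s.kind == "utr3"]
        pairs = pairs_frame(predict_pairs(mirnas, utrs, config))
        full = dem_deg_network(de_mir, de_gene, pairs, matrices, design,
                               ("Sad", "Ud"), config)
        assert len(full) > 0
        none_left = dem_deg_network(de_mir, de_gene, pairs, matrices, design,
                                    ("Sad", "Ud"), config, gene_whitelist=set())
        assert none_left.empty
        subset = dem_deg_network(de_mir, de_gene, pairs, matrices, design,
                                 ("Sad", "Ud"), config,
                                 gene_whitelist=set(full["node_b"][:1]))
        assert set(subset["node_b"]) <= set(full["node_b"][:1])


class TestSelectCore:
    def test_hand_ranked_toy(self):
        t = _triads([("c1", "miR-A", f"g{i}") for i in range(4)]
                    + [("c2", "miR-A", "g0")]
                    + [("c3", "miR-B", "g1"), ("c4", "miR-B", "g2")])
        assert mirna_degrees(t)["miR-A"] == 6  # 2 sponge + 4 target pairs
        core = select_core({"A": t, "B": t}, k=1)
        assert core.mirnas == ["miR-A"]
        assert set(core.triads["mir_id"]) == {"miR-A"}

    def test_identical_comparisons_are_idempotent(self):
        t = _triads([("c1", "m1", "g1"), ("c2", "m2", "g2")])
        core = select_core({"A": t, "B": t}, k=10)
        assert core.mirnas == ["m1", "m2"]

    def test_disjoint_topk_gives_empty_core(self):
        ta = _triads([("c1", "m1", "g1")])
        tb = _triads([("c2", "m2", "g2")])
        core = select_core({"A": ta, "B": tb}, k=10)
        assert core.mirnas == [] and core.triads.empty

    def test_invalid_k_and_single_comparison(self):
        t = _triads([("c1", "m1", "g1")])
        with pytest.raises(ValueError):
            select_core({"A": t, "B": t}, k=0)
        with pytest.raises(ValueError):
            select_core({"A": t}, k=5)

    def test_matches_set_algebra_brute_force(self, rng):
        for _ in range(10):
            tri = {}
            for name in ("A", "B"):
                rows = {(f"c{rng.integers(8)}", f"m{rng.integers(8)}",
                         f"g{rng.integers(8)}") for _ in range(15)}
                tri[name] = _triads(sorted(rows))
            k = int(rng.integers(1, 5))
            core = select_core(tri, k=k)
            expected_core = None
            for t in tri.values():
                deg = {}
                for c, m, g in {(r.circ_id, r.mir_id, r.mrna_id)
                                for r in t.itertuples(index=False)}:
                    pass
                sponge = {(r.circ_id, r.mir_id) for r in t.itertuples(index=False)}
                target = {(r.mir_id, r.mrna_id) for r in t.itertuples(index=False)}
                for _, m in sponge:
                    deg[m] = deg.get(m, 0) + 1
                for m, _ in target:
                    deg[m] = deg.get(m, 0) + 1
                top = set(sorted(deg, key=lambda m: (-deg[m], m))[:k])
                expected_core = top if expected_core is None else expected_core & top
            assert set(core.mirnas) == expected_core


class TestIntegrateNetworks:
    def _core(self, rows):
        t = _triads(rows)
        t["comparison"] = "x"
        return CoreNetwork(sorted(set(t["mir_id"])), t, {})

    def test_single_shared_triad_two_pairs(self):
        a = self._core([("c1", "m1", "g1"), ("c2", "m2", "g2")])
        b = self._core([("c1", "m1", "g1"), ("c3", "m3", "g3")])
        triples, pairs = integrate_networks(a, b, {"g1", "g2", "g3"})
        assert len(triples) == 1
        assert len(pairs) == 2
        assert set(pairs["relation"]) == {"sponges", "targets"}

    def test_empty_whitelist_gives_empty_integration(self):
        a = self._core([("c1", "m1", "g1")])
        triples, pairs = integrate_networks(a, a, set())
        assert triples.empty and pairs.empty

    def test_matches_set_algebra_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        wl = set(genes[:3])
        rows_a = sorted({(f"c{rng.integers(6)}", f"m{rng.integers(6)}",
                          genes[rng.integers(6)]) for _ in range(12)})
        rows_b = sorted({(f"c{rng.integers(6)}", f"m{rng.integers(6)}",
                          genes[rng.integers(6)]) for _ in range(12)})
        triples, pairs = integrate_networks(self._core(rows_a),
                                            self._core(rows_b), wl)
        keys_a = {(m, g) for _, m, g in rows_a if g in wl}
        keys_b = {(m, g) for _, m, g in rows_b if g in wl}
        shared = keys_a & keys_b
        expected = {(c, m, g) for c, m, g in rows_a + rows_b if (m, g) in shared}
        got = {(r.circ_id, r.mir_id, r.mrna_id)
               for r in triples.itertuples(index=False)}
        assert got == expected
        expected_pairs = ({(c, m) for c, m, _ in expected}
                          | {(m, g) for _, m, g in expected})
        assert len(pairs) == len(expected_pairs)
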