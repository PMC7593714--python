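import dataclasses

import networkx as nx
import numpy as np
import pytest

from herbnet.errors import ConfigurationError
from herbnet.synthetic import (
    SimConfig,
    gen_component_table,
    gen_expression_matrix,
    gen_geneset_db,
    gen_ppi_with_planted_hubs,
    gen_target_universe,
    write_bundle,
)


class TestComponentTable:
    def test_size_and_determinism(self):
        cfg = SimConfig(seed=1, n_components=20, ob_range=(10, 60), dl_range=(0, 0.5))
        a, b = gen_component_table(cfg), gen_component_table(cfg)
        assert len(a) == 20
        assert a == b

    def test_degenerate_interval(self):
        cfg = SimConfig(seed=1, ob_range=(40, 40))
        assert all(c.ob == 40 for c in gen_component_table(cfg))

    def test_straddling_ranges_populate_both_sides(self):
        cfg = SimConfig(seed=3)
        comps = gen_component_table(cfg)
        assert any(c.ob > 30 for c in comps) and any(c.ob <= 30 for c in comps)
        assert any(c.dl > 0.18 for c in comps) and any(c.dl <= 0.18 for c in comps)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_component_table(SimConfig(ob_range=(60, 10)))


class TestTargetUniverse:
    @pytest.mark.parametrize("frac, expected", [(0.0, 0), (1.0, None), (0.3, None)])
    def test_overlap_is_exact(self, frac, expected):
        cfg = SimConfig(seed=2, overlap_fraction=frac, n_disease_targets=10)
        mapping, disease, _ = gen_target_universe(cfg)
        comp_targets = set().union(*mapping.values())
        want = expected if expected is not None else round(frac * len(disease))
        assert len(comp_targets & set(disease)) == want

    def test_symbols_uppercase_and_deterministic(self):
        cfg = SimConfig(seed=5)
        m1, d1, u1 = gen_target_universe(cfg)
        m2, d2, _ = gen_target_universe(cfg)
        assert (m1, d1) == (m2, d2)
        assert all(g == g.upper() for g in d1)

    def test_infeasible_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_target_universe(SimConfig(n_background_genes=5, n_disease_targets=10))

    def test_external_disease_list_is_respected(self):
        ext = ["tnf", "IL4", "MMP2", "STAT6"] * 3
        cfg = SimConfig(seed=1, overlap_fraction=0.5)
        mapping, disease, universe = gen_target_universe(cfg, disease_symbols=ext)
        assert disease == ["TNF", "IL4", "MMP2", "STAT6"] or set(disease) == {
            "TNF",
            "IL4",
            "MMP2",
            "STAT6",
        }
        assert set(disease) <= set(universe)


class TestPlantedGraph:
    def test_clique_present_and_graph_simple(self):
        g, truth = gen_ppi_with_planted_hubs(SimConfig(seed=4))
        hubs = sorted(truth.planted_hub_ids)
        assert len(hubs) == 5
        for i, a in enumerate(hubs):
            for b in hubs[i + 1 :]:
                assert g.has_edge(a, b)
        assert nx.number_of_selfloops(g) == 0

    def test_planted_degree_exceeds_twice_global_median(self):
        g, truth = gen_ppi_with_planted_hubs(SimConfig(seed=8))
        degs = dict(g.degree())
        med = float(np.median(list(degs.values())))
        for h in truth.planted_hub_ids:
            assert degs[h] > 2 * med

    def test_deterministic_edge_set(self):
        cfg = SimConfig(seed=6)
        g1, _ = gen_ppi_with_planted_hubs(cfg)
        g2, _ = gen_ppi_with_planted_hubs(cfg)
        assert set(g1.edges()) == set(g2.edges())

    def test_alternative_background_models(self):
        for model in ("er", "pa"):
            g, truth = gen_ppi_with_planted_hubs(
                SimConfig(seed=1, background_model=model)
            )
            assert truth.planted_hub_ids <= set(g.nodes())

    def test_too_small_module_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_ppi_with_planted_hubs(SimConfig(hub_module_size=2))


class TestGenesetDb:
    def test_planted_term_count_and_hub_share(self):
        cfg = SimConfig(seed=3, n_planted_terms=3)
        hubs = {f"H{i}" for i in range(20)}
        db, truth = gen_geneset_db(cfg, hubs)
        assert len(truth.planted_term_ids) == 3
        for s in db:
            if s.term_id in truth.planted_term_ids:
                share = len(s.members & hubs) / len(s.members)
                assert share >= 0.8

    def test_no_random_terms(self):
        cfg = SimConfig(seed=1, n_terms=0, n_planted_terms=1)
        db, truth = gen_geneset_db(cfg, {"H1", "H2", "H3", "H4", "H5"})
        assert len(db) == 1 and len(truth.planted_term_ids) == 1

    def test_categories_cycle_over_vocabulary(self):
        db, _ = gen_geneset_db(SimConfig(seed=1, n_terms=8), {"H1"})
        assert [s.category for s in db[:8]] == ["BP", "MF", "CC", "KEGG"] * 2

    def test_oversized_terms_rejected(self):
        cfg = SimConfig(seed=1, n_background_genes=20, n_disease_targets=5,
                        term_size_range=(30, 40))
        with pytest.raises(ConfigurationError):
            gen_geneset_db(cfg, {"H1"})


class TestExpressionMatrix:
    def test_planted_shift_structure(self):
        cfg = SimConfig(seed=10, n_genes=50, n_per_group=50, effect_log2=3.0, noise_sd=0.3)
        m, groups, truth = gen_expression_matrix(cfg)
        ctrl = m.loc[:, groups == "control"].mean(axis=1)
        case = m.loc[:, groups == "case"].mean(axis=1)
        diff = case - ctrl
        for g in truth.planted_up:
            assert diff[g] == pytest.approx(3.0, abs=0.5)
        for g in truth.planted_down:
            assert diff[g] == pytest.approx(-3.0, abs=0.5)
        null = diff.drop(list(truth.planted_up | truth.planted_down))
        assert abs(null.mean()) < 0.2

    def test_up_down_sets_disjoint_and_in_universe(self):
        m, _, truth = gen_expression_matrix(SimConfig(seed=2))
        assert not (truth.planted_up & truth.planted_down)
        assert (truth.planted_up | truth.planted_down) <= set(m.index)

    def test_determinism_and_group_sizes(self):
        cfg = SimConfig(seed=12)
        m1, g1, _ = gen_expression_matrix(cfg)
        m2, _, _ = gen_expression_matrix(cfg)
        assert m1.equals(m2)
        assert (g1 == "control").sum() == (g1 == "case").sum() == cfg.n_per_group

    def test_tiny_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_expression_matrix(SimConfig(n_per_group=1))


class TestBundle:
    def test_bundle_files_and_truth_subsets(self, tmp_path):
        cfg = SimConfig(seed=7)
        truth = write_bundle(cfg, tmp_path)
        for name in (
            "components.tsv",
            "targets.tsv",
            "disease.tsv",
            "network.sif",
            "genesets.gmt",
            "expression.tsv",
            "groups.tsv",
            "truth.json",
        ):
            assert (tmp_path / name).exists(), name
        assert truth.planted_hub_ids and truth.planted_term_ids

    def test_bundle_bitwise_determinism(self, tmp_path):
        cfg = SimConfig(seed=7)
        write_bundle(cfg, tmp_path / "a")
        write_bundle(cfg, tmp_path / "b")
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes(), p.name
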