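import json
import math

import numpy as np
import pytest

from phylocongruence import (
    dcov_test,
    environment_distance,
    jc69,
    p_distance,
    robinson_foulds,
    select_abc,
    select_erm,
    subset_with_both,
)
from phylocongruence.errors import SimulationError
from phylocongruence.io_formats import leaf_labels
from phylocongruence.njtree import path_length_matrix
from phylocongruence.simulate import (
    SimulationConfig,
    _joint_bernoulli_probs,
    apply_hgt,
    emit_hit_tables,
    evolve_alignment,
    simulate_dataset,
    simulate_environment,
    simulate_presence,
    simulate_species_tree,
    tree_height,
)
from phylocongruence.io_formats import read_newick


class TestSpeciesTree:
    def test_reproducible_and_right_size(self):
        cfg = SimulationConfig(n_taxa=8, seed=42)
        t1, t2 = simulate_species_tree(cfg), simulate_species_tree(cfg)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        for seed in range(20):
            t = simulate_species_tree(SimulationConfig(n_taxa=9, seed=seed))
            assert len(leaf_labels(t)) == 9

    def test_ultrametric(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=12, seed=3))
        plm = path_length_matrix(t)
        h = tree_height(t)
        # every leaf is at the same depth: all root-to-leaf distances equal
        depths = {
            round(sum(nd.edge.length for nd in lf.ancestor_iter(inclusive=False)
                      if nd.edge.length) + lf.edge.length, 9)
            for lf in t.leaf_node_iter()
        }
        assert len(depths) == 1
        assert depths.pop() == pytest.approx(h, abs=1e-9)

    def test_mean_height_matches_yule_expectation(self):
        """E[height] = sum_{k=2..n} 1/(k * birth_rate) for a Yule tree."""
        n, reps = 6, 2000
        cfg = SimulationConfig(n_taxa=n, birth_rate=1.0)
        heights = [
            tree_height(simulate_species_tree(cfg, seed=s)) for s in range(reps)
        ]
        expected = sum(1.0 / k for k in range(2, n + 1))
        se = np.std(heights) / math.sqrt(reps)
        assert abs(np.mean(heights) - expected) < 3 * se


class TestHgt:
    def test_zero_events_identity(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=10, seed=1))
        assert robinson_foulds(t, apply_hgt(t, 0, seed=9)) == 0

    def test_one_event_usually_changes_topology(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=10, seed=1))
        changed = sum(
            robinson_foulds(t, apply_hgt(t, 1, seed=s)) > 0 for s in range(100)
        )
        assert changed >= 95

    def test_mean_rf_non_decreasing_in_events(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=10, seed=1))
        means = []
        for h in (0, 1, 2, 5, 10):
            means.append(
                np.mean([robinson_foulds(t, apply_hgt(t, h, seed=s)) for s in range(100)])
            )
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_gene_tree_stays_ultrametric(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=12, seed=5))
        g = apply_hgt(t, 4, seed=8)
        depths = set()
        for lf in g.leaf_node_iter():
            d = lf.edge.length + sum(
                nd.edge.length
                for nd in lf.ancestor_iter(inclusive=False)
                if nd.edge.length
            )
            depths.add(round(d, 9))
        assert len(depths) == 1

    def test_too_few_taxa(self):
        t = read_newick("(a:1,b:1);")
        with pytest.raises(SimulationError):
            apply_hgt(t, 1, seed=0)


class TestEvolve:
    def test_zero_distance_identical_states(self):
        t = read_newick("(a:0.0,b:0.0);")
        aln = evolve_alignment(t, "JC69", 50, seed=0)
        assert aln.rows[0] == aln.rows[1]

    def test_jc69_closed_form_transition(self):
        """Observed p at path distance 0.2 matches (3/4)(1 - e^{-4d/3})."""
        t = read_newick("(a:0.1,b:0.1);")
        aln = evolve_alignment(t, "JC69", 100_000, seed=7)
        p_hat = p_distance(aln).values[0, 1]
        p_true = 0.75 * (1 - math.exp(-4 * 0.2 / 3))
        sd = math.sqrt(p_true * (1 - p_true) / 100_000)
        assert abs(p_hat - p_true) < 3 * sd

    def test_jc_estimates_track_true_path_lengths(self):
        tree = simulate_species_tree(SimulationConfig(n_taxa=10, seed=2))
        aln = evolve_alignment(tree, "JC69", 2000, seed=3, rate=0.05)
        D = jc69(aln)
        truth = path_length_matrix(tree).submatrix(D.labels)
        iu = np.triu_indices(10, k=1)
        r = np.corrcoef(D.values[iu], 0.05 * truth.values[iu])[0, 1]
        assert r >= 0.95

    def test_determinism(self):
        t = simulate_species_tree(SimulationConfig(n_taxa=6, seed=4))
        a1 = evolve_alignment(t, "JTT", 100, seed=9)
        a2 = evolve_alignment(t, "JTT", 100, seed=9)
        assert a1.rows == a2.rows


class TestEnvironment:
    def test_fixed_seed_identical_table(self):
        cfg = SimulationConfig(n_taxa=10, seed=6)
        t = simulate_species_tree(cfg, seed=6)
        df1 = simulate_environment(t, cfg, seed=2)
        df2 = simulate_environment(t, cfg, seed=2)
        assert df1.equals(df2)

    def test_strong_signal_recovered_by_dcov(self):
        """With BM scale >> noise, 16S and environment distances correlate."""
        ps = []
        for s in range(20):
            cfg = SimulationConfig(n_taxa=20, env_bm_sigma=2.0, env_noise_sd=0.05, seed=s)
            tree = simulate_species_tree(cfg, seed=s)
            aln = evolve_alignment(tree, "JC69", 750, s + 1000, rate=cfg.marker_rate)
            D = jc69(aln)
            meta = simulate_environment(tree, cfg, seed=s + 2000)
            meta = meta.set_index("strain").loc[list(D.labels)].reset_index()
            E = environment_distance(meta, ["pH", "organic_matter"])
            ps.append(dcov_test(D, E, n_perm=199, seed=s).p)
        assert np.median(ps) <= 0.05

    def test_no_bm_signal_null_behaved(self):
        """Pure-noise covariates: dependence on 16S should not be detected
        more often than nominal (checked loosely over 20 seeds)."""
        rejections = 0
        for s in range(20):
            cfg = SimulationConfig(n_taxa=15, env_bm_sigma=0.0, env_noise_sd=1.0, seed=s)
            tree = simulate_species_tree(cfg, seed=s)
            aln = evolve_alignment(tree, "JC69", 500, s + 500, rate=cfg.marker_rate)
            D = jc69(aln)
            meta = simulate_environment(tree, cfg, seed=s + 900)
            meta = meta.set_index("strain").loc[list(D.labels)].reset_index()
            E = environment_distance(meta, ["pH", "organic_matter"])
            rejections += dcov_test(D, E, n_perm=199, seed=s).p <= 0.05
        assert rejections <= 4


class TestPresence:
    def test_zero_logodds_calibrated(self):
        cfg = SimulationConfig(
            n_taxa=10_000, presence_prob=(0.3, 0.4), co_occurrence_logodds=0.0
        )
        _, tab = simulate_presence(cfg, seed=2)
        (a, b), (c, d) = tab
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or) < 3 * se

    def test_infinite_logodds_equal_marginals_always_together(self):
        cfg = SimulationConfig(
            n_taxa=500, presence_prob=(0.3, 0.3), co_occurrence_logodds=math.inf
        )
        df, tab = simulate_presence(cfg, seed=3)
        assert tab[0][1] == 0 and tab[1][0] == 0

    def test_fixed_seed_identical(self):
        cfg = SimulationConfig(n_taxa=50, seed=8)
        df1, t1 = simulate_presence(cfg, seed=5)
        df2, t2 = simulate_presence(cfg, seed=5)
        assert df1.equals(df2) and t1 == t2

    def test_target_odds_ratio_solution(self):
        p = _joint_bernoulli_probs(0.3, 0.4, 1.5)
        p11, p10, p01, p00 = p
        assert math.log(p11 * p00 / (p10 * p01)) == pytest.approx(1.5, abs=1e-9)
        assert p11 + p10 == pytest.approx(0.3)
        assert p11 + p01 == pytest.approx(0.4)


class TestHitTables:
    def test_curation_round_trip_no_decoys(self):
        cfg = SimulationConfig(n_taxa=80, seed=10, decoy_subthreshold=0, decoy_ksga=0)
        pres, _ = simulate_presence(cfg, seed=4)
        erm_hits, abc_hits, nbrs, ledger = emit_hit_tables(cfg, pres, seed=5)
        sel_e = select_erm(erm_hits, nbrs)
        sel_a = select_abc(abc_hits)
        assert sorted(sel_e["genome"]) == ledger["erm_expected_genomes"]
        assert sorted(sel_a["genome"]) == ledger["abc_expected_genomes"]

    def test_decoys_do_not_change_selection(self):
        cfg = SimulationConfig(n_taxa=80, seed=10, decoy_subthreshold=5, decoy_ksga=5)
        pres, _ = simulate_presence(cfg, seed=4)
        erm_hits, abc_hits, nbrs, ledger = emit_hit_tables(cfg, pres, seed=5)
        sel_e = select_erm(erm_hits, nbrs)
        assert sorted(sel_e["genome"]) == ledger["erm_expected_genomes"]
        assert sorted(sel_e["subject_id"]) == ledger["erm_expected_subjects"]
        sel_a = select_abc(abc_hits)
        best = dict(zip(sel_a["genome"], sel_a["subject_id"]))
        assert best == ledger["abc_expected_best"]

    def test_intersection_matches_ledger(self):
        cfg = SimulationConfig(n_taxa=60, seed=11, co_occurrence_logodds=math.log(5))
        pres, _ = simulate_presence(cfg, seed=6)
        erm_hits, abc_hits, nbrs, ledger = emit_hit_tables(cfg, pres, seed=7)
        both = subset_with_both(select_erm(erm_hits, nbrs), select_abc(abc_hits))
        assert sorted(both) == ledger["both_expected_genomes"]

    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_taxa=20, seed=12)
        pres, _ = simulate_presence(cfg, seed=1)
        for run in ("a", "b"):
            erm_hits, _, _, _ = emit_hit_tables(cfg, pres, seed=2)
            erm_hits.to_csv(tmp_path / f"{run}.tsv", sep="\t", index=False)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestDataset:
    def test_whole_dataset_deterministic_on_disk(self, tmp_path):
        cfg = SimulationConfig(n_taxa=10, seed=21)
        for run in ("x", "y"):
            simulate_dataset(cfg).write(tmp_path / run)
        for f in sorted((tmp_path / "x").iterdir()):
            assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes(), f.name

    def test_ledger_counts_verifiable(self, tmp_path):
        cfg = SimulationConfig(n_taxa=30, seed=22, n_missing_housekeeping=4)
        ds = simulate_dataset(cfg)
        assert ds.ledger["n_mls_retained"] == 30 - 4
        (a, bb), (c, d) = ds.ledger["true_presence_table"]
        assert a + bb + c + d == 30
        assert a + bb == int(ds.presence["erm"].sum())
        ds.write(tmp_path)
        ledger = json.loads((tmp_path / "ledger.json").read_text())
        assert ledger["n_mls_retained"] == 26
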