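import numpy as np
import pytest

import chromstate.simulate as sim
from chromstate.constants import MISSING
from chromstate.genome import BinnedGenome


@pytest.fixture(scope="module")
def genome():
    return BinnedGenome([("chr1", 2_000_000), ("chr2", 2_000_000)])


class TestGroundTruthModel:
    def test_two_state_one_mark_full_separation_is_exact(self):
        m = sim.generate_ground_truth_model(2, ["m1"], 1.0, 0.9, seed=3)
        rows = sorted(m.emissions.ravel().tolist())
        assert rows == [0.0, 1.0]

    def test_transition_construction(self):
        m = sim.generate_ground_truth_model(
            5, [f"m{i}" for i in range(10)], 0.3, 0.95, seed=7
        )
        assert np.allclose(m.transitions.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(np.diag(m.transitions), 0.95)
        off = m.transitions[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.05 / 4)
        assert np.allclose(m.initial, 0.2)

    def test_pairwise_l1_separation_brute_force(self):
        m = sim.generate_ground_truth_model(
            18, [f"m{i}" for i in range(10)], 0.3, 0.95, seed=1
        )
        E = m.emissions
        for i in range(18):
            for j in range(i + 1, 18):
                assert np.abs(E[i] - E[j]).sum() >= 3.0 - 1e-9

    def test_infeasible_separation_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sim.generate_ground_truth_model(3, ["m1"], 1.0, 0.9, seed=0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sim.generate_ground_truth_model(1, ["m1"], 0.5, 0.9)
        with pytest.raises(ValueError):
            sim.generate_ground_truth_model(2, ["m1"], 0.5, 1.0)


class TestStatePaths:
    def test_absorbing_diagonal_gives_constant_path(self, genome):
        m = sim.GroundTruthModel(
            ["m1"], np.array([0.3, 0.7]), np.eye(2), np.array([[0.1], [0.9]])
        )
        paths = sim.simulate_state_paths(m, genome, 3, seed=5)
        for per in paths.values():
            for arr in per.values():
                assert (arr == arr[0]).all()

    def test_symmetric_two_state_frequency(self, genome):
        m = sim.GroundTruthModel(
            ["m1"], np.array([0.5, 0.5]), np.full((2, 2), 0.5),
            np.array([[0.1], [0.9]]),
        )
        paths = sim.simulate_state_paths(m, genome, 1, seed=2)
        flat = np.concatenate([paths["sample1"][c] for c in genome.chrom_names])
        assert len(flat) >= 100_000 * 0.2
        assert abs(flat.mean() - 0.5) < 0.01

    def test_seed_determinism(self, default_model, genome):
        a = sim.simulate_state_paths(default_model, genome, 2, seed=9)
        b = sim.simulate_state_paths(default_model, genome, 2, seed=9)
        for bs in a:
            for c in a[bs]:
                assert (a[bs][c] == b[bs][c]).all()

    def test_empirical_transitions_converge(self, default_model, genome):
        paths = sim.simulate_state_paths(default_model, genome, 2, seed=13)
        K = default_model.n_states
        counts = np.zeros((K, K))
        for per in paths.values():
            for arr in per.values():
                np.add.at(counts, (arr[:-1], arr[1:]), 1)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - default_model.transitions).max() < 0.02


class TestBinaryObservations:
    def test_deterministic_emissions(self, genome):
        m = sim.GroundTruthModel(
            ["m1"], np.array([0.5, 0.5]), np.full((2, 2), 0.5),
            np.array([[0.0], [1.0]]),
        )
        paths = sim.simulate_state_paths(m, genome, 1, seed=1)
        obs = sim.simulate_binary_observations(m, paths, seed=2)
        for c in genome.chrom_names:
            assert (obs["sample1"][c][:, 0] == paths["sample1"][c]).all()

    def test_missing_rate_one_blanks_column(self, default_model, genome):
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=1)
        obs = sim.simulate_binary_observations(
            default_model, paths, missing_mark="meCpG", missing_rate=1.0, seed=2
        )
        col = default_model.mark_names.index("meCpG")
        for c in genome.chrom_names:
            x = obs["sample1"][c]
            assert (x[:, col] == MISSING).all()
            assert (x[:, :col] != MISSING).all()

    def test_unknown_mark_rejected(self, default_model, genome):
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=1)
        with pytest.raises(ValueError, match="unknown mark"):
            sim.simulate_binary_observations(
                default_model, paths, missing_mark="H3K119ub", missing_rate=0.5
            )

    def test_emission_frequencies_within_binomial_error(self, default_model, genome):
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=21)
        obs = sim.simulate_binary_observations(default_model, paths, seed=22)
        path = np.concatenate([paths["sample1"][c] for c in genome.chrom_names])
        x = np.concatenate([obs["sample1"][c] for c in genome.chrom_names])
        for k in range(default_model.n_states):
            sel = path == k
            n = sel.sum()
            if n < 10_000:
                continue
            freq = x[sel].mean(axis=0)
            p = default_model.emissions[k]
            se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
            assert (np.abs(freq - p) <= 3 * se + 1e-9).all()


class TestRawTracks:
    def test_equal_rates_make_fg_bg_indistinguishable(self, default_model, genome):
        spec = {"x": sim.CountTrackSpec(2.0, 2.0, {0, 1}, paired_control=False)}
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=3)
        tracks = sim.simulate_raw_tracks(default_model, paths, spec, seed=4)
        path = np.concatenate([paths["sample1"][c] for c in genome.chrom_names])
        counts = np.concatenate(
            [tracks["sample1"]["x"][c]["counts"] for c in genome.chrom_names]
        )
        fg = np.isin(path, [0, 1])
        se = np.sqrt(2.0 / fg.sum() + 2.0 / (~fg).sum())
        assert abs(counts[fg].mean() - counts[~fg].mean()) < 3 * se

    def test_zero_cpg_density_gives_empty_bins(self, default_model, genome):
        spec = {
            "me": sim.MethylationTrackSpec(
                0.0, {k: (2.0, 2.0) for k in range(10)}
            )
        }
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=3)
        tracks = sim.simulate_raw_tracks(default_model, paths, spec, seed=4)
        for c in genome.chrom_names:
            assert len(tracks["sample1"]["me"][c]["pos"]) == 0

    def test_high_beta_methylation_exceeds_half(self, default_model):
        genome = BinnedGenome([("chr1", 400_000)])
        spec = {
            "me": sim.MethylationTrackSpec(
                4.0, {k: (50.0, 1.0) for k in range(10)}
            )
        }
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=3)
        tracks = sim.simulate_raw_tracks(
            default_model, paths, spec, seed=4, binned_genome=genome
        )
        data = tracks["sample1"]["me"]["chr1"]
        bins = data["pos"] // 200
        means = np.zeros(genome.total_bins)
        ns = np.zeros(genome.total_bins)
        np.add.at(means, bins, data["percent"].mean(axis=0))
        np.add.at(ns, bins, 1)
        sel = ns >= 3
        frac = ((means[sel] / ns[sel]) > 50).mean()
        assert frac >= 0.99

    def test_nonpositive_rate_rejected(self, default_model, genome):
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=3)
        with pytest.raises(ValueError, match="rate"):
            sim.simulate_raw_tracks(
                default_model, paths,
                {"x": sim.CountTrackSpec(0.0, 1.0, {0})}, seed=1,
            )

    def test_control_track_emitted_for_chip(self, default_model, genome):
        spec = {"k27": sim.CountTrackSpec(0.5, 5.0, {0}, paired_control=True)}
        paths = sim.simulate_state_paths(default_model, genome, 1, seed=3)
        tracks = sim.simulate_raw_tracks(default_model, paths, spec, seed=4)
        t = tracks["sample1"]["k27"]["chr1"]
        assert "control" in t and len(t["control"]) == len(t["counts"])


class TestGeneAndSilencerPlacement:
    def test_pure_tss_bias_places_all_tss_in_tss_bins(self, small_dataset):
        ds = small_dataset
        bias = {"Tss": 1.0}
        genes, expr = sim.simulate_gene_set(
            ds.state_paths, ds.model.role_map, 100, bias,
            sim.DEFAULT_EXPRESSION_SPEC, seed=5, binned_genome=ds.genome,
        )
        ref = ds.biosample_names[0]
        tss_states = set(ds.model.states_with_role("Tss"))
        for g in genes:
            chrom, pos = g.tss[0]
            assert ds.state_paths[ref][chrom][pos // 200] in tss_states

    def test_bivalent_genes_lowly_expressed_everywhere(self, small_dataset):
        # A gene is bivalent *in a biosample*: group by each biosample's own
        # state at the TSS, mirroring tissue-specific repression.
        ds = small_dataset
        biv = set(ds.model.states_with_role("TssBiv"))
        tss = set(ds.model.states_with_role("Tss"))
        for b in ds.biosample_names:
            groups = {"biv": [], "tss": []}
            for g in ds.genes:
                chrom, pos = g.tss[0]
                state = ds.state_paths[b][chrom][pos // 200]
                if state in biv:
                    groups["biv"].append(g.gene_id)
                elif state in tss:
                    groups["tss"].append(g.gene_id)
            assert len(groups["biv"]) >= 10 and len(groups["tss"]) >= 10
            assert (
                ds.expression.loc[groups["biv"], b].median()
                < ds.expression.loc[groups["tss"], b].median()
            )

    def test_zero_genes_and_zero_silencers(self, small_dataset):
        ds = small_dataset
        genes, expr = sim.simulate_gene_set(
            ds.state_paths, ds.model.role_map, 0, {"Tss": 1.0}, {}, seed=1
        )
        assert genes == [] and expr.empty
        sset = sim.simulate_silencer_set(
            ds.state_paths, ds.model.role_map, 0,
            sim.DEFAULT_SILENCER_GROUP_BIAS, seed=1, binned_genome=ds.genome,
        )
        assert len(sset) == 0

    def test_single_role_bias_places_all_centers(self, small_dataset):
        ds = small_dataset
        sset = sim.simulate_silencer_set(
            ds.state_paths, ds.model.role_map, 50, {g: {"TssBiv": 1.0} for g in
            (1, 2, 3, 4)}, seed=6, binned_genome=ds.genome,
        )
        ref = ds.biosample_names[0]
        biv = set(ds.model.states_with_role("TssBiv"))
        for _, r in sset.centers().iterrows():
            assert ds.state_paths[ref][r.chrom][r.center // 200] in biv

    def test_uniform_bias_matches_genomic_role_fractions(self, small_dataset):
        ds = small_dataset
        roles = set(ds.model.role_map.values())
        uniform = {g: {r: 1.0 for r in roles} for g in (1, 2, 3, 4)}
        sset = sim.simulate_silencer_set(
            ds.state_paths, ds.model.role_map, 400, uniform, seed=7,
            binned_genome=ds.genome,
        )
        ref = ds.biosample_names[0]
        path = np.concatenate(
            [ds.state_paths[ref][c] for c in ds.genome.chrom_names]
        )
        quies = set(ds.model.states_with_role("Quies"))
        genome_frac = np.isin(path, list(quies)).mean()
        centers = sset.centers()
        states = np.array(
            [ds.state_paths[ref][r.chrom][r.center // 200]
             for _, r in centers.iterrows()]
        )
        obs = np.isin(states, list(quies)).mean()
        se = np.sqrt(genome_frac * (1 - genome_frac) / len(centers))
        assert abs(obs - genome_frac) < 4 * se


class TestDatasetDeterminism:
    def test_same_seed_bitwise_identical(self):
        kwargs = dict(
            n_tissues=1, n_timepoints=2, n_genes=50, n_silencers=30,
            chromosomes=[("chr1", 400_000)],
        )
        a = sim.simulate_dataset(seed=77, **kwargs)
        b = sim.simulate_dataset(seed=77, **kwargs)
        for bs in a.state_paths:
            for c in a.state_paths[bs]:
                assert (a.state_paths[bs][c] == b.state_paths[bs][c]).all()
                assert (a.binary_obs[bs][c] == b.binary_obs[bs][c]).all()
        assert a.expression.equals(b.expression)
        assert a.silencers.df.equals(b.silencers.df)
        for c in a.conservation:
            assert (a.conservation[c] == b.conservation[c]).all()
        at = a.raw_tracks[a.biosample_names[0]]["H3K27me3"]["chr1"]
        bt = b.raw_tracks[b.biosample_names[0]]["H3K27me3"]["chr1"]
        assert (at["counts"] == bt["counts"]).all()

    def test_all_roles_covered(self, small_dataset):
        ds = small_dataset
        path = np.concatenate(
            [ds.state_paths[b][c] for b in ds.state_paths
             for c in ds.state_paths[b]]
        )
        assert set(np.unique(path)) == set(range(ds.model.n_states))
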