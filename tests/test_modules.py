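"""Module detection tests: average-linkage clustering against a naive
agglomeration oracle, the deterministic dynamic cut, eigengenes, kIM/kME,
hub identification and dataset-module correlation QC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_dataset
from modpres.modules import (
    GREY,
    Dendrogram,
    ModuleError,
    ModulePartition,
    cluster_genes,
    cut_tree_dynamic,
    dataset_module_correlation,
    detect_modules,
    identify_hubs,
    intramodular_connectivity,
    module_eigengenes,
    module_membership,
)
from modpres.network import (
    CoexpressionNetwork,
    correlation_matrix,
    signed_adjacency,
    tom_dissimilarity,
)
from modpres.simulate import PlantedModule, SimulationConfig, simulate_condition


def naive_average_linkage(d: np.ndarray):
    """O(n^3) reference agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


def planted_dataset(sizes, n_genes, loading=0.9, noise_sd=0.3, samples=60, seed=0,
                    min_loading_fraction=1.0):
    mods = [
        PlantedModule(s, {"ref": loading, "t": loading},
                      min_loading_fraction=min_loading_fraction)
        for s in sizes
    ]
    cfg = SimulationConfig(
        n_genes=n_genes,
        samples_per_condition={"ref": samples, "t": 4},
        modules=mods,
        noise_sd=noise_sd,
        seed=seed,
    )
    return simulate_condition(cfg, "ref")


class TestClustering:
    def test_zero_dissimilarity_pairs_merge_first_at_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dendro = cluster_genes(d)
        assert dendro.heights[0] == 0.0 and dendro.heights[1] == 0.0

    def test_matches_naive_agglomeration_on_five_leaves(self, rng):
        x = rng.uniform(0, 1, (5, 5))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = cluster_genes(d)
        assert np.allclose(sorted(dendro.heights), naive_average_linkage(d), atol=1e-12)

    def test_nonsymmetric_input_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.5
        with pytest.raises(ModuleError, match="symmetric"):
            cluster_genes(d)

    def test_partition_invariant_to_gene_order(self):
        ds, truth = planted_dataset([40, 40], 120, seed=5)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net)

        perm = np.random.default_rng(1).permutation(120)
        ds_p = make_dataset(ds.matrix()[perm])
        ds_p.values.index = ds.gene_ids[perm]
        net_p = signed_adjacency(correlation_matrix(ds_p), 6)
        part_p, _ = detect_modules(ds_p, net_p)
        merged = part_p.labels.reindex(part.labels.index)
        assert adjusted_rand_score(part.labels.values, merged.values) == 1.0


class TestDynamicCut:
    def test_two_planted_blocks_recovered_exactly(self):
        ds, truth = planted_dataset([40, 40], 120, loading=1.0, noise_sd=0.05)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net)
        named = part.module_names
        assert len(named) == 2
        assert adjusted_rand_score(truth.labels.values, part.labels.values) == 1.0

    def test_block_below_min_size_goes_grey(self):
        ds, _ = planted_dataset([25], 100, loading=0.9)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net, min_module_size=30)
        assert part.module_names == []
        assert (part.labels == GREY).all()

    def test_pure_noise_is_mostly_grey(self):
        for seed in (0, 1, 2):
            ds, _ = planted_dataset([], 400, samples=80, noise_sd=1.0, seed=seed)
            net = signed_adjacency(correlation_matrix(ds), 6)
            part, _ = detect_modules(ds, net)
            assert (part.labels == GREY).mean() >= 0.95

    def test_min_size_above_gene_count_warns_all_grey(self):
        d = np.ones((10, 10)) - np.eye(10)
        dendro = cluster_genes(d)
        with pytest.warns(UserWarning, match="grey"):
            labels = cut_tree_dynamic(dendro, min_module_size=50)
        assert (labels == GREY).all()

    def test_module_recovery_at_moderate_signal(self):
        # lambda=0.6, sigma=0.8, 100 samples: median ARI above 0.8
        aris = []
        for seed in range(10):
            mods = [PlantedModule(60, {"ref": 0.6, "t": 0.6}) for _ in range(4)]
            cfg = SimulationConfig(
                n_genes=500,
                samples_per_condition={"ref": 100, "t": 4},
                modules=mods,
                noise_sd=0.8,
                seed=seed,
            )
            ds, truth = simulate_condition(cfg, "ref")
            net = signed_adjacency(correlation_matrix(ds), 6)
            part, _ = detect_modules(ds, net)
            aris.append(adjusted_rand_score(truth.labels.values, part.labels.values))
        assert np.median(aris) > 0.8

    def test_partition_accounting(self):
        ds, _ = planted_dataset([40, 35], 150, seed=2)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net)
        sizes = part.sizes()
        assert sizes.sum() == 150
        for m in part.module_names:
            assert sizes[m] >= 30


class TestEigengenes:
    def test_rank_one_module(self, rng):
        profile = rng.normal(0, 1, 20)
        x = np.tile(profile, (5, 1)) * rng.uniform(0.5, 2.0, (5, 1)) + 3
        ds = make_dataset(x)
        labels = pd.Series(["blue"] * 5, index=ds.gene_ids)
        eig, pve = module_eigengenes(ds, labels)
        assert pve["blue"] == pytest.approx(1.0)
        r = np.corrcoef(eig.loc["blue"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented along the module mean profile

    def test_matches_brute_force_eigendecomposition(self, rng):
        x = rng.normal(0, 1, (4, 12))
        ds = make_dataset(x)
        labels = pd.Series(["m"] * 4, index=ds.gene_ids)
        eig, pve = module_eigengenes(ds, labels)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(z @ z.T)
        assert pve["m"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-9)
        # eigengene spans the leading left-singular direction's profile
        e = eig.loc["m"].to_numpy()
        recon = evecs[:, -1] @ z
        recon /= np.linalg.norm(recon)
        assert abs(np.dot(e, recon)) == pytest.approx(1.0, abs=1e-9)

    def test_pve_bounds_and_orientation(self):
        ds, _ = planted_dataset([30, 30], 80, seed=3)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net)
        for m in part.module_names:
            assert 0 < part.prop_var_explained[m] <= 1
            z = ds.matrix()[[ds.gene_ids.get_loc(g) for g in part.module_genes(m)]]
            z = (z - z.mean(1, keepdims=True)) / z.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(part.eigengenes.loc[m], z.mean(0))[0, 1] >= 0

    def test_zero_variance_gene_rejected(self):
        x = np.vstack([np.arange(8.0), np.full(8, 2.0)])
        ds = make_dataset(x)
        labels = pd.Series(["m", "m"], index=ds.gene_ids)
        with pytest.raises(ModuleError, match="zero-variance"):
            module_eigengenes(ds, labels)


class TestConnectivity:
    def test_uniform_adjacency_closed_form(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        net = CoexpressionNetwork(a, beta=1, gene_ids=pd.Index(["a", "b", "c"]))
        labels = pd.Series(["m", "m", "m"], index=net.gene_ids)
        kim = intramodular_connectivity(net, labels)
        assert np.allclose(kim, 1.0)

    def test_matches_brute_force_sum(self, rng):
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = CoexpressionNetwork(a, beta=1, gene_ids=pd.RangeIndex(6))
        labels = pd.Series(["m", "m", "m", "n", "n", GREY], index=net.gene_ids)
        kim = intramodular_connectivity(net, labels)
        for i, lab in enumerate(labels):
            expected = sum(
                a[i, j] for j in range(6) if labels.iloc[j] == lab and j != i
            )
            assert kim.iloc[i] == pytest.approx(expected, abs=1e-12)


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self, rng):
        ds, _ = planted_dataset([30], 60, seed=1)
        net = signed_adjacency(correlation_matrix(ds), 6)
        part, _ = detect_modules(ds, net)
        m = part.module_names[0]
        x2 = ds.values.copy()
        x2.iloc[0] = part.eigengenes.loc[m].to_numpy()
        from modpres.datasets import ExpressionDataset

        ds2 = ExpressionDataset(x2, ds.metadata.copy())
        kme, p = module_membership(ds2, part.eigengenes)
        assert kme.iloc[0][m] == pytest.approx(1.0)
        assert p.iloc[0][m] < 1e-30
        assert (kme.to_numpy() >= -1).all() and (kme.to_numpy() <= 1).all()

    def test_p_value_matches_permutation_oracle(self, rng):
        n = 10
        gene = rng.normal(0, 1, n)
        eig = 0.5 * gene + rng.normal(0, 1, n)
        ds = make_dataset(np.vstack([gene, rng.normal(0, 1, n)]))
        eigengenes = pd.DataFrame([eig], index=["m"], columns=ds.sample_ids)
        kme, p = module_membership(ds, eigengenes)
        r_obs = abs(np.corrcoef(gene, eig)[0, 1])
        perm_rng = np.random.default_rng(7)
        hits = sum(
            abs(np.corrcoef(perm_rng.permutation(gene), eig)[0, 1]) >= r_obs
            for _ in range(10_000)
        )
        p_perm = (hits + 1) / 10_001
        assert p.iloc[0]["m"] == pytest.approx(p_perm, abs=0.03)

    def test_too_few_samples_rejected(self, rng):
        ds = make_dataset(rng.normal(0, 1, (3, 3)))
        eigengenes = pd.DataFrame(
            rng.normal(0, 1, (1, 3)), index=["m"], columns=ds.sample_ids
        )
        with pytest.raises(ModuleError, match="4 samples"):
            module_membership(ds, eigengenes)


class TestHubs:
    def build_partition(self, seed=0):
        # the generating factor is markedly strongest for the first 10 genes
        profile = np.concatenate([np.ones(10), np.full(40, 0.5)])
        mod = PlantedModule(50, {"ref": 0.9, "t": 0.9}, custom_profile=profile)
        cfg = SimulationConfig(
            n_genes=200,
            samples_per_condition={"ref": 80, "t": 4},
            modules=[mod],
            noise_sd=0.6,
            seed=seed,
        )
        ds, truth = simulate_condition(cfg, "ref")
        net = signed_adjacency(correlation_matrix(ds), 6)
        labels = pd.Series(
            np.where(truth.labels.values == 1, "turquoise", GREY), index=ds.gene_ids
        )
        eig, pve = module_eigengenes(ds, labels)
        kme, kme_p = module_membership(ds, eig)
        part = ModulePartition(labels=labels, eigengenes=eig,
                               prop_var_explained=pve, kme=kme, kme_p=kme_p)
        part.kim = intramodular_connectivity(net, labels)
        return part

    def test_hubs_are_strongest_loading_genes(self):
        strongest = {f"G{i + 1:04d}" for i in range(10)}
        hits = 0
        for seed in range(20):
            part = self.build_partition(seed)
            hubs = identify_hubs(part, top_n=10)["turquoise"]
            hits += set(hubs) <= strongest
        assert hits >= 18  # >= 90% of replicates

    def test_alpha_zero_empty_and_truncation(self):
        part = self.build_partition(0)
        assert identify_hubs(part, alpha=0.0)["turquoise"] == []
        small = self.build_partition(0)
        # shrink the module to 5 genes; hub list cannot exceed the module
        keep = small.labels.index[:5]
        small.labels.iloc[5:] = GREY
        small.labels.iloc[:5] = "turquoise"
        hubs = identify_hubs(small, top_n=10)["turquoise"]
        assert len(hubs) <= 5


class TestDatasetModuleCorrelation:
    def run_with_batches(self, batch_driven, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.normal(0, 1, (80, n))
        f = rng.normal(0, 1, n)
        if batch_driven:
            f = np.concatenate([np.full(n // 2, 1.0), np.full(n - n // 2, -1.0)])
            f += rng.normal(0, 0.3, n)
        x[:30] += 0.9 * f
        ds = make_dataset(x, batch=["d1"] * (n // 2) + ["d2"] * (n - n // 2))
        labels = pd.Series(["blue"] * 30 + [GREY] * 50, index=ds.gene_ids)
        eig, pve = module_eigengenes(ds, labels)
        part = ModulePartition(labels=labels, eigengenes=eig, prop_var_explained=pve)
        return dataset_module_correlation(part, ds.metadata["batch"])

    def test_batch_free_modules_not_flagged(self):
        flagged = 0
        for seed in range(10):
            table = self.run_with_batches(False, seed)
            flagged += (table["p_adj"] < 0.05).any()
        assert flagged <= 1  # >= 90% of replicates clean

    def test_batch_driven_module_flagged(self):
        table = self.run_with_batches(True, 0)
        assert (table.loc[table["module"] == "blue", "p_adj"] < 0.05).all()

    def test_single_dataset_rejected(self, rng):
        ds = make_dataset(rng.normal(0, 1, (20, 10)))
        labels = pd.Series(["m"] * 20, index=ds.gene_ids)
        eig, pve = module_eigengenes(ds, labels)
        part = ModulePartition(labels=labels, eigengenes=eig)
        with pytest.raises(ModuleError, match="2 datasets"):
            dataset_module_correlation(part, ds.metadata["batch"])


class TestDendrogramInvariants:
    def test_heights_non_decreasing(self, rng):
        x = rng.uniform(0, 1, (20, 20))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = cluster_genes(d)
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_decreasing_heights_rejected(self):
        merges = np.array([[0.0, 1.0, 0.5, 2.0], [2.0, 3.0, 0.2, 3.0]])
        with pytest.raises(ModuleError, match="non-decreasing"):
            Dendrogram(merges=merges, gene_ids=pd.RangeIndex(3))
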