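"""Signed adjacency, TOM, module detection, module stats and edge export."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from circregnet.core import SampleDesign
from circregnet.network import (CoexpressionNetwork, build_tom,
                                pick_soft_threshold, signed_adjacency,
                                topological_overlap)


def tom_oracle(a):
    """Direct triple-loop evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestAdjacency:
    def test_formula_endpoints(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == 1.0
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == 0.0

    def test_zero_correlation_at_power_12(self):
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == pytest.approx(0.000244140625)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.eye(2), 0)


class TestTom:
    def test_isolated_perfect_pair_has_tom_one(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            x = rng.normal(size=(50, 12))
            a = signed_adjacency(np.corrcoef(x), 6)
            assert np.allclose(topological_overlap(a), tom_oracle(a), atol=1e-10)

    def test_symmetric_unit_diagonal_in_unit_interval(self):
        rng = np.random.default_rng(1)
        a, tom = build_tom(pd.DataFrame(rng.normal(size=(40, 10))), beta=6)
        for m in (a, tom):
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12

    def test_zero_variance_feature_rejected(self):
        frame = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            build_tom(frame, beta=6)


def _two_module_data(n_per=50, n_noise=40, n_samples=15, seed=0):
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n_samples))
    rows, labels = [], []
    for name, f in (("m1", f1), ("m2", f2)):
        for _ in range(n_per):
            rows.append(1.2 * f + rng.normal(0, 0.35, n_samples))
            labels.append(name)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append("noise")
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx)


class TestModules:
    def test_two_planted_modules_recovered(self):
        data, truth = _two_module_data()
        net = CoexpressionNetwork(power=6, log_transform=False).fit(data)
        labels = net.module_labels_
        planted = truth[truth != "noise"].index
        assert len(net.eigengenes_.columns) == 2
        agreement = adjusted_rand_score(truth[planted], labels[planted])
        assert agreement >= 0.9

    def test_eigengene_explains_module_variance(self):
        data, _ = _two_module_data()
        net = CoexpressionNetwork(power=6, log_transform=False).fit(data)
        assert all(v >= 0.5 for v in net.eigengene_variance_.values())

    def test_correlated_factors_merge_below_cut_height(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        # two drivers correlated ~0.95: eigengene dissimilarity < 0.25
        f1 = base + rng.normal(0, 0.3, 20)
        f2 = base + rng.normal(0, 0.3, 20)
        rows = [1.5 * f + rng.normal(0, 0.3, 20)
                for f in (f1, f2) for _ in range(40)]
        data = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)])
        net = CoexpressionNetwork(power=6, merge_cut_height=0.25,
                                  log_transform=False).fit(data)
        assert len(net.eigengenes_.columns) == 1

    def test_all_noise_leaves_everything_unassigned(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(120, 15)),
                            index=[f"g{i}" for i in range(120)])
        net = CoexpressionNetwork(power=12, log_transform=False).fit(data)
        assert (net.module_labels_ == "grey").all()

    def test_permuting_features_permutes_labels_only(self):
        data, _ = _two_module_data(n_per=40, n_noise=20)
        net_a = CoexpressionNetwork(power=6, log_transform=False).fit(data)
        perm = data.sample(frac=1.0, random_state=5)
        net_b = CoexpressionNetwork(power=6, log_transform=False).fit(perm)
        a = net_a.module_labels_.sort_index()
        b = net_b.module_labels_.sort_index()
        assert adjusted_rand_score(a, b) == 1.0

    def test_planted_family_modules_recovered_on_synthetic_data(self, dataset,
                                                                fitted_network):
        truth = dataset.truth.module_membership
        feats = list(truth)
        labels = fitted_network.module_labels_[feats]
        assert adjusted_rand_score([truth[f] for f in feats], labels) >= 0.8


class TestSoftThreshold:
    def test_fit_table_has_one_row_per_power(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(60, 12)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, table = pick_soft_threshold(data, powers=range(1, 31))
        assert len(table) == 30
        assert list(table.power) == list(range(1, 31))

    def test_pure_noise_falls_back_to_operating_point(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(80, 12)))
        with pytest.warns(UserWarning, match="falling back"):
            beta, _ = pick_soft_threshold(data)
        assert beta == 12

    def test_scale_free_generator_reaches_target_fit(self):
        # latent-factor model with heavy-tailed couplings: connectivity is
        # approximately power-law, so some power reaches signed R^2 >= 0.8
        rng = np.random.default_rng(0)
        n, m = 800, 40
        w = rng.random(n) ** 4.0
        x = np.outer(w, rng.normal(size=m))
        x += np.sqrt(1 - w**2)[:, None] * rng.normal(size=(n, m))
        beta, table = pick_soft_threshold(pd.DataFrame(x))
        assert table.loc[table.power == beta, "fit"].iloc[0] >= 0.8


class TestModuleStats:
    def test_eigengene_equal_to_stage_indicator_is_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        design = [SampleDesign(f"A0-{r}", "A0", r) for r in (1, 2, 3)] + [
            SampleDesign(f"A120-{r}", "A120", r) for r in (1, 2, 3)
        ]
        indicator = np.array([1.0, 1, 1, 0, 0, 0])
        rows = [3 * indicator + rng.normal(0, 0.05, 6) for _ in range(40)]
        rows += [rng.normal(size=6) for _ in range(10)]
        data = pd.DataFrame(rows, index=[f"g{i}" for i in range(50)],
                            columns=[d.sample_id for d in design])
        net = CoexpressionNetwork(power=6, min_module_size=10,
                                  log_transform=False).fit(data)
        stats = net.module_stats(design)
        top = stats.module_trait_r.loc["M1"].abs().idxmax()
        assert top == "A0"
        assert stats.module_trait_p.loc["M1", "A0"] < 0.01
        # planted members are hubs for that stage
        assert len(stats.hubs) > 0
        assert set(stats.hubs.stage) <= {"A0", "A120"}

    def test_stage_specific_planted_module_is_called(self, dataset, fitted_network):
        stats = fitted_network.module_stats()
        assert (stats.module_trait_p.min(axis=1) < 0.01).any()
        assert (stats.gs.abs() <= 1.0 + 1e-12).all().all()
        assert (stats.mm.abs() <= 1.0 + 1e-12).all().all()
        for row in stats.hubs.itertuples():
            assert abs(row.gs) > 0.8 and abs(row.mm) > 0.8

    def test_missing_design_rejected(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(40, 10)))
        net = CoexpressionNetwork(power=6, min_module_size=5,
                                  log_transform=False).fit(data)
        with pytest.raises(ValueError, match="design"):
            net.module_stats()


class TestTopEdges:
    def test_edge_count_capped_by_module_size(self, fitted_network):
        module = fitted_network.eigengenes_.columns[0]
        n_members = int((fitted_network.module_labels_ == module).sum())
        edges = fitted_network.export_top_edges(module, n_edges=10**9)
        assert len(edges) == n_members * (n_members - 1) // 2

    def test_top_200_of_larger_module(self, fitted_network):
        sizes = fitted_network.module_labels_.value_counts()
        module = sizes.drop("grey", errors="ignore").idxmax()
        edges = fitted_network.export_top_edges(module, n_edges=200)
        assert len(edges) == 200
        assert (np.diff(edges.weight) <= 1e-12).all()

    def test_ties_break_lexicographically(self):
        frame = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4.0]],
            index=["b", "a", "c"],
        )
        frame += np.random.default_rng(0).normal(0, 1e-9, frame.shape)
        net = CoexpressionNetwork(power=2, min_module_size=2,
                                  cut_height=0.99999, log_transform=False).fit(frame)
        module = net.module_labels_.iloc[0]
        edges = net.export_top_edges(module, 10)
        assert list(edges.source) == sorted(edges.source)

    def test_unknown_module_rejected(self, fitted_network):
        with pytest.raises(ValueError, match="unknown module"):
            fitted_network.export_top_edges("M999")
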