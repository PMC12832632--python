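import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regenhubnet.netcore import (
    EXCLUDED,
    AdjacencyMatrix,
    CoexpressionNetwork,
    NetworkParams,
    TOMatrix,
    compute_adjacency,
    compute_tom,
    detect_modules,
    filter_genes_by_fraction,
    scale_free_fit,
    scan_soft_powers,
    select_soft_power,
)
from regenhubnet.synthdata import ExpressionSection


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop oracle for the topological overlap matrix."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n, power=2):
    x = rng.normal(size=(n + 5, n))
    cor = np.corrcoef(x, rowvar=False)
    a = ((1 + cor) / 2) ** power
    np.fill_diagonal(a, 1.0)
    return a


def section_from(values, celltypes):
    values = np.asarray(values, float)
    n, g = values.shape
    cells = pd.DataFrame(
        {"cell_id": [f"c{i}" for i in range(n)], "celltype": celltypes,
         "x": np.zeros(n), "y": np.zeros(n)}
    )
    return ExpressionSection(values=values, genes=tuple(f"g{j}" for j in range(g)),
                             cells=cells, condition="2dpi")


class TestFilterGenes:
    def test_detection_boundary_is_inclusive(self):
        values = np.zeros((100, 3))
        values[:5, 0] = 1.0   # 5% exactly -> retained
        values[:4, 1] = 1.0   # 4% -> dropped
        section = section_from(values, ["A"] * 100)
        kept = filter_genes_by_fraction(section, "A", 0.05)
        assert kept == ["g0"]

    def test_all_zero_gene_dropped(self):
        values = np.ones((20, 2))
        values[:, 1] = 0.0
        section = section_from(values, ["A"] * 20)
        assert filter_genes_by_fraction(section, "A", 0.01) == ["g0"]

    def test_empty_group_rejected(self):
        section = section_from(np.ones((5, 2)), ["A"] * 5)
        with pytest.raises(ValueError):
            filter_genes_by_fraction(section, "B", 0.05)


class TestAdjacency:
    def test_perfectly_correlated_genes_have_unit_adjacency(self, rng):
        base = rng.normal(size=10)
        frame = pd.DataFrame({"a": base, "b": 2 * base + 1})
        for power in (1, 6, 12):
            adj = compute_adjacency(frame, power, "signed")
            assert adj.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_signed_power_two_is_zero(self, rng):
        base = rng.normal(size=10)
        frame = pd.DataFrame({"a": base, "b": -base})
        adj = compute_adjacency(frame, 2, "signed")
        assert adj.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_signed_formula_at_half_correlation(self):
        # ((1 + 0.5)/2)^9 = 0.75^9, evaluated directly from the formula
        rng = np.random.default_rng(0)
        z = rng.normal(size=20000)
        a = z
        b = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=20000)
        frame = pd.DataFrame({"a": a, "b": b})
        adj = compute_adjacency(frame, 9, "signed")
        cor = np.corrcoef(a, b)[0, 1]
        assert adj.values[0, 1] == pytest.approx(((1 + cor) / 2) ** 9, rel=1e-12)
        assert adj.values[0, 1] == pytest.approx(0.75**9, rel=0.05)

    def test_unsigned_uses_absolute_correlation(self, rng):
        base = rng.normal(size=30)
        frame = pd.DataFrame({"a": base, "b": -base})
        adj = compute_adjacency(frame, 3, "unsigned")
        assert adj.values[0, 1] == pytest.approx(1.0)

    def test_constant_gene_rejected_by_name(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=5), "flat": np.ones(5)})
        with pytest.raises(ValueError, match="flat"):
            compute_adjacency(frame, 2)

    def test_raising_power_weakly_decreases_offdiagonal(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 8)), columns=list("abcdefgh"))
        prev = None
        for power in (1, 2, 4, 8):
            adj = compute_adjacency(x, power).values.copy()
            np.fill_diagonal(adj, 0)
            if prev is not None:
                assert (adj <= prev + 1e-12).all()
            prev = adj


class TestScaleFreeFit:
    def test_exact_power_law_bins_score_one(self):
        # connectivities placed so bin means follow p(k) ~ k^-2 exactly
        ks = []
        for k, count in [(1.0, 1024), (2.0, 256), (4.0, 64), (8.0, 16)]:
            ks.extend([k] * count)  # frequencies follow p(k) = c k^-2 exactly

        class Stub:  # adjacency stand-in exposing prepared connectivities
            connectivity = np.array(ks)

        fit = scale_free_fit(Stub(), 8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope < 0

    def test_increasing_degree_law_scores_non_positive(self):
        ks = []
        for k, count in [(1.0, 5), (2.0, 20), (4.0, 80), (8.0, 320)]:
            ks.extend([k] * count)
        class Stub:
            connectivity = np.array(ks)
        fit = scale_free_fit(Stub(), 8)
        assert fit.r_squared <= 0

    def test_hub_structured_network_outscores_random_one(self, single_section):
        section, _ = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0].iloc[:, :200]
        planted = scale_free_fit(compute_adjacency(frame, 8), 10)
        rng = np.random.default_rng(0)
        noise = pd.DataFrame(rng.normal(size=(200, 200)))
        noise.columns = [f"n{i}" for i in range(200)]
        random_fit = scale_free_fit(compute_adjacency(noise, 8), 10)
        assert planted.r_squared > random_fit.r_squared

    def test_single_bin_rejected(self):
        class Stub:
            connectivity = np.full(50, 3.0)
        with pytest.raises(ValueError):
            scale_free_fit(Stub(), 10)


class TestSelectSoftPower:
    def test_returns_minimum_qualifying_candidate(self, single_section):
        section, _ = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0]
        params = NetworkParams()
        chosen = select_soft_power(frame, params)
        scan = scan_soft_powers(frame, params)
        qualifying = [
            int(p) for p, r in zip(scan["power"], scan["r_squared"])
            if r >= params.r2_threshold
        ]
        assert chosen == min(qualifying)

    def test_unattainable_threshold_gives_excluded(self, single_section):
        section, _ = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0]
        result = select_soft_power(frame, NetworkParams(r2_threshold=1.01))
        assert result is EXCLUDED
        assert not result  # falsy sentinel

    def test_threshold_accepting_everything_gives_first_candidate(self, single_section):
        section, _ = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0]
        assert select_soft_power(frame, NetworkParams(r2_threshold=-1.0)) == 1


class TestTOM:
    def test_complete_graph_has_unit_overlap(self):
        a = np.ones((3, 3))
        tom = compute_tom(AdjacencyMatrix(a, ("a", "b", "c"), 1, "signed"))
        # (1 + 1) / (2 + 1 - 1) = 1 for every off-diagonal pair
        assert np.allclose(tom.values, 1.0)

    def test_three_node_star(self):
        a = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        tom = compute_tom(AdjacencyMatrix(a, ("hub", "l1", "l2"), 1, "signed"))
        # leaves: (1*1 + 0) / (min(1,1) + 1 - 0) = 0.5
        assert tom.values[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        a = random_adjacency(rng, n)
        tom = compute_tom(AdjacencyMatrix(a, tuple(f"g{i}" for i in range(n)), 2, "signed"))
        np.testing.assert_allclose(tom.values, tom_bruteforce(a), atol=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            compute_tom(AdjacencyMatrix(a, ("a", "b"), 1, "signed"))


class TestDetectModules:
    def _block_tom(self, sizes, within=0.8, between=0.02, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        t = np.full((n, n), between) + rng.uniform(0, 0.005, (n, n))
        t = (t + t.T) / 2
        start = 0
        for s in sizes:
            t[start : start + s, start : start + s] = within + rng.uniform(
                0, 0.05, (s, s)
            )
            start += s
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        return TOMatrix(np.clip(t, 0, 1), tuple(f"g{i:03d}" for i in range(n)))

    def test_two_planted_blocks_recovered_exactly(self):
        tom = self._block_tom([40, 40])
        assignment = detect_modules(tom, NetworkParams(min_module_size=30))
        truth = ["A"] * 40 + ["B"] * 40
        detected = [assignment.labels[g] for g in tom.genes]
        assert assignment.n_modules == 2
        assert adjusted_rand_score(truth, detected) == 1.0

    def test_min_module_size_larger_than_clusters_gives_all_grey(self):
        tom = self._block_tom([20, 20])
        assignment = detect_modules(tom, NetworkParams(min_module_size=50))
        assert assignment.n_modules == 0
        assert assignment.n_grey == 40

    def test_identical_tom_rows_give_single_module(self):
        # identical rows means zero dissimilarity everywhere: one module
        n = 40
        t = np.ones((n, n))
        tom = TOMatrix(t, tuple(f"g{i}" for i in range(n)))
        assignment = detect_modules(tom, NetworkParams(min_module_size=10))
        assert assignment.n_modules == 1
        assert set(assignment.labels.values()) == {"M1"}

    def test_labels_ordered_by_size_deterministically(self):
        tom = self._block_tom([50, 35])
        assignment = detect_modules(tom, NetworkParams(min_module_size=30))
        sizes = assignment.module_sizes()
        assert sizes["M1"] >= sizes["M2"]


class TestModelRecovery:
    def test_planted_modules_recovered_via_model_fit(self, single_section):
        section, truth = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0]
        res = CoexpressionNetwork(frame, NetworkParams(min_module_size=25)).fit()
        assert not res.excluded
        truth_labels = [truth.module_membership.get(g, "none") for g in frame.columns]
        detected = [res.modules.labels[g] for g in frame.columns]
        assert adjusted_rand_score(truth_labels, detected) >= 0.8
        assert "soft power" in res.summary()

    def test_excluded_fit_has_no_modules_and_summary_reports_it(self, single_section):
        section, _ = single_section
        frame = pd.DataFrame(section.values, columns=list(section.genes))
        frame = frame.loc[:, frame.std(axis=0) > 0]
        res = CoexpressionNetwork(frame, NetworkParams(r2_threshold=1.5)).fit()
        assert res.excluded
        assert res.modules.n_modules == 0
        assert "EXCLUDED" in res.summary()
        assert res.hub_genes().empty


class TestNetworkParamsValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(fraction=0.0),
            dict(fraction=1.0),
            dict(power_candidates=(3, 2)),
            dict(power_candidates=(0, 1)),
            dict(network_type="semi"),
            dict(deep_split=9),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            NetworkParams(**bad)
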