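import numpy as np
import pytest
from scipy import stats

from angiotomo import (
    Branch,
    Node,
    VascularGraph,
    compare_groups,
    diameter_colormap,
    summarize,
    trend_report,
)
from angiotomo.morphometry import Morphometry


def y_graph(diameters=(8.0, 15.0, 25.0), lengths=(100.0, 50.0, 50.0)):
    nodes = [
        Node(0, np.zeros(3), "endpoint", 1),
        Node(1, np.ones(3) * 50, "junction", 3),
        Node(2, np.array([100.0, 0, 50]), "endpoint", 1),
        Node(3, np.array([100.0, 100, 50]), "endpoint", 1),
    ]
    path = np.array([[0, 0, 0], [1, 1, 1]])
    branches = [
        Branch(i, *ab, path, l, d)
        for i, (ab, l, d) in enumerate(zip(((0, 1), (1, 2), (1, 3)), lengths, diameters))
    ]
    return VascularGraph(nodes, branches, 5.2)


def make_morpho(condition, values, metric="n_branches"):
    out = []
    for i, v in enumerate(values):
        kw = dict(
            sample_id=f"{condition}_{i}", condition=condition, n_branches=1, n_nodes=2,
            mean_length_um=1.0, total_length_um=1.0, diameter_histogram=(1, 0, 0, 0),
            vascular_volume_fraction=0.1, cavity_volume_um3=0.0,
        )
        kw[metric] = v
        out.append(Morphometry(**kw))
    return out


class TestSummarize:
    def test_y_graph_oracle(self):
        m = summarize(y_graph())
        assert m.n_branches == 3
        assert m.n_nodes == 4
        assert m.mean_length_um == pytest.approx(200.0 / 3.0)
        assert m.diameter_histogram == (1, 1, 1, 0)

    def test_empty_graph(self):
        m = summarize(VascularGraph([], [], 5.2))
        assert m.n_branches == 0 and m.n_nodes == 0
        assert m.diameter_histogram == (0, 0, 0, 0)
        assert m.warning == "empty graph"

    @pytest.mark.parametrize("diameter,bin_idx", [(5, 0), (15, 1), (35, 2), (60, 3)])
    def test_bin_assignment(self, diameter, bin_idx):
        m = summarize(y_graph(diameters=(diameter,) * 3))
        assert m.diameter_histogram[bin_idx] == 3

    def test_histogram_conservation(self):
        for diam in ((3.0, 12.0, 80.0), (10.0, 20.0, 50.0)):
            m = summarize(y_graph(diameters=diam))
            assert sum(m.diameter_histogram) == m.n_branches

    def test_boundary_values_bin_upward(self):
        # edges at 10/20/50: a 10 μm branch counts in the 10–20 bin
        m = summarize(y_graph(diameters=(10.0, 20.0, 50.0)))
        assert m.diameter_histogram == (0, 1, 1, 1)


class TestCompareGroups:
    def test_identical_groups_f0_p1(self):
        samples = make_morpho("a", [1, 2, 3]) + make_morpho("b", [1, 2, 3])
        comp = compare_groups(samples, "n_branches")
        assert comp.F_statistic == 0.0
        assert comp.p_value == 1.0

    def test_hand_computed_f(self):
        samples = make_morpho("a", [1, 2, 3]) + make_morpho("b", [4, 5, 6])
        comp = compare_groups(samples, "n_branches")
        assert comp.F_statistic == pytest.approx(13.5, rel=1e-12)
        assert comp.df_between == 1 and comp.df_within == 4

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            data = {g: rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 7))
                    for g in ("a", "b", "c")}
            samples = sum((make_morpho(g, v, "mean_length_um") for g, v in data.items()), [])
            comp = compare_groups(samples, "mean_length_um")
            F, p = stats.f_oneway(*data.values())
            assert comp.F_statistic == pytest.approx(F, rel=1e-10)
            assert comp.p_value == pytest.approx(p, rel=1e-10, abs=1e-12)

    def test_small_group_fails_with_name(self):
        samples = make_morpho("a", [1, 2, 3]) + make_morpho("tiny", [4])
        with pytest.raises(ValueError, match="tiny"):
            compare_groups(samples, "n_branches")

    def test_zero_within_variance_flagged(self):
        samples = make_morpho("a", [1, 1, 1]) + make_morpho("b", [2, 2, 2])
        comp = compare_groups(samples, "n_branches")
        assert np.isinf(comp.F_statistic)
        assert comp.p_value == 0.0
        assert comp.flag == "zero within-group variance"

    def test_tukey_covers_all_pairs_once(self):
        rng = np.random.default_rng(1)
        samples = []
        for g in ("sham", "4h", "6h", "3d", "18d"):
            samples += make_morpho(g, rng.normal(0, 1, 3))
        comp = compare_groups(samples, "n_branches")
        pairs = {frozenset((a, b)) for a, b, _, _ in comp.tukey_pairs}
        assert len(comp.tukey_pairs) == 10
        assert len(pairs) == 10

    def test_tukey_familywise_error_under_null(self):
        """All-pairs Tukey at α=0.05 keeps the family-wise error ≤ 0.07
        across 5 groups of 3 under the null."""
        rng = np.random.default_rng(0)
        fw = 0
        n_sim = 1000
        for _ in range(n_sim):
            samples = []
            for g in ("a", "b", "c", "d", "e"):
                samples += make_morpho(g, rng.normal(0, 1, 3), "mean_length_um")
            comp = compare_groups(samples, "mean_length_um")
            fw += any(p < 0.05 for _, _, _, p in comp.tukey_pairs)
        assert fw / n_sim <= 0.07


class TestColormap:
    def test_endpoints_clamped(self):
        g = y_graph(diameters=(5.0, 50.0, 80.0))
        table, legend = diameter_colormap(g)
        assert table.loc[0, "t"] == 0.0  # below range → dark blue end
        assert table.loc[1, "t"] == 1.0
        assert table.loc[2, "t"] == 1.0  # clamped at red end
        assert legend["range_um"] == (10.0, 50.0)
        # blue end has dominant blue channel, red end dominant red
        assert table.loc[0, "b"] > table.loc[0, "r"]
        assert table.loc[2, "r"] > table.loc[2, "b"]

    def test_midpoint_and_monotonicity(self):
        g = y_graph(diameters=(20.0, 30.0, 40.0))
        table, _ = diameter_colormap(g)
        assert table.loc[1, "t"] == pytest.approx(0.5)
        assert table["t"].is_monotonic_increasing

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            diameter_colormap(y_graph(), (50.0, 10.0))


class TestTrendReport:
    def test_report_shape_and_markers(self):
        rng = np.random.default_rng(2)
        samples = []
        for g, mu in (("sham", 100), ("4h", 160), ("6h", 180), ("3d", 80), ("18d", 40)):
            samples += make_morpho(g, rng.normal(mu, 5, 3))
        comps = [compare_groups(samples, "n_branches")]
        rep = trend_report(comps)
        assert "n_branches" in rep.orderings
        assert set(rep.orderings["n_branches"]) == {"sham", "4h", "6h", "3d", "18d"}
        assert "ANOVA" in rep.text

    def test_single_group_means_only(self):
        samples = make_morpho("sham", [1.0, 2.0, 3.0])
        comp = compare_groups(samples, "n_branches")
        assert comp.flag is not None and "single group" in comp.flag
        rep = trend_report([comp])
        assert "no test" in rep.text
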