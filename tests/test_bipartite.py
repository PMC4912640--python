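import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongenet import bipartite
from spongenet.bipartite import BipartiteNetwork
from spongenet.io_prep import CountTable, SampleMetadata


def _study(presence_map, reps=2):
    """Build a tiny study from {species: {otu: [flags per replicate]}}."""
    rows, meta_rows = {}, []
    otus = sorted({o for d in presence_map.values() for o in d})
    for sp, d in presence_map.items():
        for r in range(reps):
            sid = f"{sp}_r{r}"
            meta_rows.append((sid, sp, "sponge"))
            rows[sid] = [10 * d.get(o, [0] * reps)[r] for o in otus]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=otus)
    counts.index.name = "sample_id"
    meta = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "host_species", "habitat"]).set_index(
            "sample_id"
        )
    )
    return CountTable(counts), meta


class TestBuildNetwork:
    def test_hand_counted_links(self):
        table, meta = _study(
            {
                "h1": {"o1": [1, 1], "o2": [1, 0]},
                "h2": {"o1": [1, 1], "o3": [0, 1]},
                "h3": {"o1": [1, 1], "o2": [1, 1]},
            }
        )
        net = bipartite.build_network(table, meta, min_samples=1)
        assert set(net.links) == {
            ("h1", "o1"), ("h1", "o2"), ("h2", "o1"), ("h2", "o3"),
            ("h3", "o1"), ("h3", "o2"),
        }
        assert net.otu_degrees()["o1"] == 3
        assert net.host_degrees()["h2"] == 2

    def test_min_samples_boundary(self):
        # o_in occurs in exactly 25 samples, o_out in 24
        n = 30
        counts = pd.DataFrame(
            {
                "o_in": [1] * 25 + [0] * (n - 25),
                "o_out": [1] * 24 + [0] * (n - 24),
                "o_base": [1] * n,
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        meta = SampleMetadata(
            pd.DataFrame(
                [(f"s{i}", f"sp{i % 3}", "sponge") for i in range(n)],
                columns=["sample_id", "host_species", "habitat"],
            ).set_index("sample_id")
        )
        net = bipartite.build_network(CountTable(counts), meta, min_samples=25)
        assert "o_in" in net.otu_nodes
        assert "o_out" not in net.otu_nodes

    def test_single_species_gives_degree_one(self):
        table, meta = _study({"h1": {"o1": [1, 1]}, "h2": {"o2": [1, 1]}})
        net = bipartite.build_network(table, meta, min_samples=1)
        assert net.otu_degrees()["o1"] == 1

    def test_empty_network_errors(self):
        table, meta = _study({"h1": {"o1": [1, 0]}})
        with pytest.raises(ValueError, match="min_samples|empty"):
            bipartite.build_network(table, meta, min_samples=99)


class TestCcdf:
    def test_small_example(self):
        out = bipartite.ccdf([1, 1, 2])
        assert out.loc[out.k == 1, "pc"].iloc[0] == 1.0
        assert out.loc[out.k == 2, "pc"].iloc[0] == pytest.approx(1 / 3)

    def test_equal_degrees_single_point(self):
        out = bipartite.ccdf([4, 4, 4])
        assert len(out) == 1 and out["pc"].iloc[0] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=1, max_size=100))
    def test_ccdf_invariants(self, degrees):
        """Pc starts at 1, never increases, and ignores node duplication."""
        out = bipartite.ccdf(degrees)
        assert out["pc"].iloc[0] == 1.0
        assert (np.diff(out["pc"]) <= 1e-12).all()
        doubled = bipartite.ccdf(degrees + degrees)
        np.testing.assert_allclose(out["pc"], doubled["pc"])


class TestDegreeFits:
    def test_exact_truncated_power_law_recovery(self):
        k = np.arange(1, 82, dtype=float)
        pts = pd.DataFrame({"k": k, "pc": k**-0.32 * np.exp(-k / 7.44)})
        fit = bipartite.fit_truncated_power_law(pts)
        assert fit.params["a"] == pytest.approx(0.32, abs=1e-3)
        assert fit.params["b"] == pytest.approx(7.44, abs=1e-3)

    def test_pure_power_law_flags_no_cutoff(self):
        k = np.arange(1, 40, dtype=float)
        pts = pd.DataFrame({"k": k, "pc": k**-0.8})
        fit = bipartite.fit_truncated_power_law(pts)
        assert "no cutoff support" in fit.flags

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"k": [1, 2, 3], "pc": [1.0, 0.5, 0.2]})
        with pytest.raises(ValueError, match=">=4"):
            bipartite.fit_truncated_power_law(pts)

    def test_exact_exponential_recovery(self):
        k = np.linspace(1, 7000, 60)
        pts = pd.DataFrame({"k": k, "pc": np.exp(-k / 1849.0)})
        fit = bipartite.fit_exponential(pts)
        assert fit.params["scale"] == pytest.approx(1849.0, rel=1e-6)

    def test_constant_pc_flags_divergent_scale(self):
        pts = pd.DataFrame({"k": [1.0, 2, 3, 4], "pc": [1.0, 1.0, 1.0, 1.0]})
        fit = bipartite.fit_exponential(pts)
        assert fit.flags


class TestNullNetwork:
    def _net(self):
        hosts = [f"h{i}" for i in range(6)]
        otus = [f"o{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        links = {(hosts[rng.integers(6)], o) for o in otus for _ in range(2)}
        return BipartiteNetwork(hosts, otus, links)

    def test_counts_preserved_and_reproducible(self):
        net = self._net()
        null1 = bipartite.null_network(net, seed=5)
        null2 = bipartite.null_network(net, seed=5)
        assert null1.n_links == net.n_links
        assert set(null1.host_nodes) == set(net.host_nodes)
        assert null1.links == null2.links
        assert bipartite.null_network(net, seed=6).links != null1.links

    def test_expected_degree_uniform(self):
        net = self._net()
        mean_deg = np.mean(
            [bipartite.null_network(net, seed=s).otu_degrees().mean() for s in range(100)]
        )
        assert mean_deg == pytest.approx(net.n_links / len(net.otu_nodes), rel=0.02)


class TestClassification:
    def test_degree_boundaries(self):
        hosts = [f"h{i}" for i in range(60)]
        links = set()
        otus = ["spec", "mid_lo", "mid_hi", "gen"]
        for i in range(4):
            links.add((hosts[i], "spec"))
        for i in range(5):
            links.add((hosts[i], "mid_lo"))
        for i in range(50):
            links.add((hosts[i], "mid_hi"))
        for i in range(51):
            links.add((hosts[i], "gen"))
        net = BipartiteNetwork(hosts, otus, links)
        counts = pd.DataFrame(
            {o: [1] * 60 for o in otus},
            index=pd.Index([f"{h}_r0" for h in hosts], name="sample_id"),
        )
        meta = SampleMetadata(
            pd.DataFrame(
                [(f"{h}_r0", h, "sponge") for h in hosts],
                columns=["sample_id", "host_species", "habitat"],
            ).set_index("sample_id")
        )
        cls = bipartite.classify_otus(net, CountTable(counts), meta)
        assert cls.loc["spec", "otu_class"] == "specialist"
        assert cls.loc["mid_lo", "otu_class"] == "intermediate"
        assert cls.loc["mid_hi", "otu_class"] == "intermediate"
        assert cls.loc["gen", "otu_class"] == "generalist"
        assert "mean_degree" in cls.attrs["diagnostics"]

    def test_prevalence_fraction_hand_computed(self):
        table, meta = _study(
            {
                "h1": {"o1": [1, 1], "o2": [1, 0]},
                "h2": {"o1": [1, 0], "o2": [0, 0]},
            }
        )
        net = bipartite.build_network(table, meta, min_samples=1)
        cls = bipartite.classify_otus(net, table, meta)
        # o1 is linked to h1 and h2, found in 3 of their 4 samples
        assert cls.loc["o1", "prevalence_fraction"] == pytest.approx(0.75)
        # o2 linked only to h1 (no presence in h2), 1 of 2 samples
        assert cls.loc["o2", "prevalence_fraction"] == pytest.approx(0.5)

    def test_full_prevalence_is_one(self):
        table, meta = _study({"h1": {"o1": [1, 1]}, "h2": {"o1": [1, 1]}})
        net = bipartite.build_network(table, meta, min_samples=1)
        cls = bipartite.classify_otus(net, table, meta)
        assert cls.loc["o1", "prevalence_fraction"] == 1.0


class TestPrevalenceSpline:
    def _frame(self, degree, prev):
        return pd.DataFrame({"degree": degree, "prevalence_fraction": prev})

    def test_constant_input_gives_constant_spline(self):
        df = self._frame([1, 3, 6, 10, 20], [0.4] * 5)
        out = bipartite.prevalence_spline(df)
        np.testing.assert_allclose(out["prevalence_fit"], 0.4, atol=1e-8)

    def test_interpolation_limit_at_zero_smoothing(self):
        x = np.array([1.0, 2, 4, 7, 11, 16])
        y = 0.1 + 0.05 * x
        df = self._frame(x, y)
        out = bipartite.prevalence_spline(df, smoothing="fixed", lam=1e-10)
        fit_at_x = np.interp(x, out["degree"], out["prevalence_fit"])
        np.testing.assert_allclose(fit_at_x, y, atol=1e-5)

    def test_grid_spans_degree_range(self):
        df = self._frame([2, 5, 9, 14, 30], [0.2, 0.5, 0.3, 0.8, 0.9])
        out = bipartite.prevalence_spline(df)
        assert out["degree"].iloc[0] == 2
        assert out["degree"].iloc[-1] == 30


class TestCoreEnrichment:
    def _net(self):
        hosts = [f"h{i}" for i in range(10)]
        otus = [f"o{i}" for i in range(20)]
        links = set()
        for j, o in enumerate(otus):
            for h in hosts[: 1 + j % 10]:
                links.add((h, o))
        return BipartiteNetwork(hosts, otus, links)

    def test_full_core_sits_on_identity_line(self):
        net = self._net()
        out = bipartite.core_degree_enrichment(net, list(net.otu_nodes))
        np.testing.assert_allclose(
            out["curve"]["global_fraction"], out["curve"]["core_fraction"]
        )
        assert out["break_k"] is None

    def test_top_degree_core_is_enriched(self):
        net = self._net()
        deg = net.otu_degrees()
        core = list(deg.sort_values(ascending=False).index[:5])
        out = bipartite.core_degree_enrichment(net, core)
        curve = out["curve"]
        above = curve[curve.degree > curve.degree.min()]
        assert (above["core_fraction"] >= above["global_fraction"]).all()
        assert out["break_k"] is not None
        assert out["mean_degree_core"] > out["mean_degree_global"]

    def test_empty_core_errors(self):
        with pytest.raises(ValueError, match="core"):
            bipartite.core_degree_enrichment(self._net(), [])
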