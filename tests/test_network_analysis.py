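"""Centrality, shortest paths, and sensitivity sweeps.

Shortest paths are cross-checked against an independent min-plus
matrix-power oracle (repeated relaxation in pure numpy), degree centrality
against a brute-force double loop.
"""

import numpy as np
import pytest

from lingfcm.fcm_engine import ConceptMap, SimulationSettings
from lingfcm.knowledge_base import ValidationError
from lingfcm.network_analysis import (
    CentralitySettings,
    centrality_report,
    closeness_centrality,
    degree_centrality,
    sensitivity_sweep,
    shortest_paths,
    sweep_summary,
    to_graph,
)
from lingfcm.synthetic_data import SyntheticMapSpec, random_map


def brute_degree(cmap):
    """Oracle: explicit double loop over ordered pairs, self-loops excluded."""
    out = np.zeros(cmap.n)
    for x in range(cmap.n):
        for y in range(cmap.n):
            if x == y:
                continue
            out[x] += abs(cmap.W[x, y]) + abs(cmap.W[y, x])
    return out


def minplus_distances(cmap):
    """Oracle: min-plus relaxation to fixed point on d = 1/|w|."""
    n = cmap.n
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for j in range(n):
        for i in range(n):
            if i != j and cmap.W[j, i] != 0:
                D[j, i] = 1.0 / abs(cmap.W[j, i])
    for _ in range(n):
        # D[x,y] <- min_k D[x,k] + D[k,y]
        D = np.minimum(D, np.min(D[:, :, None] + D[None, :, :], axis=1))
    return D


@pytest.fixture(scope="module", params=list(range(10)))
def synthetic_map(request):
    seed = request.param
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(4, 11))
    return random_map(SyntheticMapSpec(
        n_concepts=n, density=float(rng.uniform(0.15, 0.5)),
        negative_fraction=0.4, seed=seed,
    ))


class TestDegreeCentrality:
    def test_matches_brute_force_on_synthetic_maps(self, synthetic_map):
        got = degree_centrality(synthetic_map).to_numpy()
        np.testing.assert_allclose(got, brute_degree(synthetic_map), atol=1e-12)

    @pytest.mark.parametrize(
        "concept,expected,tol",
        [
            ("Childhood Homelessness", 1.2500, 0.01),
            ("Non-Government Assistance", 0.5000, 0.005),
            ("Income", 1.3978, 0.02),
            ("Government Assistance", 1.3844, 0.02),
            ("Cost of Housing", 0.4984, 0.02),
        ],
    )
    def test_packaged_low_degree_rows(self, homeless_map, concept, expected, tol):
        deg = degree_centrality(homeless_map)
        assert deg[concept] == pytest.approx(expected, abs=tol)

    def test_isolated_concept_zero(self):
        cmap = ConceptMap(("A", "B", "C"),
                          np.array([[0, 0.5, 0], [0, 0, 0], [0, 0, 0.0]]))
        assert degree_centrality(cmap)["C"] == 0.0

    def test_invariant_to_sign_flips(self, synthetic_map):
        flipped = ConceptMap(synthetic_map.concepts, -synthetic_map.W)
        np.testing.assert_allclose(
            degree_centrality(synthetic_map).to_numpy(),
            degree_centrality(flipped).to_numpy(),
        )


class TestShortestPaths:
    def test_matches_minplus_oracle(self, synthetic_map):
        settings = CentralitySettings(big_m=100.0)
        got = shortest_paths(synthetic_map, settings).to_numpy()
        oracle = minplus_distances(synthetic_map)
        oracle[np.isinf(oracle)] = settings.big_m
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_max_single_edge_distance_is_four(self, homeless_map):
        W = homeless_map.W
        dists = 1.0 / np.abs(W[W != 0])
        assert dists.max() == pytest.approx(4.0, abs=1e-9)

    def test_cost_of_housing_reaches_only_outcome(self, homeless_map):
        settings = CentralitySettings(big_m=100.0)
        D = shortest_paths(homeless_map, settings)
        row = D.loc["Cost of Housing"]
        unreachable = (row == settings.big_m).sum()
        assert unreachable == 12          # all but itself and Homelessness
        assert row["Homelessness"] < settings.big_m

    def test_triangle_inequality_on_finite_entries(self, synthetic_map):
        D = minplus_distances(synthetic_map)    # true infinities
        n = synthetic_map.n
        for x in range(n):
            for y in range(n):
                for k in range(n):
                    assert D[x, y] <= D[x, k] + D[k, y] + 1e-9

    def test_increasing_weight_never_increases_distance(self, synthetic_map):
        boosted = synthetic_map.W.copy()
        mask = boosted != 0
        boosted[mask] = np.sign(boosted[mask]) * np.minimum(
            np.abs(boosted[mask]) * 1.5, 1.0
        )
        stronger = ConceptMap(synthetic_map.concepts, boosted)
        d0 = minplus_distances(synthetic_map)
        d1 = minplus_distances(stronger)
        finite = np.isfinite(d0)
        assert np.all(d1[finite] <= d0[finite] + 1e-9)


class TestClosenessCentrality:
    def test_cost_of_housing_value(self, homeless_map):
        # single outgoing edge; 12 unreachable concepts at Big-M
        close = closeness_centrality(homeless_map)
        w = abs(homeless_map.W[
            homeless_map.concept_index("Cost of Housing"),
            homeless_map.concept_index("Homelessness"),
        ])
        expected = 1.0 / (12 * 100.0 + 1.0 / w)
        assert close.loc["Cost of Housing", "closeness_raw"] == pytest.approx(
            expected, rel=1e-9
        )
        assert close.loc["Cost of Housing", "closeness_scaled"] == pytest.approx(
            8.32, abs=0.02
        )

    def test_matches_oracle_on_synthetic_maps(self, synthetic_map):
        settings = CentralitySettings(big_m=100.0)
        got = closeness_centrality(synthetic_map, settings)
        D = minplus_distances(synthetic_map)
        D[np.isinf(D)] = settings.big_m
        oracle = 1.0 / D.sum(axis=1)
        np.testing.assert_allclose(
            got["closeness_raw"].to_numpy(), oracle, rtol=1e-9
        )

    def test_single_concept_map_degenerate(self):
        cmap = ConceptMap(("A",), np.zeros((1, 1)))
        close = closeness_centrality(cmap)
        assert bool(close["degenerate"].iloc[0])

    def test_big_m_change_preserves_packaged_ranking(self, homeless_map):
        r100 = closeness_centrality(
            homeless_map, CentralitySettings(big_m=100)
        )["closeness_raw"].rank()
        r1000 = closeness_centrality(
            homeless_map, CentralitySettings(big_m=1000)
        )["closeness_raw"].rank()
        assert (r100 == r1000).all()

    def test_report_table(self, homeless_map, tmp_path):
        report = centrality_report(homeless_map)
        assert list(report.frame.columns) == [
            "concept", "degree", "closeness_raw", "closeness_scaled"
        ]
        assert len(report.frame) == 14
        report.to_csv(tmp_path / "centrality.csv")
        assert (tmp_path / "centrality.csv").exists()


class TestSensitivitySweep:
    def test_addiction_sweep_monotone_increasing(self, homeless_map):
        res = sensitivity_sweep(homeless_map, "Addiction")
        assert np.all(np.diff(res.homelessness_values) > 0)

    def test_two_node_toy_closed_form(self):
        cmap = ConceptMap(("Homelessness", "X"),
                          np.array([[0.0, 0.0], [0.5, 0.0]]))
        res = sensitivity_sweep(cmap, "X", iterations=1, baseline=0.01)
        np.testing.assert_allclose(
            res.homelessness_values, np.tanh(0.5 * res.grid), atol=1e-12
        )

    def test_concept_with_no_path_gives_constant_curve(self):
        # B feeds the outcome; C is disconnected from it
        W = np.zeros((3, 3))
        W[1, 0] = 0.6
        cmap = ConceptMap(("Outcome", "B", "C"), W)
        res = sensitivity_sweep(cmap, "C", outcome="Outcome")
        assert np.ptp(res.homelessness_values) == 0.0

    def test_sweeping_outcome_rejected(self, homeless_map):
        with pytest.raises(ValidationError):
            sensitivity_sweep(homeless_map, "Homelessness")

    def test_unknown_concept_rejected(self, homeless_map):
        with pytest.raises(ValidationError):
            sensitivity_sweep(homeless_map, "Quux")


class TestSweepSummary:
    def test_constant_curve_zero_iqr(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.6
        cmap = ConceptMap(("Outcome", "B", "C"), W)
        res = sensitivity_sweep(cmap, "C", outcome="Outcome")
        frame = sweep_summary([res])
        assert frame["iqr"].iloc[0] == 0.0

    def test_addiction_box_narrower_than_cost_of_housing(self, homeless_map):
        add = sensitivity_sweep(homeless_map, "Addiction")
        coh = sensitivity_sweep(homeless_map, "Cost of Housing")
        frame = sweep_summary([add, coh]).set_index("concept")
        assert frame.loc["Addiction", "iqr"] < frame.loc["Cost of Housing", "iqr"]

    def test_quartiles_match_reference_definition(self):
        import statistics

        values = np.array([0.1, 0.2, 0.35, 0.4, 0.41, 0.55, 0.6, 0.8, 0.85, 0.9])
        from lingfcm.network_analysis import SweepResult

        res = SweepResult(concept="X", grid=np.arange(10) + 1.0,
                          homelessness_values=values, baseline=0.01,
                          iterations=3)
        frame = sweep_summary([res])
        q1, q2, q3 = statistics.quantiles(values, n=4, method="inclusive")
        assert frame["q1"].iloc[0] == pytest.approx(q1)
        assert frame["median"].iloc[0] == pytest.approx(q2)
        assert frame["q3"].iloc[0] == pytest.approx(q3)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            sweep_summary([])


def test_graph_export_matches_edges(homeless_map):
    g = to_graph(homeless_map)
    assert g.number_of_nodes() == 14
    assert g.number_of_edges() == 31
    w = g["Addiction"]["Homelessness"]["weight"]
    assert w == pytest.approx(2 / 3, abs=1e-3)
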