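"""Synapse-strength classes and clock/oviposition bipartite connectivity."""

import pytest

from ovirhythm.connectome import (CLOCK_CLUSTERS, OVI_CLUSTERS, SynapseEdge,
                                  bidirectionality, bipartite_connectivity,
                                  classify_strength, default_cluster_map,
                                  example_clock_ovi_spec, export_network,
                                  generate_connectome_fixture, read_edges,
                                  read_network, write_edges)
from ovirhythm.records import RecordError
from ovirhythm.simulate import ParameterError

CLOCK = list(CLOCK_CLUSTERS)
OVI = list(OVI_CLUSTERS)


def _edge(pre, post, w, ids={}):
    return SynapseEdge(pre_id=ids.get(pre, 1), pre_name=pre,
                       post_id=ids.get(post, 2), post_name=post, weight=w)


@pytest.fixture(scope="module")
def cmap():
    return default_cluster_map()


@pytest.fixture(scope="module")
def fixture_edges():
    return generate_connectome_fixture(example_clock_ovi_spec(), seed=5)


@pytest.fixture(scope="module")
def fixture_report(fixture_edges, cmap):
    return bipartite_connectivity(fixture_edges, cmap, CLOCK, OVI)


def test_strength_thresholds_exhaustive():
    """Exact class boundaries: 0-2 weak, 3-9 intermediate, >9 strong."""
    for w in range(0, 21):
        expected = "weak" if w <= 2 else ("intermediate" if w <= 9 else "strong")
        assert classify_strength(w) == expected
    with pytest.raises(RecordError):
        classify_strength(-1)


def test_cluster_map_covers_clock_and_ovi_neurons(cmap):
    assert cmap.cluster_of("LNd4") == "E1" and cmap.cluster_of("LNd5") == "E1"
    assert cmap.cluster_of("LNd6") == "E2" and cmap.cluster_of("5th-sLNv") == "E2"
    assert {cmap.cluster_of(f"LNd{i}") for i in (1, 2, 3)} == {"E3"}
    assert cmap.cluster_of("LPN-L") == "LPN"
    assert sum(len(v) for v in CLOCK_CLUSTERS.values()) == 28
    assert sum(len(v) for v in OVI_CLUSTERS.values()) == 25
    # every name maps to exactly one cluster
    assert len(cmap.neuron_to_cluster) == 28 + 25


def test_fixture_realizes_requested_strength_classes(fixture_edges, cmap):
    e1_ovi = [e for e in fixture_edges
              if cmap.cluster_of(e.pre_name) == "E1"
              and cmap.cluster_of(e.post_name) == "oviIN"]
    assert e1_ovi and all(e.weight > 9 for e in e1_ovi)
    e3_pc1b = [e for e in fixture_edges
               if cmap.cluster_of(e.pre_name) == "E3"
               and cmap.cluster_of(e.post_name) == "pC1b"]
    assert e3_pc1b and all(3 <= e.weight <= 9 for e in e3_pc1b)


def test_empty_spec_and_unknown_class():
    assert generate_connectome_fixture({}, seed=0) == []
    with pytest.raises(ParameterError, match="strength class"):
        generate_connectome_fixture({("E1", "oviIN"): "huge"}, seed=0)


def test_fixture_topology_matches_known_circuit(fixture_report):
    """E1<->oviIN bidirectional; E2 contacts nothing on the oviposition
    side; E3 contacts only pC1b."""
    assert fixture_report.total("E1", "oviIN") > 9
    assert fixture_report.total("oviIN", "E1") > 0
    e2_pairs = [p for p in fixture_report.pair_totals if "E2" in p]
    assert e2_pairs == []
    e3_partners = {p[1] for p in fixture_report.pair_totals if p[0] == "E3"}
    assert e3_partners == {"pC1b"}


def test_weak_edges_are_excluded_everywhere(cmap):
    edges = [_edge("LNd4", "oviIN-R", 2), _edge("LNd5", "pC1a", 1)]
    report = bipartite_connectivity(edges, cmap, CLOCK, OVI)
    assert report.pair_totals == {}


def test_single_retained_pair_total(cmap):
    report = bipartite_connectivity([_edge("LNd1", "pC1b-R", 5)], cmap, CLOCK, OVI)
    assert report.pair_totals == {("E3", "pC1b"): 5}


def test_unresolved_names_are_collected_not_fatal(cmap):
    edges = [_edge("LNd4", "mystery-cell", 12), _edge("LNd4", "oviIN-R", 12)]
    report = bipartite_connectivity(edges, cmap, CLOCK, OVI)
    assert report.unresolved == ("mystery-cell",)
    assert report.total("E1", "oviIN") == 12


def test_same_side_edges_are_not_counted(cmap):
    report = bipartite_connectivity([_edge("LNd4", "LNd5", 20)], cmap, CLOCK, OVI)
    assert report.pair_totals == {}


def test_empty_sides_are_a_parameter_error(cmap):
    with pytest.raises(ParameterError):
        bipartite_connectivity([], cmap, [], OVI)


def test_min_class_strong_never_increases_totals(fixture_edges, cmap):
    inter = bipartite_connectivity(fixture_edges, cmap, CLOCK, OVI, "intermediate")
    strong = bipartite_connectivity(fixture_edges, cmap, CLOCK, OVI, "strong")
    for pair, total in strong.pair_totals.items():
        assert total <= inter.pair_totals[pair]


def test_report_is_invariant_to_edge_order(fixture_edges, cmap, rng):
    shuffled = [fixture_edges[i] for i in rng.permutation(len(fixture_edges))]
    a = bipartite_connectivity(fixture_edges, cmap, CLOCK, OVI)
    b = bipartite_connectivity(shuffled, cmap, CLOCK, OVI)
    assert a == b


def test_ovi_to_lpn_asymmetry(fixture_report):
    """The fixture realizes 135 oviIN->LPN vs 16 LPN->oviIN synapses; the
    dominant direction is into the clock."""
    w_ab, w_ba, dominant = bidirectionality(fixture_report, ("oviIN", "LPN"))
    assert (w_ab, w_ba) == (135, 16)
    assert dominant == "oviIN->LPN"


def test_bidirectionality_balanced_and_missing(cmap):
    edges = [_edge("LNd4", "oviIN-R", 7), _edge("oviIN-R", "LNd4", 7)]
    report = bipartite_connectivity(edges, cmap, CLOCK, OVI)
    assert bidirectionality(report, ("E1", "oviIN"))[2] == "balanced"
    assert bidirectionality(report, ("E2", "oviIN")) == (0, 0, "none")


@pytest.mark.parametrize("fmt", ["graphml", "json"])
def test_export_round_trips_through_own_reader(fixture_report, cmap, tmp_path, fmt):
    path = tmp_path / f"net.{fmt}"
    export_network(fixture_report, path, fmt=fmt, cmap=cmap)
    assert read_network(path, fmt=fmt) == fixture_report


def test_export_counts_and_empty_report(fixture_report, cmap, tmp_path):
    path = tmp_path / "net.graphml"
    export_network(fixture_report, path, fmt="graphml", cmap=cmap)
    back = read_network(path)
    assert back.neurons() == fixture_report.neurons()
    empty = bipartite_connectivity([], cmap, CLOCK, OVI)
    export_network(empty, tmp_path / "empty.graphml", cmap=cmap)
    assert read_network(tmp_path / "empty.graphml").pair_totals == {}
    with pytest.raises(ParameterError):
        export_network(empty, tmp_path / "x.xyz", fmt="xyz")


def test_dot_export_is_valid_text(fixture_report, cmap, tmp_path):
    path = tmp_path / "net.dot"
    export_network(fixture_report, path, fmt="dot", cmap=cmap)
    text = path.read_text()
    assert text.startswith("digraph") and '"LNd4" -> ' in text


def test_edge_csv_round_trip(fixture_edges, tmp_path):
    path = tmp_path / "edges.csv"
    write_edges(fixture_edges, path)
    header = path.read_text().splitlines()[0]
    assert header == "bodyId_pre,instance_pre,bodyId_post,instance_post,weight"
    assert read_edges(path) == fixture_edges
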