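#!/usr/bin/env python
"""Clock/oviposition bipartite connectivity on the bundled fixture.

Builds the synthetic edge list realizing the known cluster-level wiring
(E1<->oviIN, E3<->pC1b, oviIN<->LPN with a 135-vs-16 synapse asymmetry),
classifies connection strengths, extracts the bipartite clock/oviposition
network with weak edges excluded, summarizes bidirectionality per cluster
pair, and exports the network as GraphML and JSON.

To analyse a real neuPrint connection table instead, point
``ovirhythm connectome --edges <csv>`` at it; this script only
demonstrates the pipeline on the packaged synthetic fixture.
"""

import json
import pathlib

from ovirhythm.connectome import (CLOCK_CLUSTERS, OVI_CLUSTERS,
                                  bidirectionality, bipartite_connectivity,
                                  default_cluster_map, example_clock_ovi_spec,
                                  export_network, generate_connectome_fixture,
                                  write_edges)

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cmap = default_cluster_map()
    edges = generate_connectome_fixture(example_clock_ovi_spec(), seed=400)
    write_edges(edges, RESULTS / "connectome_fixture_edges.csv")

    report = bipartite_connectivity(edges, cmap, list(CLOCK_CLUSTERS),
                                    list(OVI_CLUSTERS))
    print(f"{len(edges)} fixture edges; retained cluster pairs:")
    summary = {}
    for (a, b), total in sorted(report.pair_totals.items()):
        n_edges = len(report.pair_edges[(a, b)])
        print(f"  {a} -> {b}: {total} synapses across {n_edges} neuron pairs")
        summary[f"{a}->{b}"] = total

    bidir = {}
    for pair in (("E1", "oviIN"), ("E3", "pC1b"), ("oviIN", "LPN")):
        w_ab, w_ba, dom = bidirectionality(report, pair)
        bidir["%s/%s" % pair] = {"forward": w_ab, "reverse": w_ba,
                                 "dominant": dom}
        print(f"  {pair[0]} <-> {pair[1]}: {w_ab} vs {w_ba} (dominant: {dom})")

    export_network(report, RESULTS / "clock_ovi_network.graphml", "graphml", cmap)
    export_network(report, RESULTS / "clock_ovi_network.json", "json", cmap)
    (RESULTS / "connectivity_summary.json").write_text(
        json.dumps({"pair_totals": summary, "bidirectionality": bidir}, indent=1))


if __name__ == "__main__":
    main()
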