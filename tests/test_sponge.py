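"""Seed-site scanning, miRNA selection, target intersection, network."""

import numpy as np
import pandas as pd
import pytest

from circsponge.diffexp import DEResult
from circsponge.sponge import (
    MiRNA,
    SiteCountTable,
    TargetRecord,
    build_network,
    integrate_targets,
    revcomp_rna,
    scan_sites,
    select_mirnas,
    site_count_table,
)

# miRNA whose seed (nt 2-7) is AGCUUA; target hexamer revcomp = UAAGCU.
# nt8 = G, so the m8 target base is C; nt1 is irrelevant to site classes.
MIR = MiRNA("mir-x", "UAGCUUAGGGAUCGAAUGCCAA")


def brute_force_scan(seq, mirna, circular=True):
    """Position-by-position oracle on the doubled sequence."""
    length = len(seq)
    hexamer = revcomp_rna(mirna.seed6)
    m8 = revcomp_rna(mirna.nt8) if mirna.nt8 is not None else None
    doubled = seq + seq if circular else seq
    out = []
    for c in range(length if circular else length - 5):
        if doubled[c : c + 6] != hexamer:
            continue
        if circular:
            has_m8 = m8 is not None and doubled[(c - 1) % length] == m8
            has_a1 = doubled[c + 6] == "A"
        else:
            has_m8 = m8 is not None and c > 0 and doubled[c - 1] == m8
            has_a1 = c + 6 < length and doubled[c + 6] == "A"
        if has_m8 and has_a1:
            st, span, start0 = "8mer", 8, (c - 1) % length
        elif has_m8:
            st, span, start0 = "7mer-m8", 7, (c - 1) % length
        elif has_a1:
            st, span, start0 = "7mer-A1", 7, c
        else:
            st, span, start0 = "6mer", 6, c
        wraps = circular and start0 + span > length
        out.append((start0 + 1, st, wraps))
    return sorted(out)


def _sites(found):
    return sorted((s.start, s.site_type, s.wraps_junction) for s in found)


class TestScanSites:
    def test_single_internal_hexamer_match(self):
        # G G G U A A G C U G G G -> target hexamer UAAGCU at position 4
        found = scan_sites("GGGUAAGCUGGG", MIR, circular=True)
        assert _sites(found) == [(4, "6mer", False)]

    def test_site_split_across_the_junction(self):
        # suffix "UA" + prefix "AGCU" reconstitute UAAGCU around the circle
        circ = "AGCUGGGGGUA"
        assert scan_sites(circ, MIR, circular=False) == []
        (site,) = scan_sites(circ, MIR, circular=True)
        assert (site.start, site.wraps_junction) == (10, True)

    def test_absent_seed_gives_no_sites(self):
        assert scan_sites("GGGGGGGGGGGG", MIR) == []

    def test_8mer_classification(self):
        # m8 target base C before the hexamer, A after it
        found = scan_sites("GG" + "C" + "UAAGCU" + "A" + "GG", MIR)
        assert _sites(found) == [(3, "8mer", False)]

    def test_7mer_classes(self):
        (m8_only,) = scan_sites("GG" + "C" + "UAAGCU" + "G" + "GG", MIR)
        assert (m8_only.site_type, m8_only.start) == ("7mer-m8", 3)
        (a1_only,) = scan_sites("GG" + "G" + "UAAGCU" + "A" + "GG", MIR)
        assert (a1_only.site_type, a1_only.start) == ("7mer-A1", 4)

    def test_linear_sites_subset_of_circular(self, rng):
        alphabet = np.array(list("ACGU"))
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(20, 60))))
            mir = MiRNA("m", "".join(rng.choice(alphabet, size=22)))
            lin = {(s.start, s.site_type) for s in scan_sites(seq, mir, circular=False)}
            circ_found = scan_sites(seq, mir, circular=True)
            circ = {(s.start, s.site_type) for s in circ_found}
            assert lin <= circ
            extra = circ - lin
            wrapping = {(s.start, s.site_type) for s in circ_found if s.wraps_junction}
            # non-wrapping circular-only sites arise only from boundary
            # promotion (flank context across the junction)
            for start, st in extra - wrapping:
                assert st != "6mer"

    def test_agrees_with_brute_force_on_random_pairs(self, rng):
        alphabet = np.array(list("ACGU"))
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(15, 80))))
            mir = MiRNA("m", "".join(rng.choice(alphabet, size=int(rng.integers(7, 23)))))
            assert _sites(scan_sites(seq, mir, circular=True)) == brute_force_scan(
                seq, mir, circular=True
            )

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-RNA"):
            scan_sites("ACGN", MIR)


class TestSiteCountTable:
    def test_counts_and_mean(self):
        # two UAAGCU hexamers, well separated, no flank promotion
        circ = {"c1": "CC" + "UAAGCU" + "CCCC" + "UAAGCU" + "CC"}
        out = site_count_table(circ, [MIR])
        assert out.table.loc["c1", "mir-x"] == 2
        assert out.mean_sites_per_circ == 2.0

    def test_empty_panel(self):
        out = site_count_table({"c1": "ACGUACGU"}, [])
        assert out.table.shape == (1, 0)

    def test_missing_sequence_reported_as_nan(self):
        with pytest.warns(UserWarning, match="no sequence"):
            out = site_count_table({"c1": "UAAGCUGG"}, [MIR], circ_ids=["c1", "c2"])
        assert np.isnan(out.table.loc["c2", "mir-x"])
        assert out.mean_sites_per_circ == out.table.loc["c1"].sum()


def _table(values, circ_ids, mirna_ids):
    return SiteCountTable(
        table=pd.DataFrame(values, index=circ_ids, columns=mirna_ids),
        mean_sites_per_circ=float(np.mean(np.sum(values, axis=1))),
    )


class TestSelectMirnas:
    def test_min_circ_threshold_excludes_nine_of_ten(self):
        circ_ids = [f"c{i}" for i in range(10)]
        vals = np.zeros((10, 2))
        vals[:9, 0] = 1  # miRNA a: sites in 9 circRNAs
        vals[:, 1] = 1   # miRNA b: sites in all 10
        with pytest.warns(UserWarning, match="pass"):
            out = select_mirnas(_table(vals, circ_ids, ["a", "b"]), circ_ids,
                                min_circ=10, top_k=5)
        assert list(out["mirna_id"]) == ["b"]

    def test_ties_broken_lexicographically(self):
        circ_ids = [f"c{i}" for i in range(3)]
        vals = np.ones((3, 2))
        out = select_mirnas(_table(vals, circ_ids, ["zzz", "aaa"]), circ_ids,
                            min_circ=1, top_k=2)
        assert list(out["mirna_id"]) == ["aaa", "zzz"]

    def test_ranking_by_up_circ_site_totals(self):
        circ_ids = ["u1", "u2", "d1"]
        vals = np.array([[1.0, 5.0], [1.0, 5.0], [9.0, 0.0]])
        out = select_mirnas(_table(vals, circ_ids, ["a", "b"]), ["u1", "u2"],
                            min_circ=1, top_k=2)
        # b dominates on upregulated circRNAs even though a has more sites overall
        assert list(out["mirna_id"]) == ["b", "a"]
        assert out["up_circ_site_total"].tolist() == [10.0, 2.0]

    def test_invariant_to_row_and_column_permutation(self, rng):
        circ_ids = [f"c{i}" for i in range(12)]
        mirna_ids = [f"m{i}" for i in range(6)]
        vals = rng.integers(0, 4, size=(12, 6)).astype(float)
        t = _table(vals, circ_ids, mirna_ids)
        up = circ_ids[:5]
        base = select_mirnas(t, up, min_circ=2, top_k=4)
        rp = rng.permutation(12)
        cp = rng.permutation(6)
        t2 = _table(vals[np.ix_(rp, cp)], [circ_ids[i] for i in rp],
                    [mirna_ids[j] for j in cp])
        out2 = select_mirnas(t2, up, min_circ=2, top_k=4)
        assert list(base["mirna_id"]) == list(out2["mirna_id"])

    def test_warns_when_fewer_than_top_k_survive(self):
        circ_ids = ["c0", "c1"]
        vals = np.ones((2, 1))
        with pytest.warns(UserWarning, match="pass"):
            out = select_mirnas(_table(vals, circ_ids, ["a"]), circ_ids,
                                min_circ=1, top_k=5)
        assert len(out) == 1


def _de(feature_id, lfc, adj_p):
    return DEResult(feature_id, lfc, 0.0, 10.0, adj_p, adj_p, 0.0)


class TestIntegrateTargets:
    TARGETS = [
        TargetRecord("m1", "g_up", -0.4),
        TargetRecord("m1", "g_down", -0.4),
        TargetRecord("m2", "g_up", -0.1),
        TargetRecord("m_unselected", "g_other", -0.9),
    ]

    def test_upregulated_target_included_with_annotations(self):
        out = integrate_targets(["m1", "m2"], self.TARGETS,
                                [_de("g_up", 1.5, 0.01)])
        assert out["gene_id"].tolist() == ["g_up"]
        assert out.loc[0, "mirnas"] == "m1,m2"

    def test_downregulated_target_excluded(self):
        out = integrate_targets(["m1"], self.TARGETS, [_de("g_down", -1.5, 0.01)])
        assert len(out) == 0

    def test_non_significant_and_unselected_excluded(self):
        de = [_de("g_up", 1.5, 0.2), _de("g_other", 2.0, 0.001)]
        out = integrate_targets(["m1", "m2"], self.TARGETS, de)
        assert len(out) == 0

    def test_context_score_cutoff(self):
        de = [_de("g_up", 1.5, 0.01)]
        out = integrate_targets(["m2"], self.TARGETS, de, max_context_score=-0.2)
        assert len(out) == 0  # m2 -> g_up scores -0.1, weaker than the cutoff

    def test_empty_target_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = integrate_targets(["m1"], [], [_de("g_up", 1.0, 0.01)])
        assert len(out) == 0


class TestBuildNetwork:
    def test_hand_counted_chain(self):
        tbl = _table(np.ones((2, 1)), ["c1", "c2"], ["m1"])
        affected = pd.DataFrame({"gene_id": ["g1", "g2", "g3"]})
        targets = [TargetRecord("m1", g, -0.3) for g in ["g1", "g2", "g3"]]
        net = build_network({"SCC": ["c1", "c2"]}, ["m1"], tbl, affected, targets)
        assert net.n_edges == 5  # 2 circ->miRNA + 3 miRNA->mRNA
        assert net.graph.nodes["m1"]["degree"] == 5
        assert net.graph.nodes["m1"]["log2_size"] == pytest.approx(np.log2(5))
        assert net.graph.nodes["c1"]["tissue_of_origin"] == "SCC"

    def test_no_affected_genes_means_no_mrna_layer(self):
        tbl = _table(np.ones((1, 1)), ["c1"], ["m1"])
        net = build_network({"SCC": ["c1"]}, ["m1"], tbl,
                            pd.DataFrame(columns=["gene_id"]), [])
        assert net.nodes_by_class("mRNA") == []
        assert net.n_edges == 1

    def test_every_edge_mirna_is_selected(self):
        tbl = _table(np.array([[1.0, 2.0]]), ["c1"], ["m1", "m2"])
        affected = pd.DataFrame({"gene_id": ["g1"]})
        targets = [TargetRecord("m1", "g1", -0.2), TargetRecord("m2", "g1", -0.2)]
        net = build_network({"SCC": ["c1"]}, ["m1"], tbl, affected, targets)
        for u, v in net.graph.edges:
            classes = {net.graph.nodes[u]["node_class"], net.graph.nodes[v]["node_class"]}
            assert "miRNA" in classes
            mirnas = [n for n in (u, v) if net.graph.nodes[n]["node_class"] == "miRNA"]
            assert mirnas == ["m1"]

    def test_simple_chain_round_trips_through_edge_list(self, tmp_path):
        from circsponge import io as cio

        tbl = _table(np.ones((1, 1)), ["c1"], ["m1"])
        affected = pd.DataFrame({"gene_id": ["g1"]})
        net = build_network({"SCC": ["c1"]}, ["m1"], tbl, affected,
                            [TargetRecord("m1", "g1", -0.2)])
        path = tmp_path / "net.tsv"
        cio.write_network(net, path, "edge_list")
        edges = pd.read_csv(path, sep="\t")
        assert len(edges) == 2 and set(edges["source_class"]) == {"circRNA", "miRNA"}
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")
        m1 = nodes.set_index("node_id").loc["m1"]
        assert m1["log2_size"] == pytest.approx(1.0)  # degree 2
        cio.write_network(net, tmp_path / "net.graphml", "graphml_like_xml")
        import networkx as nx

        g2 = nx.read_graphml(tmp_path / "net.graphml")
        assert g2.number_of_edges() == 2
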