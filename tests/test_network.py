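"""The internal patient–protein network: aberration calls, edges, export."""
from __future__ import annotations

from itertools import combinations

import pytest

from oncointegrate import network as nw
from oncointegrate.edks import ScoringConfig


def expr_doc(sid, values, i=0):
    return {
        "record_id": f"e{sid}", "sample_id": sid, "data_type": "expression",
        "source_file": "", "source_study": "S",
        "fields": {k: str(v) for k, v in values.items()},
    }


def cnv_doc(sid, values):
    return {
        "record_id": f"c{sid}", "sample_id": sid, "data_type": "cnv",
        "source_file": "", "source_study": "S",
        "fields": {k: str(v) for k, v in values.items()},
    }


def clin_doc(sid, **fields):
    return {
        "record_id": f"k{sid}", "sample_id": sid, "data_type": "clinical",
        "source_file": "", "source_study": "S",
        "fields": {k: str(v) for k, v in fields.items()},
    }


class TestCallAberrantProteins:
    def test_zero_variance_never_aberrant(self):
        docs = [expr_doc(f"p{i}", {"TP53": 1.0}) for i in range(5)]
        stats = nw.expression_cohort_stats(docs)
        assert nw.call_aberrant_proteins(docs[0], cohort_stats=stats) == set()

    def test_z_outlier_called(self):
        # independent mean/SD oracle: values [0,0,0,0,6]: mean 1.2, sd 2.4 -> z=+2.0
        docs = [expr_doc(f"p{i}", {"TP53": v}) for i, v in enumerate([0, 0, 0, 0, 6])]
        stats = nw.expression_cohort_stats(docs)
        mean, sd = stats["TP53"]
        assert mean == pytest.approx(1.2) and sd == pytest.approx(2.4)
        assert nw.call_aberrant_proteins(docs[4], cohort_stats=stats) == {"TP53"}
        assert nw.call_aberrant_proteins(docs[0], cohort_stats=stats) == set()

    def test_cnv_thresholds(self):
        cfg = nw.AberrationConfig()
        doc = cnv_doc("p1", {"A": 0.0, "B": 0.5, "C": -0.6})
        assert nw.call_aberrant_proteins(doc, cfg) == {"B", "C"}

    def test_non_numeric_skipped(self, caplog):
        doc = cnv_doc("p1", {"A": "NA", "B": 1.0})
        with caplog.at_level("WARNING"):
            assert nw.call_aberrant_proteins(doc) == {"B"}
        assert any("non-numeric" in m for m in caplog.messages)

    def test_empty_record(self):
        assert nw.call_aberrant_proteins(cnv_doc("p1", {})) == set()


class TestBuildInternalNetwork:
    def test_disjoint_proteins_no_shared_edges(self):
        docs = [clin_doc("p1"), clin_doc("p2"),
                cnv_doc("p1", {"A": 1.0}), cnv_doc("p2", {"B": 1.0})]
        net = nw.build_internal_network(docs, scoring=ScoringConfig(trusted_threshold=1))
        kinds = [r.kind for r in net.relations()]
        assert nw.KIND_PATIENT_PATIENT_SHARED not in kinds

    def test_shared_protein_pairwise_edges(self):
        # 3 patients aberrant in TP53; threshold 2 makes it trusted -> C(3,2) edges
        docs = [clin_doc(f"p{i}") for i in range(3)]
        docs += [cnv_doc(f"p{i}", {"TP53": 1.0}) for i in range(3)]
        net = nw.build_internal_network(docs, scoring=ScoringConfig(trusted_threshold=2))
        rels = net.relations()
        pp = [r for r in rels if r.kind == nw.KIND_PATIENT_PATIENT_SHARED]
        assert len(pp) == 3
        freq = {r.frequency for r in rels if r.kind == nw.KIND_PATIENT_PROTEIN_CNV}
        assert freq == {3}

    def test_orphan_molecular_record_kept(self, caplog):
        docs = [clin_doc("p1"), cnv_doc("p1", {"A": 1.0}), cnv_doc("px", {"A": 1.0})]
        with caplog.at_level("WARNING"):
            net = nw.build_internal_network(docs)
        assert "px" in net.patients
        assert any("orphan" in m for m in caplog.messages)

    def test_bipartite_internal_layer(self, linked_network):
        patients = linked_network.patients
        proteins = linked_network.proteins
        for r in linked_network.relations():
            if r.kind in (nw.KIND_PATIENT_PROTEIN_EXPR, nw.KIND_PATIENT_PROTEIN_CNV):
                assert {r.source, r.target} <= patients | proteins
                assert len({r.source, r.target} & patients) == 1
                assert len({r.source, r.target} & proteins) == 1

    def test_recovers_planted_modules(self, documents, manifest):
        net = nw.build_internal_network(documents)
        for sid, truth in manifest["aberrations"].items():
            found = {
                nbr
                for _, nbr, d in net.graph.edges(sid, data=True)
                if d["kind"] in (nw.KIND_PATIENT_PROTEIN_EXPR, nw.KIND_PATIENT_PROTEIN_CNV)
            } if sid in net.graph else set()
            assert found == set(truth)

    def test_frequency_equals_bruteforce_carriers(self, documents, linked_network):
        stats = nw.expression_cohort_stats(documents)
        brute: dict[str, set] = {}
        for doc in documents:
            if doc["data_type"] in ("expression", "cnv"):
                for prot in nw.call_aberrant_proteins(doc, cohort_stats=stats):
                    brute.setdefault(prot, set()).add(doc["sample_id"])
        for prot in linked_network.proteins:
            carriers = nw.patients_by_protein(linked_network, prot)
            assert carriers == brute.get(prot, set())

    def test_monotone_frequency_under_added_patient(self):
        docs = [clin_doc(f"p{i}") for i in range(4)]
        docs += [cnv_doc(f"p{i}", {"A": 1.0}) for i in range(3)]
        net1 = nw.build_internal_network(docs)
        docs.append(cnv_doc("p3", {"A": 1.0}))
        net2 = nw.build_internal_network(docs)
        f1 = [r.frequency for r in net1.relations() if r.target == "A"]
        f2 = [r.frequency for r in net2.relations() if r.target == "A"]
        assert min(f2) >= max(f1)


class TestPatientsByProtein:
    def test_absent_protein(self, linked_network):
        assert nw.patients_by_protein(linked_network, "NOSUCHGENE") == set()

    def test_planted_carriers(self, linked_network, manifest):
        mod = manifest["modules"][0]
        protein = mod["proteins"][0]
        assert nw.patients_by_protein(linked_network, protein) == set(mod["carriers"])

    def test_subset_of_patients(self, linked_network):
        for protein in list(linked_network.proteins)[:5]:
            assert nw.patients_by_protein(linked_network, protein) <= linked_network.patients


class TestExportImport:
    def _edge_multiset(self, net):
        return sorted(
            (tuple(sorted((r.source, r.target))), r.kind, r.origin, r.frequency,
             round(r.score, 12), r.trusted)
            for r in net.relations()
        )

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_roundtrip(self, tmp_path, fmt, linked_network):
        path = tmp_path / f"net.{fmt}"
        nw.export_network(linked_network, path, fmt)
        back = nw.import_network(path, fmt)
        assert self._edge_multiset(back) == self._edge_multiset(linked_network)
        assert back.patients == linked_network.patients
        assert back.proteins == linked_network.proteins

    def test_empty_network_valid(self, tmp_path):
        net = nw.IntegratedNetwork()
        path = nw.export_network(net, tmp_path / "empty.graphml")
        assert nw.import_network(path).graph.number_of_edges() == 0

    def test_tsv_byte_stable(self, tmp_path, linked_network):
        p1 = nw.export_network(linked_network, tmp_path / "a.tsv", "tsv")
        p2 = nw.export_network(linked_network, tmp_path / "b.tsv", "tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_format_lists_supported(self, tmp_path):
        with pytest.raises(ValueError, match="graphml"):
            nw.export_network(nw.IntegratedNetwork(), tmp_path / "x", "sqlite")
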