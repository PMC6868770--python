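"""Per-patient enrichment: rings, brute-force traversal oracle, features."""
from __future__ import annotations

import numpy as np
import pytest

from oncointegrate import enrichment as en, network as nw
from oncointegrate.errors import InsufficientCohortError, TICFUndefinedError


def random_small_network(rng: np.random.Generator) -> nw.IntegratedNetwork:
    """Random patient–protein network with <= 30 nodes and random trust flags."""
    n_pat = int(rng.integers(3, 16))
    n_prot = int(rng.integers(2, 15))
    net = nw.IntegratedNetwork()
    patients = [f"p{i:02d}" for i in range(n_pat)]
    proteins = [f"G{i:02d}" for i in range(n_prot)]
    for p in patients:
        net.add_patient(p)
    for g in proteins:
        net.add_protein(g)
    for p in patients:
        for g in proteins:
            if rng.random() < 0.25:
                net.graph.add_edge(
                    p, g, key=nw.KIND_PATIENT_PROTEIN_CNV,
                    kind=nw.KIND_PATIENT_PROTEIN_CNV, origin="internal",
                    frequency=1, score=1.0, trusted=bool(rng.random() < 0.6),
                )
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            if rng.random() < 0.15:
                net.graph.add_edge(
                    a, b, key=nw.KIND_PROTEIN_PROTEIN_LINKED,
                    kind=nw.KIND_PROTEIN_PROTEIN_LINKED, origin="linked",
                    frequency=1, score=0.5, trusted=bool(rng.random() < 0.5),
                    provider_score=0.9,
                )
    return net


def brute_force_rings(net: nw.IntegratedNetwork, ring0: set[str]):
    """Independent breadth-2 traversal over trusted edges, from raw edge lists."""
    internal = [
        (u, v, d) for u, v, d in net.graph.edges(data=True)
        if d["kind"] in (nw.KIND_PATIENT_PROTEIN_EXPR, nw.KIND_PATIENT_PROTEIN_CNV)
    ]
    linked = [
        (u, v, d) for u, v, d in net.graph.edges(data=True)
        if d["kind"] == nw.KIND_PROTEIN_PROTEIN_LINKED
    ]
    patients = net.patients

    def endpoints(u, v):
        return (u, v) if u in patients else (v, u)

    def group_proteins(group):
        return {
            prot for u, v, d in internal if d["trusted"]
            for pat, prot in [endpoints(u, v)] if pat in group
        }

    def carriers(prots):
        return {
            pat for u, v, d in internal
            for pat, prot in [endpoints(u, v)] if prot in prots
        }

    ring1 = carriers(group_proteins(ring0)) - ring0
    cohort = ring0 | ring1
    prots = group_proteins(cohort)
    partners = set()
    for u, v, d in linked:
        if d["trusted"]:
            if u in prots:
                partners.add(v)
            if v in prots:
                partners.add(u)
    partners -= prots
    ring2 = carriers(partners) - cohort
    return ring1, ring2


class TestSeedGroup:
    def test_group_membership(self):
        groups = {"a": 0, "b": 0, "c": 1}
        assert en.seed_group("a", groups) == {"a", "b"}
        assert en.seed_group("c", groups) == {"c"}

    def test_undefined_seed_errors(self):
        with pytest.raises(TICFUndefinedError):
            en.seed_group("zz", {"a": 0})

    def test_ring0_union_partitions_cohort(self, ticf_table):
        union = set()
        for seed in ticf_table.groups:
            union |= en.seed_group(seed, ticf_table.groups)
        assert union == set(ticf_table.groups)


class TestRingExpansion:
    def test_no_trusted_proteins_empty_ring1(self):
        rng = np.random.default_rng(0)
        net = random_small_network(rng)
        for _, _, d in net.graph.edges(data=True):
            d["trusted"] = False
        assert en.expand_internal({"p00"}, net) == set()

    def test_rings_disjoint_from_ring0(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_small_network(rng)
            ring0 = {"p00", "p01"}
            ring1 = en.expand_internal(ring0, net)
            assert ring1 & ring0 == set()
            ring2 = en.expand_linked(ring0 | ring1, net)
            assert ring2 & (ring0 | ring1) == set()

    def test_matches_bruteforce_oracle_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net = random_small_network(rng)
            patients = sorted(net.patients)
            k = int(rng.integers(1, max(2, len(patients) // 2)))
            ring0 = set(rng.choice(patients, size=k, replace=False).tolist())
            ring1 = en.expand_internal(ring0, net)
            ring2 = en.expand_linked(ring0 | ring1, net)
            oracle1, oracle2 = brute_force_rings(net, ring0)
            assert ring1 == oracle1
            assert ring2 == oracle2
            # monotone enrichment
            assert ring0 <= ring0 | ring1 <= ring0 | ring1 | ring2

    def test_planted_module_reached_through_linked_layer(
        self, linked_network, manifest, ticf_table, documents
    ):
        # a satellite protein's carriers are reachable only via the linked hop
        mod = manifest["modules"][0]
        sat_carriers = set(mod["satellite_carriers"])
        core_carriers = set(mod["carriers"])
        ring0 = core_carriers
        ring1 = en.expand_internal(ring0, linked_network)
        ring2 = en.expand_linked(ring0 | ring1, linked_network)
        assert sat_carriers - (ring0 | ring1) <= ring2

    def test_untrusted_linked_edges_contribute_nothing(self):
        rng = np.random.default_rng(7)
        net = random_small_network(rng)
        for _, _, d in net.graph.edges(data=True):
            if d["kind"] == nw.KIND_PROTEIN_PROTEIN_LINKED:
                d["trusted"] = False
        assert en.expand_linked(set(net.patients), net) == set()


class TestAssembleFeatures:
    def test_full_cohort_features(self, documents, ticf_table, linked_network):
        seed = sorted(ticf_table.groups)[0]
        cohort = en.enrich_patient(seed, documents, ticf_table, linked_network)
        assert seed in cohort.ring0
        assert cohort.feature_matrix.shape[0] == len(cohort.patients)
        # non-degenerate columns are z-normalized
        X = cohort.feature_matrix.to_numpy()
        for j in range(X.shape[1]):
            col = X[:, j]
            if col.std() > 0:
                assert abs(col.mean()) < 1e-9
                assert abs(col.var() - 1) < 1e-9
            else:
                assert np.all(col == 0.0)

    def test_deduplication_keeps_single_row(self, documents, ticf_table, linked_network):
        seed = sorted(ticf_table.groups)[0]
        cohort = en.build_cohort(seed, ticf_table, linked_network)
        duplicated = documents + [d for d in documents if d["data_type"] == "clinical"][:5]
        enriched = en.assemble_features(cohort, duplicated, ticf_table, linked_network)
        assert enriched.feature_matrix.index.is_unique

    def test_insufficient_targets_error(self, ticf_table, linked_network):
        seed = sorted(ticf_table.groups)[0]
        cohort = en.build_cohort(seed, ticf_table, linked_network)
        no_survival_docs = [
            {"record_id": f"k{s}", "sample_id": s, "data_type": "clinical",
             "source_file": "", "source_study": "S", "fields": {}}
            for s in sorted(cohort.patients)
        ]
        with pytest.raises(InsufficientCohortError):
            en.assemble_features(cohort, no_survival_docs, ticf_table, linked_network)

    def test_determinism(self, documents, ticf_table, linked_network):
        seed = sorted(ticf_table.groups)[10]
        a = en.enrich_patient(seed, documents, ticf_table, linked_network)
        b = en.enrich_patient(seed, documents, ticf_table, linked_network)
        assert a.feature_matrix.equals(b.feature_matrix)
        assert a.targets.equals(b.targets)
        assert (a.ring0, a.ring1, a.ring2) == (b.ring0, b.ring1, b.ring2)
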