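"""Vertical integration: the two-layer patient–protein relation network.

Builds the internal layer from expression z-score and copy-number
aberration calls, adds the linked layer from an external-knowledge
fixture, and keeps only trusted relations (supported by more than 10
distinct patients).
"""
import tempfile
from pathlib import Path

from oncointegrate import edks, network as nw, semistructure as ss, synthetic

out = Path(tempfile.mkdtemp())
cfg = synthetic.SyntheticConfig(seed=7)
manifest = synthetic.generate_cohort(cfg, out)
synthetic.generate_edks_fixture(cfg, manifest, out / "edks.tsv")

docs = []
for study, files in sorted(manifest["studies"].items()):
    for data_type in ss.DATA_TYPES:
        records = ss.read_records(out / files[data_type], data_type, study)
        semi = ss.fold_records(ss.empty_semistructure(data_type), records)
        docs.extend(ss.apply_schema(r, semi) for r in records)

scoring = edks.ScoringConfig()  # internal 1.0 > linked 0.5, trust at >10 patients
net = nw.build_internal_network(docs, scoring=scoring)
print(f"internal layer: {len(net.patients)} patients, {len(net.proteins)} "
      f"aberrant proteins, {net.graph.number_of_edges()} relations")

net = edks.mark_trusted(net, scoring)
net = nw.add_linked_layer(net, edks.FixtureProvider.from_tsv(out / "edks.tsv"), scoring)
net = edks.prune_untrusted(net, scoring)
relations = net.relations()
linked = [r for r in relations if r.origin == "linked"]
print(f"after linking + pruning: {len(relations)} relations, "
      f"{sum(r.trusted for r in relations)} trusted, {len(linked)} linked survived")

# every protein's carriers; a trusted protein is carried by >10 patients
protein = manifest["modules"][0]["proteins"][0]
carriers = nw.patients_by_protein(net, protein)
print(f"\nprotein {protein}: carried by {len(carriers)} patients "
      f"(planted: {len(manifest['modules'][0]['carriers'])})")
print("Carriers of one trusted protein are exactly the patients the "
      "generator planted in that module — the network recovers the raw signal.")
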