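"""Shared fixtures: one synthetic two-study cohort built once per session."""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pytest

from oncointegrate import edks, network, semistructure, synthetic, ticf


@pytest.fixture(scope="session")
def _cohort(tmp_path_factory) -> tuple[Path, dict]:
    """Default synthetic scenario written to disk, with the EDKS fixture."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = synthetic.SyntheticConfig(seed=11)
    manifest = synthetic.generate_cohort(cfg, out)
    synthetic.generate_edks_fixture(cfg, manifest, out / "edks.tsv")
    return out, manifest


@pytest.fixture(scope="session")
def cohort_dir(_cohort) -> Path:
    return _cohort[0]


@pytest.fixture(scope="session")
def manifest(_cohort) -> dict:
    return _cohort[1]


@pytest.fixture(scope="session")
def documents(cohort_dir, manifest) -> list[dict]:
    """Schema-validated documents for the whole two-study cohort."""
    docs: list[dict] = []
    for study, files in sorted(manifest["studies"].items()):
        for data_type in semistructure.DATA_TYPES:
            records = semistructure.read_records(
                cohort_dir / files[data_type], data_type, study
            )
            semi = semistructure.fold_records(
                semistructure.empty_semistructure(data_type), records
            )
            docs.extend(semistructure.apply_schema(r, semi) for r in records)
    return docs


@pytest.fixture(scope="session")
def linked_network(documents, cohort_dir) -> network.IntegratedNetwork:
    """Internal network + linked layer, trusted flags set, untrusted pruned."""
    scoring = edks.ScoringConfig()
    net = network.build_internal_network(documents, scoring=scoring)
    net = edks.mark_trusted(net, scoring)
    net = network.add_linked_layer(
        net, edks.FixtureProvider.from_tsv(cohort_dir / "edks.tsv"), scoring
    )
    return edks.prune_untrusted(net, scoring)


@pytest.fixture(scope="session")
def ticf_table(documents) -> ticf.TICFTable:
    clinical = [d for d in documents if d["data_type"] == "clinical"]
    return ticf.build_ticf_table(clinical)
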