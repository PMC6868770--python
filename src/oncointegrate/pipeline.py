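"""End-to-end pipeline: simulate → ingest → network → link → TICF → predict.

One master seed drives every stage; completed stages are skipped on rerun
(resume) unless forced.  Each stage persists its artifact under the run
directory and the summary report echoes the effective configuration and
the headline counts.
"""
from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import edks, enrichment, network, semistructure, survival, synthetic, ticf
from .errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "simulate": True,
    "inputs": None,            # dir of pre-existing fixture files (with manifest.json)
    "aberration": {},          # AberrationConfig overrides
    "scoring": {},             # ScoringConfig overrides
    "ticf_k": 5,
    "folds": 5,
    "models": list(survival.FAMILIES),
    "ablate": True,
    "provider": "fixture",
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG)


def validate_config(config: Optional[dict]) -> dict:
    """Merge with defaults; reject unknown keys and malformed values."""
    config = dict(config or {})
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    if not isinstance(merged["seed"], int):
        raise ConfigError("seed must be an integer")
    if merged["provider"] not in ("fixture", "online"):
        raise ConfigError("provider must be 'fixture' or 'online'")
    if not 2 <= int(merged["folds"]):
        raise ConfigError("folds must be >= 2")
    unknown_models = set(merged["models"]) - set(survival.FAMILIES)
    if unknown_models:
        raise ConfigError(f"unknown model families: {sorted(unknown_models)}")
    for section, cls in (("aberration", network.AberrationConfig),
                         ("scoring", edks.ScoringConfig)):
        try:
            cls(**merged[section])
        except TypeError as exc:
            raise ConfigError(f"bad {section} config: {exc}") from exc
    return merged


def _stage_done(path: Path, force: bool) -> bool:
    return path.exists() and not force


def run_pipeline(config: Optional[dict], out_dir: str | Path, force: bool = False) -> dict:
    """Run every stage in dependency order; return the summary report.

    A stage whose artifact already exists is skipped unless *force*; a
    failing stage raises with its name after partial artifacts have been
    persisted.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    summary: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}

    # -- stage: simulate --------------------------------------------------
    fixtures = Path(cfg["inputs"]) if cfg["inputs"] else out / "fixtures"
    manifest_path = fixtures / "manifest.json"
    edks_path = fixtures / "edks.tsv"
    if cfg["simulate"] and not _stage_done(manifest_path, force):
        try:
            sim_cfg = replace(synthetic.SyntheticConfig(), seed=seed)
            manifest = synthetic.generate_cohort(sim_cfg, fixtures)
            synthetic.generate_edks_fixture(sim_cfg, manifest, edks_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    if not manifest_path.exists():
        raise RuntimeError("stage 'simulate' failed: no fixtures or manifest found")
    manifest = json.loads(manifest_path.read_text())
    summary["stages"]["simulate"] = {"n_patients": len(manifest["patients"])}

    # -- stage: ingest -----------------------------------------------------
    store = semistructure.DocumentStore(out / "store")
    ingest_marker = store.root / "clinical.jsonl"
    if not _stage_done(ingest_marker, force):
        try:
            for data_type in semistructure.DATA_TYPES:
                docs: list[dict] = []
                semi = semistructure.empty_semistructure(data_type)
                for study, files in sorted(manifest["studies"].items()):
                    recs = semistructure.read_records(
                        fixtures / files[data_type], data_type, study
                    )
                    semi = semistructure.fold_records(semi, recs)
                    docs.extend(semistructure.apply_schema(r, semi) for r in recs)
                store.write(data_type, docs)
                semistructure.semistructure_to_json(
                    semi, store.root / f"{data_type}.semistructure.json"
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc
    try:
        documents = store.read_all()
    except Exception as exc:
        raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc
    summary["stages"]["ingest"] = {
        "records": len(documents),
        "by_type": {dt: len(store.read(dt)) for dt in semistructure.DATA_TYPES},
    }

    # -- stage: build-network ---------------------------------------------
    scoring = edks.ScoringConfig(**cfg["scoring"])
    aberration = network.AberrationConfig(**cfg["aberration"])
    net_path = out / "network.graphml"
    if not _stage_done(net_path, force):
        try:
            net = network.build_internal_network(documents, aberration, scoring)
            network.export_network(net, net_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'build-network' failed: {exc}") from exc
    net = network.import_network(net_path)

    # -- stage: link -------------------------------------------------------
    linked_path = out / "network_linked.graphml"
    if not _stage_done(linked_path, force):
        try:
            provider = edks.FixtureProvider.from_tsv(edks_path)
            net = edks.mark_trusted(net, scoring)
            net = network.add_linked_layer(net, provider, scoring)
            net = edks.prune_untrusted(net, scoring)
            network.export_network(net, linked_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'link' failed: {exc}") from exc
    net = network.import_network(linked_path)
    relations = net.relations()
    summary["stages"]["network"] = {
        "patients": len(net.patients),
        "proteins": len(net.proteins),
        "edges": len(relations),
        "trusted_edges": sum(1 for r in relations if r.trusted),
        "linked_edges": sum(1 for r in relations if r.origin == edks.ORIGIN_LINKED),
    }

    # -- stage: ticf -------------------------------------------------------
    ticf_path = out / "ticf.tsv"
    clinical = [d for d in documents if d["data_type"] == "clinical"]
    try:
        table = ticf.build_ticf_table(clinical, k=cfg["ticf_k"])
    except Exception as exc:
        raise RuntimeError(f"stage 'ticf' failed: {exc}") from exc
    if not _stage_done(ticf_path, force):
        lines = ["sample_id\tcomposite\tnormalized\tgroup"]
        for sid in sorted(table.values):
            v = table.values[sid]
            lines.append(f"{sid}\t{v.composite}\t{v.normalized!r}\t{table.groups[sid]}")
        ticf_path.write_text("\n".join(lines) + "\n")
    summary["stages"]["ticf"] = {
        "defined": len(table.values),
        "undefined": len(table.undefined),
        "groups": cfg["ticf_k"],
    }

    # -- stage: predict ----------------------------------------------------
    report_path = out / "cv_report.json"
    specs = [survival.ModelSpec(family=f, seed=seed) for f in cfg["models"]]
    if _stage_done(report_path, force):
        payload = json.loads(report_path.read_text())
    else:
        try:
            X, y = survival.build_design_matrix(documents, net, table)
            report = survival.cross_validate(X, y, specs=specs, k=cfg["folds"], seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'predict' failed: {exc}") from exc
        report.to_json(report_path)
        payload = report.to_dict()
    summary["stages"]["predict"] = {
        "n": payload["n"],
        "k": payload["k"],
        "mean_test_r2": {
            f: payload["models"][f]["test"]["r2"]["mean"] for f in payload["models"]
        },
    }

    # -- stage: ablate -----------------------------------------------------
    if cfg["ablate"]:
        ablation_path = out / "ablation.json"
        if _stage_done(ablation_path, force):
            ab_payload = json.loads(ablation_path.read_text())
        else:
            try:
                reports = survival.run_ablation(
                    documents, net, table, specs=specs, k=cfg["folds"], seed=seed
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'ablate' failed: {exc}") from exc
            ab_payload = {name: rep.to_dict() for name, rep in reports.items()}
            ablation_path.write_text(json.dumps(ab_payload, indent=2, sort_keys=True) + "\n")
        summary["stages"]["ablate"] = {
            name: float(np.mean([
                rep["models"][f]["test"]["r2"]["mean"] for f in sorted(rep["models"])
            ]))
            for name, rep in ab_payload.items()
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
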