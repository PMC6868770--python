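"""Vertical integration: the two-layer patient–protein relation network.

The internal layer is derived from raw data: one node per patient, one per
protein (Hugo symbol), and a patient–protein edge for every aberration
call (expression z-score outliers, copy-number gains/losses).  A protein's
*frequency* is the number of distinct patients carrying it; proteins
supported by more than the trusted threshold of patients are trusted, and
patients sharing at least one trusted protein are connected by
patient–patient similarity edges.  The linked layer (protein–protein
relations from external knowledge sources) is added by
:func:`add_linked_layer`.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from . import edks
from .edks import ORIGIN_INTERNAL, ORIGIN_LINKED, RelationProvider, ScoringConfig

logger = logging.getLogger(__name__)

KIND_PATIENT_PROTEIN_EXPR = "patient_protein_expr"
KIND_PATIENT_PROTEIN_CNV = "patient_protein_cnv"
KIND_PROTEIN_PROTEIN_LINKED = "protein_protein_linked"
KIND_PATIENT_PATIENT_SHARED = "patient_patient_shared"

RELATION_KINDS = (
    KIND_PATIENT_PROTEIN_EXPR,
    KIND_PATIENT_PROTEIN_CNV,
    KIND_PROTEIN_PROTEIN_LINKED,
    KIND_PATIENT_PATIENT_SHARED,
)

NODE_PATIENT = "patient"
NODE_PROTEIN = "protein"


def normalize_symbol(symbol: str) -> str:
    """Hugo symbols are upper-cased, stripped node keys."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class AberrationConfig:
    """Cutoffs turning molecular values into aberration calls.

    Expression values are standardized per protein across the cohort and
    called aberrant at |z| >= ``z_abs_cutoff``; copy-number log-ratios are
    called at >= ``cn_gain`` or <= ``cn_loss``.
    """

    z_abs_cutoff: float = 2.0
    cn_gain: float = 0.5
    cn_loss: float = -0.5

    def __post_init__(self) -> None:
        if self.z_abs_cutoff <= 0:
            raise ValueError("z_abs_cutoff must be positive")
        if self.cn_gain <= self.cn_loss:
            raise ValueError("cn_gain must exceed cn_loss")


@dataclass(frozen=True)
class Relation:
    """A typed, scored, origin-tagged edge of the integrated network."""

    source: str
    target: str
    kind: str
    origin: str
    frequency: int
    score: float
    trusted: bool
    provider_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in RELATION_KINDS:
            raise ValueError(f"unknown relation kind {self.kind!r}")
        if self.origin == ORIGIN_LINKED and self.kind != KIND_PROTEIN_PROTEIN_LINKED:
            raise ValueError("origin=linked only for protein_protein_linked edges")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass
class IntegratedNetwork:
    """Patient and protein nodes with a typed edge multiset.

    Backed by an undirected :class:`networkx.MultiGraph`; parallel edges
    between the same pair are distinguished by their kind (the multigraph
    key), so duplicate (source, target, kind) triples cannot exist —
    repeated observations accumulate into the frequency instead.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    trusted_threshold: int = 10

    # -- nodes ------------------------------------------------------------
    @property
    def patients(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == NODE_PATIENT}

    @property
    def proteins(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == NODE_PROTEIN}

    def add_patient(self, sample_id: str) -> None:
        self.graph.add_node(sample_id, kind=NODE_PATIENT)

    def add_protein(self, symbol: str) -> None:
        self.graph.add_node(normalize_symbol(symbol), kind=NODE_PROTEIN)

    # -- edges ------------------------------------------------------------
    def add_relation(self, rel: Relation) -> None:
        if self.graph.has_edge(rel.source, rel.target, key=rel.kind):
            raise ValueError(
                f"duplicate relation ({rel.source}, {rel.target}, {rel.kind})"
            )
        self.graph.add_edge(
            rel.source,
            rel.target,
            key=rel.kind,
            kind=rel.kind,
            origin=rel.origin,
            frequency=rel.frequency,
            score=rel.score,
            trusted=rel.trusted,
            **(
                {"provider_score": rel.provider_score}
                if rel.provider_score is not None
                else {}
            ),
        )

    def relations(self) -> list[Relation]:
        out = []
        for u, v, k, data in self.graph.edges(keys=True, data=True):
            out.append(
                Relation(
                    source=u,
                    target=v,
                    kind=data["kind"],
                    origin=data["origin"],
                    frequency=int(data["frequency"]),
                    score=float(data["score"]),
                    trusted=bool(data["trusted"]),
                    provider_score=data.get("provider_score"),
                )
            )
        return out

    def trusted_proteins(self) -> set[str]:
        """Proteins with at least one trusted internal patient–protein edge."""
        out = set()
        for u, v, data in self.graph.edges(data=True):
            if (
                data["kind"] in (KIND_PATIENT_PROTEIN_EXPR, KIND_PATIENT_PROTEIN_CNV)
                and data.get("trusted", False)
            ):
                for node in (u, v):
                    if self.graph.nodes[node].get("kind") == NODE_PROTEIN:
                        out.add(node)
        return out


# ---------------------------------------------------------------------------
# aberration calling
# ---------------------------------------------------------------------------

def expression_cohort_stats(documents: Iterable[Mapping]) -> dict[str, tuple[float, float]]:
    """Per-protein cohort mean and population SD over expression documents."""
    values: dict[str, list[float]] = {}
    for doc in documents:
        if doc.get("data_type") != "expression":
            continue
        for symbol, raw in doc.get("fields", {}).items():
            try:
                value = float(raw)
            except (TypeError, ValueError):
                continue
            values.setdefault(normalize_symbol(symbol), []).append(value)
    stats = {}
    for symbol, xs in values.items():
        n = len(xs)
        mean = sum(xs) / n
        var = sum((x - mean) ** 2 for x in xs) / n
        stats[symbol] = (mean, math.sqrt(var))
    return stats


def call_aberrant_proteins(
    document: Mapping,
    thresholds: AberrationConfig = AberrationConfig(),
    cohort_stats: Optional[Mapping[str, tuple[float, float]]] = None,
) -> set[str]:
    """Turn one molecular document into the set of aberrant proteins.

    Expression documents require *cohort_stats* (per-protein mean/SD across
    the cohort); proteins with zero cohort variance are never aberrant.
    Non-numeric values are skipped with a warning.
    """
    data_type = document.get("data_type")
    out: set[str] = set()
    for symbol, raw in document.get("fields", {}).items():
        try:
            value = float(raw)
        except (TypeError, ValueError):
            logger.warning(
                "record %s: non-numeric value %r for protein %s skipped",
                document.get("record_id"), raw, symbol,
            )
            continue
        symbol = normalize_symbol(symbol)
        if data_type == "expression":
            if cohort_stats is None:
                raise ValueError("expression aberration calls need cohort statistics")
            mean, sd = cohort_stats.get(symbol, (0.0, 0.0))
            if sd > 0 and abs(value - mean) / sd >= thresholds.z_abs_cutoff:
                out.add(symbol)
        elif data_type == "cnv":
            if value >= thresholds.cn_gain or value <= thresholds.cn_loss:
                out.add(symbol)
        else:
            raise ValueError(f"not a molecular document: data_type={data_type!r}")
    return out


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_internal_network(
    documents: Sequence[Mapping],
    thresholds: AberrationConfig = AberrationConfig(),
    scoring: ScoringConfig = ScoringConfig(),
) -> IntegratedNetwork:
    """Build the internal relation layer from schema-validated documents.

    One patient node per distinct sample ID; a patient–protein edge per
    aberration call, its frequency set to the number of distinct patients
    carrying the protein; patient–patient similarity edges between patients
    sharing at least one trusted protein, weighted by the number of shared
    trusted proteins.
    """
    net = IntegratedNetwork(trusted_threshold=scoring.trusted_threshold)

    clinical_samples = {
        doc["sample_id"] for doc in documents if doc.get("data_type") == "clinical"
    }
    for sid in clinical_samples:
        net.add_patient(sid)

    stats = expression_cohort_stats(documents)
    kind_by_type = {
        "expression": KIND_PATIENT_PROTEIN_EXPR,
        "cnv": KIND_PATIENT_PROTEIN_CNV,
    }
    # (patient, protein, kind) observations, deduplicated across records
    edges: set[tuple[str, str, str]] = set()
    carriers: dict[str, set[str]] = {}
    for doc in documents:
        data_type = doc.get("data_type")
        if data_type not in kind_by_type:
            continue
        sid = doc["sample_id"]
        if sid not in clinical_samples and sid not in net.patients:
            logger.warning(
                "molecular record %s: sample %s has no clinical record; "
                "kept as orphan patient node", doc.get("record_id"), sid,
            )
            net.add_patient(sid)
        aberrant = call_aberrant_proteins(doc, thresholds, cohort_stats=stats)
        for protein in aberrant:
            edges.add((sid, protein, kind_by_type[data_type]))
            carriers.setdefault(protein, set()).add(sid)

    for protein in carriers:
        net.add_protein(protein)
    for sid, protein, kind in sorted(edges):
        freq = len(carriers[protein])
        net.add_relation(
            Relation(
                source=sid,
                target=protein,
                kind=kind,
                origin=ORIGIN_INTERNAL,
                frequency=freq,
                score=edks.score_relation(ORIGIN_INTERNAL, freq, cfg=scoring),
                trusted=freq > scoring.trusted_threshold,
            )
        )

    # patient-patient similarity through shared trusted proteins
    shared: dict[tuple[str, str], int] = {}
    for protein, sids in carriers.items():
        if len(sids) <= scoring.trusted_threshold:
            continue
        for a, b in combinations(sorted(sids), 2):
            shared[(a, b)] = shared.get((a, b), 0) + 1
    for (a, b), count in sorted(shared.items()):
        net.add_relation(
            Relation(
                source=a,
                target=b,
                kind=KIND_PATIENT_PATIENT_SHARED,
                origin=ORIGIN_INTERNAL,
                frequency=count,
                score=float(count),
                trusted=count > scoring.trusted_threshold,
            )
        )
    return net


def patients_by_protein(network: IntegratedNetwork, protein: str) -> set[str]:
    """All patients with an internal patient–protein edge to *protein*."""
    protein = normalize_symbol(protein)
    if protein not in network.graph:
        return set()
    out = set()
    for _, nbr, data in network.graph.edges(protein, data=True):
        if data["kind"] in (KIND_PATIENT_PROTEIN_EXPR, KIND_PATIENT_PROTEIN_CNV):
            out.add(nbr)
    return out


def add_linked_layer(
    network: IntegratedNetwork,
    provider: RelationProvider,
    cfg: ScoringConfig = ScoringConfig(),
) -> IntegratedNetwork:
    """Enrich the network with protein–protein relations from an EDKS provider.

    Each protein node is looked up by Hugo symbol; a linked edge's
    frequency is the number of distinct patients carrying either endpoint
    (a linked relation "occurs" once per patient exercising it), its score
    comes from the scoring mechanism, and the trusted flag applies the
    strict more-than-threshold rule.
    """
    for symbol in sorted(network.proteins):
        for rel in edks.fetch_related_proteins(symbol, provider):
            a, b = rel.pair
            if network.graph.has_edge(a, b, key=KIND_PROTEIN_PROTEIN_LINKED):
                continue
            support = patients_by_protein(network, a) | patients_by_protein(network, b)
            if not support:
                logger.debug("linked relation %s-%s has no patient support; skipped", a, b)
                continue
            for node in (a, b):
                if node not in network.graph:
                    network.add_protein(node)
            freq = len(support)
            network.add_relation(
                Relation(
                    source=a,
                    target=b,
                    kind=KIND_PROTEIN_PROTEIN_LINKED,
                    origin=ORIGIN_LINKED,
                    frequency=freq,
                    score=edks.score_relation(ORIGIN_LINKED, freq, rel.provider_score, cfg),
                    trusted=freq > cfg.trusted_threshold,
                    provider_score=rel.provider_score,
                )
            )
    return network


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_FORMATS = ("graphml", "tsv")


def export_network(network: IntegratedNetwork, path: str | Path, format: str = "graphml") -> Path:
    """Persist the network as GraphML or a canonical TSV edge list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        graph = network.graph.copy()
        graph.graph["trusted_threshold"] = network.trusted_threshold
        for _, _, data in graph.edges(data=True):
            if "provider_score" not in data:
                data["provider_score"] = float("nan")
        nx.write_graphml(graph, path)
    elif format == "tsv":
        lines = [f"#trusted_threshold={network.trusted_threshold}"]
        for node, data in sorted(network.graph.nodes(data=True)):
            lines.append(f"node\t{node}\t{data.get('kind', '')}")
        header = "source\ttarget\tkind\torigin\tfrequency\tscore\ttrusted\tprovider_score"
        lines.append(header)
        rows = []
        for u, v, k, data in network.graph.edges(keys=True, data=True):
            a, b = sorted((u, v))
            ps = data.get("provider_score")
            rows.append(
                (a, b, k, data["origin"], str(int(data["frequency"])),
                 repr(float(data["score"])), str(bool(data["trusted"])),
                 "" if ps is None else repr(float(ps)))
            )
        for row in sorted(rows):
            lines.append("edge\t" + "\t".join(row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; supported: {_FORMATS}")
    return path


def import_network(path: str | Path, format: str = "graphml") -> IntegratedNetwork:
    path = Path(path)
    if format == "graphml":
        graph = nx.read_graphml(path, force_multigraph=True)
        net = IntegratedNetwork(graph=nx.MultiGraph(), trusted_threshold=int(graph.graph.get("trusted_threshold", 10)))
        for node, data in graph.nodes(data=True):
            net.graph.add_node(node, kind=data.get("kind", ""))
        for u, v, k, data in graph.edges(keys=True, data=True):
            ps = data.get("provider_score")
            if ps is not None and (isinstance(ps, float) and math.isnan(ps)):
                ps = None
            attrs = dict(
                kind=data["kind"], origin=data["origin"],
                frequency=int(data["frequency"]), score=float(data["score"]),
                trusted=bool(data["trusted"]),
            )
            if ps is not None:
                attrs["provider_score"] = float(ps)
            net.graph.add_edge(u, v, key=data["kind"], **attrs)
        return net
    if format == "tsv":
        net = IntegratedNetwork()
        for line in Path(path).read_text().splitlines():
            if line.startswith("#trusted_threshold="):
                net.trusted_threshold = int(line.split("=", 1)[1])
            elif line.startswith("node\t"):
                _, node, kind = line.split("\t")
                net.graph.add_node(node, kind=kind)
            elif line.startswith("edge\t"):
                parts = line.split("\t")[1:]
                a, b, kind, origin, freq, score, trusted = parts[:7]
                ps = parts[7] if len(parts) > 7 and parts[7] else None
                attrs = dict(
                    kind=kind, origin=origin, frequency=int(freq),
                    score=float(score), trusted=trusted == "True",
                )
                if ps is not None:
                    attrs["provider_score"] = float(ps)
                net.graph.add_edge(a, b, key=kind, **attrs)
        return net
    raise ValueError(f"unknown format {format!r}; supported: {_FORMATS}")
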