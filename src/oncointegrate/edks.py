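"""External domain knowledge sources (EDKS) and the relation scoring mechanism.

Protein–protein relatedness beyond the raw data comes from external
knowledge sources (GO / UniProt / Ensembl style lookups keyed by Hugo
symbol).  Providers are pluggable: the offline :class:`FixtureProvider`
reads a TSV relation table and is the default everywhere; an
:class:`OnlineProvider` with a retry contract exists for live REST
endpoints but is never used by the test suite.

The scoring mechanism ranks internal relations (derived from raw data)
above linked ones, rewards relations supported by many distinct patients,
and designates *trusted* relations — those occurring more than a threshold
number of times among different patients (default: strictly more than 10).
Only trusted relations drive cohort enrichment.
"""
from __future__ import annotations

import csv
import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Protocol

from .errors import ProviderError

logger = logging.getLogger(__name__)

ORIGIN_INTERNAL = "internal"
ORIGIN_LINKED = "linked"


@dataclass(frozen=True)
class LinkedRelation:
    """A symmetric protein–protein relation from an external source.

    The pair is stored canonically ordered so (A,B) and (B,A) are the same
    relation.
    """

    protein_a: str
    protein_b: str
    provider_score: float
    provider_name: str = ""

    def __post_init__(self) -> None:
        a = self.protein_a.strip().upper()
        b = self.protein_b.strip().upper()
        if a == b:
            raise ValueError(f"self-relation {a!r} is not allowed")
        if not 0.0 <= self.provider_score <= 1.0:
            raise ValueError(f"provider_score {self.provider_score} outside [0, 1]")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    def partner_of(self, symbol: str) -> str:
        symbol = symbol.strip().upper()
        return self.protein_b if symbol == self.protein_a else self.protein_a


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the relation scoring mechanism.

    ``base_internal`` must exceed ``base_linked`` so raw-data relations
    always rank above externally derived ones at equal patient support;
    every extra supporting patient adds ``frequency_bonus``.
    """

    base_internal: float = 1.0
    base_linked: float = 0.5
    frequency_bonus: float = 0.05
    trusted_threshold: int = 10

    def __post_init__(self) -> None:
        if self.base_internal <= self.base_linked:
            raise ValueError("base_internal must exceed base_linked")
        if self.base_internal <= 0 or self.base_linked <= 0:
            raise ValueError("base scores must be positive")
        if self.trusted_threshold < 1:
            raise ValueError("trusted_threshold must be >= 1")


class RelationProvider(Protocol):
    name: str

    def related(self, hugo_symbol: str) -> list[LinkedRelation]: ...


class FixtureProvider:
    """Offline provider backed by a TSV table ``protein_a protein_b score provider``."""

    def __init__(self, relations: Iterable[LinkedRelation], name: str = "fixture"):
        self.name = name
        self._by_symbol: dict[str, dict[tuple[str, str], LinkedRelation]] = {}
        for rel in relations:
            for symbol in rel.pair:
                self._by_symbol.setdefault(symbol, {})[rel.pair] = rel

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "fixture") -> "FixtureProvider":
        relations = []
        with Path(path).open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "protein_a":
                    continue
                a, b, score = row[0], row[1], float(row[2])
                provider = row[3] if len(row) > 3 else name
                if a.strip().upper() == b.strip().upper():
                    continue
                relations.append(LinkedRelation(a, b, score, provider))
        return cls(relations, name=name)

    def related(self, hugo_symbol: str) -> list[LinkedRelation]:
        symbol = hugo_symbol.strip().upper()
        found = self._by_symbol.get(symbol, {})
        return sorted(found.values(), key=lambda r: r.pair)


class OnlineProvider:
    """REST provider with bounded exponential-backoff retries.

    Endpoint contract: ``GET {base_url}/{symbol}`` returning a JSON list of
    ``{"symbol": ..., "score": ...}`` objects.  Not exercised by the test
    suite; offline fixtures are the default provider everywhere.
    """

    def __init__(self, base_url: str, name: str = "online",
                 max_retries: int = 3, backoff: float = 0.5):
        self.base_url = base_url.rstrip("/")
        self.name = name
        self.max_retries = max_retries
        self.backoff = backoff

    def related(self, hugo_symbol: str) -> list[LinkedRelation]:
        symbol = hugo_symbol.strip().upper()
        url = f"{self.base_url}/{symbol}"
        last_error: Optional[Exception] = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(url, timeout=10) as resp:
                    payload = json.loads(resp.read().decode())
                relations = {}
                for item in payload:
                    partner = str(item["symbol"]).strip().upper()
                    if partner == symbol:
                        continue
                    rel = LinkedRelation(symbol, partner, float(item["score"]), self.name)
                    relations[rel.pair] = rel
                return sorted(relations.values(), key=lambda r: r.pair)
            except (urllib.error.URLError, ValueError, KeyError) as exc:
                last_error = exc
                time.sleep(self.backoff * 2 ** attempt)
        raise ProviderError(
            f"provider {self.name!r} failed for {symbol!r} after "
            f"{self.max_retries} attempts: {last_error}"
        )


def fetch_related_proteins(hugo_symbol: str, provider: RelationProvider) -> list[LinkedRelation]:
    """Look up proteins related to *hugo_symbol*, deduplicated, no self-relations."""
    return provider.related(hugo_symbol)


def score_relation(
    origin: str,
    frequency: int,
    provider_score: Optional[float] = None,
    cfg: ScoringConfig = ScoringConfig(),
) -> float:
    """Score one relation.

    internal: ``base_internal + frequency_bonus * (frequency - 1)``
    linked:   ``base_linked * provider_score + frequency_bonus * (frequency - 1)``

    Strictly increasing in frequency; internal >= linked at equal frequency
    whenever provider_score <= 1.
    """
    if frequency < 1:
        raise ValueError(f"frequency must be >= 1, got {frequency}")
    if origin == ORIGIN_INTERNAL:
        return cfg.base_internal + cfg.frequency_bonus * (frequency - 1)
    if origin == ORIGIN_LINKED:
        if provider_score is None:
            raise ValueError("linked relations require a provider_score")
        if not 0.0 <= provider_score <= 1.0:
            raise ValueError(f"provider_score {provider_score} outside [0, 1]")
        return cfg.base_linked * provider_score + cfg.frequency_bonus * (frequency - 1)
    raise ValueError(f"unknown origin {origin!r}")


def mark_trusted(network, cfg: ScoringConfig = ScoringConfig()):
    """Set the trusted flag on every edge: trusted iff frequency > threshold.

    The reading of "more than N times among different patients" is strict:
    frequency N is not trusted, N+1 is.  Idempotent.
    """
    for _, _, data in network.graph.edges(data=True):
        data["trusted"] = bool(data.get("frequency", 0) > cfg.trusted_threshold)
    network.trusted_threshold = cfg.trusted_threshold
    return network


def prune_untrusted(network, cfg: ScoringConfig = ScoringConfig()):
    """Drop untrusted linked protein–protein edges; keep all internal edges.

    Raw-data (internal) edges are never discarded — enrichment traversal
    simply ignores the untrusted ones.  Idempotent.
    """
    from .network import KIND_PROTEIN_PROTEIN_LINKED  # local import, no cycle at module load

    doomed = [
        (u, v, k)
        for u, v, k, data in network.graph.edges(keys=True, data=True)
        if data.get("kind") == KIND_PROTEIN_PROTEIN_LINKED and not data.get("trusted", False)
    ]
    network.graph.remove_edges_from(doomed)
    if doomed:
        logger.info("pruned %d untrusted linked relation(s)", len(doomed))
    return network
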