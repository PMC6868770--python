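"""Per-patient cohort enrichment: the two-ring neighbourhood of a seed.

Starting from a studied patient, the enriched dataset grows in three
rings: ring0 is the seed's TICF group; ring1 adds patients reached through
trusted internal relations (patients carrying the same trusted proteins as
the group); ring2 adds patients reached through one trusted linked hop
(protein -> externally related protein -> its carriers).  The union is
deduplicated and its feature matrix — normalized TICF plus binary
per-trusted-protein aberration indicators — is z-normalized again, with
survival months as the regression target.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import fields as fieldlib
from .errors import InsufficientCohortError, TICFUndefinedError
from .network import (
    KIND_PATIENT_PROTEIN_CNV,
    KIND_PATIENT_PROTEIN_EXPR,
    KIND_PROTEIN_PROTEIN_LINKED,
    IntegratedNetwork,
    patients_by_protein,
)
from .ticf import TICFTable

logger = logging.getLogger(__name__)


@dataclass
class EnrichedCohort:
    """The per-seed enriched dataset."""

    seed: str
    ring0: set[str]
    ring1: set[str]
    ring2: set[str]
    proteins_used: dict[str, str] = field(default_factory=dict)  # protein -> origin tag
    feature_matrix: Optional[pd.DataFrame] = None
    targets: Optional[pd.Series] = None

    @property
    def patients(self) -> set[str]:
        return self.ring0 | self.ring1 | self.ring2


def seed_group(seed: str, groups: Mapping[str, int]) -> set[str]:
    """Ring0: every patient in the seed's TICF group (seed included)."""
    if seed not in groups:
        raise TICFUndefinedError(
            f"patient {seed!r} has no TICF group; only patients with a defined "
            "TICF can be studied"
        )
    target = groups[seed]
    return {sid for sid, g in groups.items() if g == target}


def trusted_proteins_of(patients: set[str], network: IntegratedNetwork) -> set[str]:
    """Proteins linked to any of *patients* by a trusted internal edge."""
    out: set[str] = set()
    for sid in patients:
        if sid not in network.graph:
            continue
        for _, nbr, data in network.graph.edges(sid, data=True):
            if (
                data["kind"] in (KIND_PATIENT_PROTEIN_EXPR, KIND_PATIENT_PROTEIN_CNV)
                and data.get("trusted", False)
            ):
                out.add(nbr)
    return out


def expand_internal(ring0: set[str], network: IntegratedNetwork) -> set[str]:
    """Ring1: carriers of the group's trusted proteins, minus ring0."""
    related: set[str] = set()
    for protein in trusted_proteins_of(ring0, network):
        related |= patients_by_protein(network, protein)
    return related - ring0


def trusted_linked_partners(proteins: set[str], network: IntegratedNetwork) -> set[str]:
    """Proteins one trusted linked hop away from any protein in *proteins*."""
    out: set[str] = set()
    for protein in proteins:
        if protein not in network.graph:
            continue
        for _, nbr, data in network.graph.edges(protein, data=True):
            if data["kind"] == KIND_PROTEIN_PROTEIN_LINKED and data.get("trusted", False):
                out.add(nbr)
    return out - proteins


def expand_linked(
    cohort_patients: set[str], network: IntegratedNetwork
) -> set[str]:
    """Ring2: one trusted linked hop, then that protein's carriers.

    The scoring mechanism's pruning is applied implicitly: only trusted
    linked edges are traversed, so untrusted external relations contribute
    nothing.
    """
    proteins = trusted_proteins_of(cohort_patients, network)
    partners = trusted_linked_partners(proteins, network)
    related: set[str] = set()
    for protein in partners:
        related |= patients_by_protein(network, protein)
    return related - cohort_patients


def build_cohort(
    seed: str, ticf_table: TICFTable, network: IntegratedNetwork
) -> EnrichedCohort:
    """Resolve the three rings for one seed patient."""
    ring0 = seed_group(seed, ticf_table.groups)
    ring1 = expand_internal(ring0, network)
    ring2 = expand_linked(ring0 | ring1, network)
    proteins0 = trusted_proteins_of(ring0 | ring1, network)
    partners = trusted_linked_partners(proteins0, network)
    proteins_used = {p: "internal" for p in sorted(proteins0)}
    proteins_used.update({p: "linked" for p in sorted(partners)})
    return EnrichedCohort(
        seed=seed, ring0=ring0, ring1=ring1, ring2=ring2,
        proteins_used=proteins_used,
    )


def extract_survival_months(document: Mapping) -> Optional[float]:
    """Survival months from a clinical document, None when missing."""
    raw = fieldlib.get_value(document.get("fields", {}), fieldlib.SURVIVAL_ALIASES)
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-normalization; constant columns become zeros."""
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        mean = x.mean()
        sd = x.std(ddof=0)
        degenerate = sd <= 1e-12 * max(1.0, abs(mean))
        out[col] = np.zeros_like(x) if degenerate else (x - mean) / sd
    return pd.DataFrame(out, index=matrix.index)


def assemble_features(
    cohort: EnrichedCohort,
    documents: Sequence[Mapping],
    ticf_table: TICFTable,
    network: IntegratedNetwork,
) -> EnrichedCohort:
    """Attach the z-normalized feature matrix and survival targets.

    Rows are the deduplicated cohort patients in canonical order.  The
    TICF column holds the cohort-level normalized composite; patients
    reached through the rings without a defined TICF are imputed to 0 (the
    post-normalization mean) and described only by their per-protein
    indicators.  Rows lacking a survival target stay in the matrix for
    prediction but are excluded from training (the caller drops them via
    ``targets``; the count is logged).
    """
    rows = sorted(cohort.patients)
    survival: dict[str, float] = {}
    seen: set[str] = set()
    for doc in sorted(
        (d for d in documents if d.get("data_type") == "clinical"),
        key=lambda d: str(d.get("record_id")),
    ):
        sid = doc["sample_id"]
        if sid in seen:
            logger.info("duplicate clinical record for sample %s ignored", sid)
            continue
        seen.add(sid)
        months = extract_survival_months(doc)
        if months is not None:
            survival[sid] = months

    normalized = ticf_table.normalized
    data: dict[str, list[float]] = {"ticf": [normalized.get(sid, 0.0) for sid in rows]}
    for protein in cohort.proteins_used:
        carriers = patients_by_protein(network, protein)
        data[f"protein:{protein}"] = [1.0 if sid in carriers else 0.0 for sid in rows]
    matrix = _zscore_columns(pd.DataFrame(data, index=rows))
    targets = pd.Series([survival.get(sid, np.nan) for sid in rows], index=rows, name="survival_months")

    n_missing = int(targets.isna().sum())
    if n_missing:
        logger.info(
            "cohort of %s: %d patient(s) without survival excluded from training",
            cohort.seed, n_missing,
        )
    if int(targets.notna().sum()) < 2:
        raise InsufficientCohortError(
            f"insufficient cohort for seed {cohort.seed!r}: fewer than 2 rows "
            "carry survival targets"
        )
    cohort.feature_matrix = matrix
    cohort.targets = targets
    return cohort


def enrich_patient(
    seed: str,
    documents: Sequence[Mapping],
    ticf_table: TICFTable,
    network: IntegratedNetwork,
) -> EnrichedCohort:
    """Convenience: rings + features in one call."""
    cohort = build_cohort(seed, ticf_table, network)
    return assemble_features(cohort, documents, ticf_table, network)
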