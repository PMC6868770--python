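"""The Tumor Integrated Clinical Feature (TICF).

TICF is a composite ordinal feature built by fixed-width numeric
concatenation of tumor stage, tumor size (mm) and age at diagnosis
(years), in this exact order.  Under the default digit widths (1, 3, 3)

    composite = stage * 10**6 + size * 10**3 + age

so the numeric order of composites equals the lexicographic order of
(stage, size, age): stage dominates, then size, then age — the ordering of
prognostic importance.  Composites are z-normalized (mean/SD stored for
transforming new patients), patients are stratified into k near-equal
groups along the normalized axis, and nearest-neighbour queries on the
same axis find the patients closest to a studied one.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import fields as fieldlib
from .errors import TICFUndefinedError

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (1, 3, 3)

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


# ---------------------------------------------------------------------------
# component normalization
# ---------------------------------------------------------------------------

def normalize_stage(value: str) -> Optional[int]:
    """Map heterogeneous stage encodings ("3", "III", "stage 3") to 1..4."""
    text = str(value).strip().lower()
    text = re.sub(r"^(stage|t)\s*", "", text)
    if text in _ROMAN:
        return _ROMAN[text]
    try:
        stage = int(float(text))
    except ValueError:
        return None
    return stage if 1 <= stage <= 4 else None


def normalize_size_mm(value: str) -> Optional[int]:
    """Tumor size in millimetres; values <10 with a decimal point are taken
    as centimetres and converted (logged)."""
    text = str(value).strip()
    try:
        size = float(text)
    except ValueError:
        return None
    if "." in text and 0 < size < 10:
        logger.info("tumor size %s looks like cm; converted to %.0f mm", text, size * 10)
        size *= 10
    size = int(round(size))
    return size if size > 0 else None


def normalize_age_years(value: str) -> Optional[int]:
    try:
        age = int(round(float(str(value).strip())))
    except ValueError:
        return None
    return age if age > 0 else None


# ---------------------------------------------------------------------------
# composite construction
# ---------------------------------------------------------------------------

def build_ticf(
    stage: int, size: int, age: int, widths: Sequence[int] = DEFAULT_WIDTHS
) -> int:
    """Concatenate (stage, size, age) into the composite integer.

    Raises on missing/overflowing components; the composite's numeric
    order equals the lexicographic order of the triple.
    """
    if stage is None or size is None or age is None:
        raise TICFUndefinedError("TICF undefined for patient: missing component")
    ws, wz, wa = widths
    if not 1 <= stage <= 4 or stage >= 10 ** ws:
        raise ValueError(f"stage {stage} outside 1..4 (width {ws})")
    if not 0 < size < 10 ** wz:
        raise ValueError(f"size {size} overflows width {wz}")
    if not 0 < age < 10 ** wa:
        raise ValueError(f"age {age} overflows width {wa}")
    return stage * 10 ** (wz + wa) + size * 10 ** wa + age


def decompose_ticf(
    composite: int, widths: Sequence[int] = DEFAULT_WIDTHS
) -> tuple[int, int, int]:
    """Invert :func:`build_ticf` exactly."""
    _, wz, wa = widths
    age = composite % 10 ** wa
    size = (composite // 10 ** wa) % 10 ** wz
    stage = composite // 10 ** (wz + wa)
    return stage, size, age


@dataclass(frozen=True)
class TICFValue:
    """One patient's composite feature with its components."""

    sample_id: str
    stage: int
    size: int
    age: int
    composite: int
    normalized: Optional[float] = None


@dataclass(frozen=True)
class NormalizationState:
    """Stored mean and SD for transforming later patients."""

    mean: float
    sd: float
    degenerate: bool = False

    def transform(self, value: float) -> float:
        if self.degenerate:
            return 0.0
        return (value - self.mean) / self.sd


def ticf_from_document(
    document: Mapping, widths: Sequence[int] = DEFAULT_WIDTHS
) -> Optional[TICFValue]:
    """Extract a TICF value from a clinical document, or None if undefined.

    Field names are resolved through aliases; stage strings, cm-sized
    tumors and float ages are normalized.  Any missing or unmappable
    component leaves the patient without a TICF (such patients can still
    be reached through the relation network).
    """
    fields = document.get("fields", {})
    stage = fieldlib.get_value(fields, fieldlib.STAGE_ALIASES)
    size = fieldlib.get_value(fields, fieldlib.SIZE_ALIASES)
    age = fieldlib.get_value(fields, fieldlib.AGE_ALIASES)
    if stage is None or size is None or age is None:
        return None
    s = normalize_stage(stage)
    z = normalize_size_mm(size)
    a = normalize_age_years(age)
    if s is None or z is None or a is None:
        return None
    try:
        composite = build_ticf(s, z, a, widths)
    except ValueError:
        logger.warning(
            "sample %s: TICF components (%s, %s, %s) overflow widths %s",
            document.get("sample_id"), s, z, a, tuple(widths),
        )
        return None
    return TICFValue(
        sample_id=document["sample_id"], stage=s, size=z, age=a, composite=composite
    )


# ---------------------------------------------------------------------------
# normalization, stratification, neighbours
# ---------------------------------------------------------------------------

def normalize(values: Sequence[float]) -> tuple[np.ndarray, NormalizationState]:
    """Center and scale to unit (population) variance.

    Constant input is degenerate: all zeros are returned and the state is
    flagged so later transforms also map to 0.
    """
    if len(values) == 0:
        raise ValueError("cannot normalize an empty value list")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    # constant input up to float fuzz counts as degenerate
    if sd <= 1e-12 * max(1.0, abs(mean)):
        return np.zeros_like(arr), NormalizationState(mean=mean, sd=0.0, degenerate=True)
    return (arr - mean) / sd, NormalizationState(mean=mean, sd=sd)


def stratify(
    normalized: Mapping[str, float], k: int = 5
) -> dict[str, int]:
    """Cut patients into k contiguous groups along the normalized axis.

    Patients are sorted by (value, sample_id) and split into k groups
    whose sizes differ by at most one (earlier groups take the extra
    patient).  Deterministic.
    """
    n = len(normalized)
    if n < k:
        raise ValueError(f"cannot stratify {n} patients into {k} groups; use a smaller k")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(normalized, key=lambda sid: (normalized[sid], sid))
    base, extra = divmod(n, k)
    groups: dict[str, int] = {}
    idx = 0
    for g in range(k):
        size = base + (1 if g < extra else 0)
        for sid in ordered[idx: idx + size]:
            groups[sid] = g
        idx += size
    return groups


def nearest_patients(
    query: str, normalized: Mapping[str, float], m: int
) -> list[str]:
    """The m patients closest to *query* on the normalized TICF axis.

    Ties are broken by sample_id; the query never appears in its own
    neighbour list.
    """
    if query not in normalized:
        raise TICFUndefinedError(f"patient {query!r} has no defined TICF")
    ref = normalized[query]
    others = sorted(
        (sid for sid in normalized if sid != query),
        key=lambda sid: (abs(normalized[sid] - ref), sid),
    )
    return others[:m]


# ---------------------------------------------------------------------------
# cohort-level table
# ---------------------------------------------------------------------------

@dataclass
class TICFTable:
    """Per-cohort TICF values, normalization state and group assignment."""

    values: dict[str, TICFValue]
    state: NormalizationState
    groups: dict[str, int]
    undefined: set[str]
    k: int
    widths: tuple[int, int, int] = DEFAULT_WIDTHS

    @property
    def normalized(self) -> dict[str, float]:
        return {sid: v.normalized for sid, v in self.values.items()}


def build_ticf_table(
    clinical_documents: Sequence[Mapping],
    k: int = 5,
    widths: Sequence[int] = DEFAULT_WIDTHS,
) -> TICFTable:
    """Build, normalize and stratify TICF for a whole cohort.

    Duplicate sample IDs across studies keep the first occurrence in
    canonical (record_id-sorted) order, logged.
    """
    values: dict[str, TICFValue] = {}
    undefined: set[str] = set()
    for doc in sorted(clinical_documents, key=lambda d: str(d.get("record_id"))):
        sid = doc["sample_id"]
        if sid in values or sid in undefined:
            logger.info("duplicate clinical record for sample %s ignored", sid)
            continue
        value = ticf_from_document(doc, widths)
        if value is None:
            undefined.add(sid)
        else:
            values[sid] = value
    if not values:
        raise TICFUndefinedError("no patient has a defined TICF")
    sids = sorted(values)
    composites = [values[sid].composite for sid in sids]
    normalized, state = normalize(composites)
    for sid, z in zip(sids, normalized):
        values[sid] = TICFValue(
            sample_id=sid,
            stage=values[sid].stage,
            size=values[sid].size,
            age=values[sid].age,
            composite=values[sid].composite,
            normalized=float(z),
        )
    groups = stratify({sid: values[sid].normalized for sid in sids}, k=k)
    return TICFTable(
        values=values, state=state, groups=groups, undefined=undefined,
        k=k, widths=tuple(widths),
    )
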