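"""Field-name alias resolution for heterogeneous clinical tables.

Different studies name the same clinical attribute differently
("tumor_stage" vs "Stage" vs "T stage").  Names are matched after
lower-casing and stripping every non-alphanumeric character, so
"Sample ID", "sample_id" and "SampleID" all collapse to "sampleid".
"""
from __future__ import annotations

import re
from typing import Mapping, Optional

_CANON = re.compile(r"[^a-z0-9]+")


def canonical(name: str) -> str:
    """Collapse a field name to its alias-matching form."""
    return _CANON.sub("", name.lower())


SAMPLE_ID_ALIASES = frozenset(
    {"sampleid", "sample", "samplename", "patientid", "patient", "subjectid"}
)
RECORD_ID_ALIASES = frozenset({"id", "recordid"})
STAGE_ALIASES = frozenset({"stage", "tumorstage", "tstage", "tumourstage"})
SIZE_ALIASES = frozenset(
    {"size", "tumorsize", "tumorsizemm", "tumoursize", "tumorsizecm", "lesionsize"}
)
AGE_ALIASES = frozenset(
    {"age", "ageatdiagnosis", "ageyears", "agediagnosis", "ageatdx"}
)
SURVIVAL_ALIASES = frozenset(
    {
        "survival",
        "survivalmonths",
        "osmonths",
        "overallsurvivalmonths",
        "survivaltime",
        "survivaltimemonths",
        "monthssurvival",
    }
)


def find_field(fields: Mapping[str, object], aliases: frozenset[str]) -> Optional[str]:
    """Return the first key of *fields* whose canonical form is in *aliases*.

    Keys are scanned in insertion order so resolution is deterministic for a
    given record.
    """
    for key in fields:
        if canonical(key) in aliases:
            return key
    return None


def get_value(fields: Mapping[str, object], aliases: frozenset[str]) -> Optional[str]:
    key = find_field(fields, aliases)
    if key is None:
        return None
    value = fields[key]
    if value is None:
        return None
    text = str(value).strip()
    return text if text else None
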