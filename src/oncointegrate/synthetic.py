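"""Synthetic two-study cancer cohorts with known ground truth.

The generator emulates the structure of multi-study cancer data: two
"studies" with different delimiters, field-name dialects and value
encodings (arabic vs roman stage, mm vs cm tumor size), each contributing
a clinical table, an expression matrix and a copy-number table joined by
sample ID, plus a protein–protein relation fixture standing in for
GO/UniProt/Ensembl lookups.

Ground truth is planted so every downstream module is testable:

* survival months follow ``max(0, α − β1·stage − β2·size − β3·age + Σδ_m + ε)``
  where δ_m is the effect of carrying planted protein module m;
* each module is a set of co-aberrant proteins whose carriers are sampled
  preferentially from one band of the composite-clinical-feature axis, so
  network neighbourhoods carry survival-correlated signal;
* each module has one *satellite* protein related to the core only through
  the external-knowledge fixture, carried by few patients — signal that
  is reachable only through the linked layer;
* expression baselines are bounded uniform jitter, so cohort z-scores of
  non-carriers provably stay below the aberration cutoff and the
  recovered patient–protein edges equal the planted manifest exactly.

A fixed seed reproduces every file byte for byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .ticf import build_ticf


@dataclass(frozen=True)
class StudyDialect:
    """Per-study file conventions: delimiter, field names, value encodings."""

    name: str
    n_patients: int
    delimiter: str
    field_names: dict[str, str]  # roles: sample, record, stage, size, age, survival
    stage_style: str = "arabic"  # or "roman"
    size_unit: str = "mm"        # or "cm"
    age_range: tuple[int, int] = (20, 90)
    technology: str = "RNA-Seq"
    hugo_column: str = "Hugo_Symbol"

    @property
    def extension(self) -> str:
        return {"\t": "tsv", ",": "csv", ";": "ssv"}.get(self.delimiter, "txt")


#: Neuroblastoma-like study: tab-delimited, snake_case names, arabic stages,
#: sizes in mm, pediatric ages.
NB_LIKE = StudyDialect(
    name="NB",
    n_patients=150,
    delimiter="\t",
    field_names={
        "record": "id",
        "sample": "sample_id",
        "stage": "tumor_stage",
        "size": "tumor_size_mm",
        "age": "age_years",
        "survival": "survival_months",
    },
    stage_style="arabic",
    size_unit="mm",
    age_range=(1, 15),
    technology="RNA-Seq",
    hugo_column="Hugo_Symbol",
)

#: Breast-cancer-like study: comma-delimited, mixed-case names, roman
#: stages, sizes in cm, adult ages.
BC_LIKE = StudyDialect(
    name="BC",
    n_patients=400,
    delimiter=",",
    field_names={
        "record": "ID",
        "sample": "Sample ID",
        "stage": "Stage",
        "size": "Size",
        "age": "Age",
        "survival": "OS_Months",
    },
    stage_style="roman",
    size_unit="cm",
    age_range=(25, 90),
    technology="Microarray",
    hugo_column="Gene",
)

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the default synthetic scenario.

    Survival coefficients follow the prognostic hierarchy the composite
    clinical feature assumes — stage dominates (30 months per stage, more
    than the largest possible combined size+age contribution), then size,
    then age — so noiseless survival is monotone in the composite.
    Module effects add survival signal carried only by the relation
    network.
    """

    studies: tuple[StudyDialect, ...] = (NB_LIKE, BC_LIKE)
    stage_probs: tuple[float, ...] = (0.30, 0.30, 0.25, 0.15)
    size_range_mm: tuple[int, int] = (5, 90)
    alpha: float = 220.0
    beta_stage: float = 30.0
    beta_size: float = 0.05
    beta_age: float = 0.01
    noise_sd: float = 6.0
    noise_sd_frac: Optional[float] = None  # overrides noise_sd as a fraction of signal SD
    survival_cap: float = 240.0
    n_proteins: int = 120
    n_modules: int = 4
    module_size: int = 5
    module_effects: tuple[float, ...] = (-20.0, -10.0, 10.0, 20.0)
    carrier_rate_in_band: float = 0.35
    carrier_rate_background: float = 0.02
    satellite_carriers: int = 8
    ticf_complete_fraction: float = 0.7
    edks_decoy_density: float = 0.05
    edks_core_score: tuple[float, float] = (0.75, 0.95)
    edks_decoy_score: tuple[float, float] = (0.05, 0.30)
    expression_shift: float = 5.0
    cnv_magnitude: float = 1.0
    seed: int = 7

    def validate(self) -> None:
        n_total = sum(s.n_patients for s in self.studies)
        if self.n_modules > 0 and self.module_size + self.satellite_carriers > n_total:
            raise ConfigError("module size exceeds the number of patients")
        if len(self.module_effects) not in (0, self.n_modules):
            raise ConfigError("module_effects must have one entry per module")
        rates = (
            self.carrier_rate_in_band,
            self.carrier_rate_background,
            self.ticf_complete_fraction,
            self.edks_decoy_density,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")
        if self.n_modules * (self.module_size + 1) > self.n_proteins:
            raise ConfigError("n_proteins too small for the requested modules")


def parameter_recovery_config(n_patients: int = 500, seed: int = 0) -> SyntheticConfig:
    """A cohort where survival is exactly linear in (stage, size, age).

    Single dialect, complete clinical data, no module effects, noise SD at
    5% of the clinical signal SD — the regime for checking that the
    regression models recover the planted survival relationship.
    """
    study = StudyDialect(
        name="S1",
        n_patients=n_patients,
        delimiter="\t",
        field_names=dict(NB_LIKE.field_names),
        age_range=(20, 90),
    )
    return SyntheticConfig(
        studies=(study,),
        n_modules=0,
        module_effects=(),
        n_proteins=20,
        noise_sd_frac=0.05,
        ticf_complete_fraction=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _format_stage(stage: int, style: str) -> str:
    return _ROMAN[stage] if style == "roman" else str(stage)


def _format_size(size_mm: int, unit: str) -> str:
    return f"{size_mm / 10:.1f}" if unit == "cm" else str(size_mm)


def generate_cohort(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the per-study files and return (and save) the manifest.

    The manifest records every ground truth: per-patient clinical values
    and survival, module membership, planted aberration sets and the
    survival model parameters.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # ---- patients -------------------------------------------------------
    patients: list[dict] = []
    for study in cfg.studies:
        stages = rng.choice(
            np.arange(1, 5), size=study.n_patients, p=np.asarray(cfg.stage_probs)
        )
        sizes = rng.integers(cfg.size_range_mm[0], cfg.size_range_mm[1] + 1,
                             size=study.n_patients)
        ages = rng.integers(study.age_range[0], study.age_range[1] + 1,
                            size=study.n_patients)
        for i in range(study.n_patients):
            sid = f"{study.name}-P{i:04d}"
            patients.append({
                "sample_id": sid,
                "study": study.name,
                "stage": int(stages[i]),
                "size": int(sizes[i]),
                "age": int(ages[i]),
                "composite": build_ticf(int(stages[i]), int(sizes[i]), int(ages[i])),
            })
    n_total = len(patients)
    sid_index = {p["sample_id"]: j for j, p in enumerate(patients)}

    # ---- protein modules ------------------------------------------------
    core_symbols: list[list[str]] = []
    satellites: list[str] = []
    for m in range(cfg.n_modules):
        core_symbols.append([f"MOD{m}P{j}" for j in range(cfg.module_size)])
        satellites.append(f"MOD{m}SAT")
    used = sum((c for c in core_symbols), []) + satellites
    decoys = [f"GENE{j:04d}" for j in range(cfg.n_proteins - len(used))]
    proteins = used + decoys

    by_composite = [patients[j]["sample_id"]
                    for j, _ in sorted(enumerate(patients),
                                       key=lambda t: (t[1]["composite"], t[1]["sample_id"]))]
    bands = np.array_split(np.arange(n_total), cfg.n_modules) if cfg.n_modules else []

    modules: list[dict] = []
    for m in range(cfg.n_modules):
        band_sids = {by_composite[j] for j in bands[m]}
        draws = rng.random(n_total)
        carriers = []
        for j, p in enumerate(patients):
            rate = (cfg.carrier_rate_in_band if p["sample_id"] in band_sids
                    else cfg.carrier_rate_background)
            if draws[j] < rate:
                carriers.append(p["sample_id"])
        pool = sorted(band_sids - set(carriers))
        n_sat = min(cfg.satellite_carriers, len(pool))
        sat_carriers = sorted(
            rng.choice(pool, size=n_sat, replace=False).tolist()
        )
        layer = "expression" if m < cfg.n_modules / 2 else "cnv"
        modules.append({
            "index": m,
            "layer": layer,
            "cnv_sign": 1.0 if m % 2 == 0 else -1.0,
            "proteins": core_symbols[m],
            "satellite": satellites[m],
            "carriers": sorted(carriers),
            "satellite_carriers": sat_carriers,
            "effect": float(cfg.module_effects[m]) if cfg.module_effects else 0.0,
        })

    # ---- survival -------------------------------------------------------
    base = np.array([
        cfg.alpha - cfg.beta_stage * p["stage"] - cfg.beta_size * p["size"]
        - cfg.beta_age * p["age"]
        for p in patients
    ])
    module_term = np.zeros(n_total)
    for mod in modules:
        for sid in mod["carriers"] + mod["satellite_carriers"]:
            module_term[sid_index[sid]] += mod["effect"]
    sd = (cfg.noise_sd_frac * float(base.std(ddof=0))
          if cfg.noise_sd_frac is not None else cfg.noise_sd)
    noise = rng.normal(0.0, sd, size=n_total) if sd > 0 else np.zeros(n_total)
    survival = np.clip(base + module_term + noise, 0.0, cfg.survival_cap)
    survival = np.round(survival, 1)
    for j, p in enumerate(patients):
        p["survival"] = float(survival[j])

    # ---- molecular matrices --------------------------------------------
    expr = rng.uniform(-0.5, 0.5, size=(len(proteins), n_total))
    cnv = rng.uniform(-0.1, 0.1, size=(len(proteins), n_total))
    protein_row = {sym: r for r, sym in enumerate(proteins)}
    aberrations: dict[str, set[str]] = {p["sample_id"]: set() for p in patients}
    for mod in modules:
        rows = [protein_row[s] for s in mod["proteins"]]
        sat_row = protein_row[mod["satellite"]]
        cols = [sid_index[s] for s in mod["carriers"]]
        sat_cols = [sid_index[s] for s in mod["satellite_carriers"]]
        if mod["layer"] == "expression":
            for r in rows:
                expr[r, cols] += cfg.expression_shift
            expr[sat_row, sat_cols] += cfg.expression_shift
        else:
            for r in rows:
                cnv[r, cols] += mod["cnv_sign"] * cfg.cnv_magnitude
            cnv[sat_row, sat_cols] += mod["cnv_sign"] * cfg.cnv_magnitude
        for sid in mod["carriers"]:
            aberrations[sid].update(mod["proteins"])
        for sid in mod["satellite_carriers"]:
            aberrations[sid].add(mod["satellite"])
    expr = np.round(expr, 4)
    cnv = np.round(cnv, 3)

    # ---- TICF completeness ---------------------------------------------
    incomplete_draw = rng.random(n_total)
    blanked_component = rng.integers(0, 3, size=n_total)
    component_names = ("stage", "size", "age")
    for j, p in enumerate(patients):
        p["ticf_complete"] = bool(incomplete_draw[j] < cfg.ticf_complete_fraction)
        p["blanked"] = None if p["ticf_complete"] else component_names[blanked_component[j]]

    # ---- file writing ---------------------------------------------------
    files: dict[str, dict] = {}
    for study in cfg.studies:
        d = study.delimiter
        fn = study.field_names
        study_patients = [p for p in patients if p["study"] == study.name]
        expr_id = f"EXP{study.name}01"

        clin_lines = [
            f"#technology={study.technology}",
            f"#ref={expr_id}",
            "#n_attributes=6",
            d.join([fn["record"], fn["sample"], fn["stage"], fn["size"],
                    fn["age"], fn["survival"]]),
        ]
        for p in study_patients:
            stage = "" if p["blanked"] == "stage" else _format_stage(p["stage"], study.stage_style)
            size = "" if p["blanked"] == "size" else _format_size(p["size"], study.size_unit)
            age = "" if p["blanked"] == "age" else str(p["age"])
            clin_lines.append(d.join([
                f"{p['sample_id']}-cl", p["sample_id"], stage, size, age,
                f"{p['survival']:.1f}",
            ]))
        clin_path = out / f"{study.name}_clinical.{study.extension}"
        clin_path.write_text("\n".join(clin_lines) + "\n")

        def matrix_lines(values: np.ndarray, decimals: int, technology: str) -> list[str]:
            lines = [f"#technology={technology}",
                     d.join([study.hugo_column] + [p["sample_id"] for p in study_patients])]
            cols = [sid_index[p["sample_id"]] for p in study_patients]
            for r, sym in enumerate(proteins):
                row = values[r, cols]
                lines.append(d.join([sym] + [f"{v:.{decimals}f}" for v in row]))
            return lines

        expr_path = out / f"{study.name}_expression.{study.extension}"
        expr_path.write_text("\n".join(matrix_lines(expr, 4, study.technology)) + "\n")
        cnv_path = out / f"{study.name}_cnv.{study.extension}"
        cnv_path.write_text("\n".join(matrix_lines(cnv, 3, "aCGH")) + "\n")

        files[study.name] = {
            "clinical": clin_path.name,
            "expression": expr_path.name,
            "cnv": cnv_path.name,
            "delimiter": d,
            "expression_file_id": expr_id,
        }

    manifest = {
        "seed": cfg.seed,
        "survival_params": {
            "alpha": cfg.alpha,
            "beta_stage": cfg.beta_stage,
            "beta_size": cfg.beta_size,
            "beta_age": cfg.beta_age,
            "noise_sd": float(sd),
            "cap": cfg.survival_cap,
        },
        "studies": files,
        "patients": {p["sample_id"]: {k: p[k] for k in
                                      ("study", "stage", "size", "age", "survival",
                                       "composite", "ticf_complete", "blanked")}
                     for p in patients},
        "proteins": proteins,
        "modules": modules,
        "aberrations": {sid: sorted(prots) for sid, prots in aberrations.items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def generate_edks_fixture(
    cfg: SyntheticConfig, manifest: dict, path: str | Path
) -> list[tuple[str, str, float]]:
    """Write the protein–protein relation fixture (TSV) standing in for EDKS.

    Within-module pairs (core proteins and the satellite) get high scores;
    random decoy pairs at ``edks_decoy_density`` × n_proteins get low
    scores.  Symmetric, canonically ordered, deterministic for a seed.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    relations: dict[tuple[str, str], float] = {}
    module_pairs: set[tuple[str, str]] = set()
    for mod in manifest["modules"]:
        members = list(mod["proteins"]) + [mod["satellite"]]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair = tuple(sorted((a, b)))
                lo, hi = cfg.edks_core_score
                relations[pair] = round(float(rng.uniform(lo, hi)), 3)
                module_pairs.add(pair)
    proteins = manifest["proteins"]
    n_decoys = round(cfg.edks_decoy_density * len(proteins))
    attempts = 0
    while n_decoys > 0 and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        a, b = rng.choice(proteins, size=2, replace=False)
        pair = tuple(sorted((str(a), str(b))))
        if pair in relations:
            continue
        lo, hi = cfg.edks_decoy_score
        relations[pair] = round(float(rng.uniform(lo, hi)), 3)
        n_decoys -= 1
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["protein_a\tprotein_b\tscore\tprovider"]
    for (a, b), score in sorted(relations.items()):
        lines.append(f"{a}\t{b}\t{score}\tsynthgo")
    path.write_text("\n".join(lines) + "\n")
    out = [(a, b, s) for (a, b), s in sorted(relations.items())]
    manifest["edks_relations"] = [[a, b, s] for a, b, s in out]
    return out
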