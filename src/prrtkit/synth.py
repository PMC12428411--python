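"""Synthetic two-level NEN cohort generator.

Emulates the statistical structure of a single-center metastatic
neuroendocrine-neoplasm cohort: ~65 patients carrying ~392 lesions, 100
patient-level and 104 lesion-level features partitioned into the four
variable groups, retrospective missingness, a minority PRRT-eligible class,
and planted covariate effects on lesion uptake.

Generative model
----------------
Uptake is log-normal and multiplicative.  Each patient i receives a latent
log uptake ratio

    mu_i = beta0 + sum_f effect_f * x_{i,f} + N(0, patient_noise_sd)

where the sum runs over the planted patient-level effects (CK7 positivity
lowers uptake, gastroenteropancreatic/pancreatic origin raises it, lung
origin, NEC histology and prior oncological treatment lower it).  Each lesion
draws one deviation delta ~ N(0, lesion_noise_sd) shared by its two
reference-organ ratios:

    ratio_liver  = exp(mu_i + delta)
    ratio_spleen = exp(mu_i + delta - spleen_offset)

Krenning grades, per-lesion PRRT flags and patient eligibility are then
derived through :mod:`prrtkit.cohort`, so every invariant of the real data
model holds by construction.  The registry records which features carry a
planted effect (``role='planted'``), which have realistic but
uptake-irrelevant structure (``'structured'``) and which are pure noise
(``'noise'``), so recovery tests can score feature rankings against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortError,
    CohortTable,
    FeatureSpec,
    KrenningThresholds,
    krenning_scores,
)

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "default_config",
    "build_registry",
    "generate_cohort",
    "inject_missingness",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted covariate effect, additive on the log uptake-ratio scale."""

    name: str
    effect: float
    level: str = "patient"

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise CohortError(f"effect for {self.name!r} must be finite")
        if self.level not in ("patient", "lesion"):
            raise CohortError(f"level must be patient or lesion; got {self.level!r}")


# Signs: CK7-negative and gastroenteropancreatic origin raise uptake, with
# the pancreatic level strongest; lung origin, NEC histology and prior
# oncological treatment lower it.  Origin levels are disjoint one-hot
# indicators (origin_gi is the non-pancreatic gastrointestinal tract), so
# every planted effect is attached to an identifiable covariate.
DEFAULT_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec("ck7_positive", -0.8),
    EffectSpec("origin_gi", +0.7),
    EffectSpec("origin_pancreas", +1.2),
    EffectSpec("origin_lung", -0.8),
    EffectSpec("nec", -0.9),
    EffectSpec("prior_treatment", -0.6),
)

# Missing fractions of the structured features, mirroring how often each
# marker was actually measured in the emulated retrospective cohort
# (e.g. CK7 measured in 51% of patients -> 0.49 missing).
STRUCTURED_MISSING: dict[str, float] = {
    "ck7_positive": 0.49,
    "ttf1_positive": 0.57,
    "ck20_positive": 0.65,
    "synaptophysin_positive": 0.17,
    "chromogranin_ihc_positive": 0.0,
    "cea": 0.42,
    "ca19_9": 0.49,
    "afp": 0.68,
    "cea_elevated": 0.42,
    "ca19_9_elevated": 0.49,
    "afp_elevated": 0.68,
    "chromogranin_a_serum": 0.05,
    "chromogranin_a_elevated": 0.05,
    "nse": 0.30,
    "ki67": 0.05,
    "t_stage_advanced": 0.28,
    "tumor_size_primary": 0.10,
}

#: Clinical cut-offs separating "elevated" from "normal" serum markers.
LAB_CUTOFFS: dict[str, float] = {
    "cea": 5.0,  # ug/L
    "ca19_9": 37.0,  # kU/L
    "afp": 10.0,  # ug/L
    "chromogranin_a_serum": 100.0,  # ug/L
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the emulated study's structure: 65 patients, a
    shifted-Poisson lesion count targeting ~392 lesions in total (every
    patient has at least one lesion), 100 patient-level and 104
    lesion-analysis features, origin/histology priors matching the reported
    cohort composition, and the planted effect signs above with magnitudes
    of 0.6-0.9 log-units.
    """

    n_patients: int = 65
    # lesions per patient = 1 + Poisson(lesion_rate); mean 6.03 -> ~392 total
    lesion_rate: float = 392 / 65 - 1.0
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS
    baseline_log_uptake: float = 0.63
    patient_noise_sd: float = 0.5
    lesion_noise_sd: float = 0.4
    spleen_offset: float = 0.35
    # patient-level pure-noise features per group (29 structured + 71 = 100)
    n_noise: dict = field(
        default_factory=lambda: {"Onco": 15, "Path": 18, "Imm": 18, "Lab": 20}
    )
    # cohort composition priors
    origin_probs: tuple[float, ...] = (33 / 65, 10 / 65, 7 / 65, 15 / 65)  # gep/lung/unk/other
    pancreas_given_gep: float = 0.4
    nec_given_origin: tuple[float, ...] = (0.06, 0.50, 0.32, 0.32)
    ck7_pos_given_gep: float = 0.20
    ck7_pos_otherwise: float = 0.50
    prior_treatment_p: float = 45 / 65
    ssa_therapy_p: float = 13 / 65
    multi_organ_p: float = 24 / 65
    grade_probs: tuple[float, ...] = (24 / 65, 25 / 65, 16 / 65)
    lab_grade_loading: float = 0.2
    noise_missing_rate: float = 0.10
    missing_rates: dict | None = None  # per-feature override; None -> registry rates
    apply_missingness: bool = True
    thresholds: KrenningThresholds = field(default_factory=KrenningThresholds)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise CohortError("n_patients must be positive")
        if self.lesion_rate < 0:
            raise CohortError("lesion_rate must be nonnegative")
        if self.patient_noise_sd <= 0 or self.lesion_noise_sd <= 0:
            raise CohortError("noise standard deviations must be positive")
        if self.spleen_offset <= 0:
            raise CohortError("spleen_offset must be positive")
        if any(n < 0 for n in self.n_noise.values()):
            raise CohortError("noise feature counts must be nonnegative")
        if unknown := set(self.n_noise) - {"Onco", "Path", "Imm", "Lab"}:
            raise CohortError(f"unknown groups in n_noise: {sorted(unknown)}")


def default_config(seed: int = 0) -> GeneratorConfig:
    """The committed study-like configuration (65 patients, ~392 lesions)."""
    return GeneratorConfig(seed=seed)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def _structured_specs() -> list[FeatureSpec]:
    def ms(name: str) -> float:
        return STRUCTURED_MISSING.get(name, 0.0)

    planted = {e.name for e in DEFAULT_EFFECTS}

    def spec(name, group, dtype, level="patient"):
        role = "planted" if name in planted else "structured"
        return FeatureSpec(name, group, dtype, level, ms(name), role)

    return [
        # Onco: origin (disjoint one-hot levels), treatment history, spread, age
        spec("origin_gi", "Onco", "binary"),
        spec("origin_pancreas", "Onco", "binary"),
        spec("origin_lung", "Onco", "binary"),
        spec("origin_unknown", "Onco", "binary"),
        spec("origin_other", "Onco", "binary"),
        spec("prior_treatment", "Onco", "binary"),
        spec("ssa_therapy", "Onco", "binary"),
        spec("multi_organ_disease", "Onco", "binary"),
        spec("age", "Onco", "numeric"),
        spec("n_lymph_node_mets", "Onco", "numeric"),
        # Path: differentiation, grade, proliferation, primary tumor
        spec("nec", "Path", "binary"),
        spec("grade", "Path", "numeric"),
        spec("ki67", "Path", "numeric"),
        spec("t_stage_advanced", "Path", "binary"),
        spec("tumor_size_primary", "Path", "numeric"),
        # Imm: immunohistochemical markers
        spec("ck7_positive", "Imm", "binary"),
        spec("ck20_positive", "Imm", "binary"),
        spec("ttf1_positive", "Imm", "binary"),
        spec("synaptophysin_positive", "Imm", "binary"),
        spec("chromogranin_ihc_positive", "Imm", "binary"),
        # Lab: serum markers and their elevated/normal flags
        spec("chromogranin_a_serum", "Lab", "numeric"),
        spec("nse", "Lab", "numeric"),
        spec("cea", "Lab", "numeric"),
        spec("ca19_9", "Lab", "numeric"),
        spec("afp", "Lab", "numeric"),
        spec("chromogranin_a_elevated", "Lab", "binary"),
        spec("cea_elevated", "Lab", "binary"),
        spec("ca19_9_elevated", "Lab", "binary"),
        spec("afp_elevated", "Lab", "binary"),
        # Lesion-only slots: metastasis site indicators + lesion size
        spec("site_liver", "Onco", "binary", "lesion"),
        spec("site_lymph_node_or_bone", "Onco", "binary", "lesion"),
        spec("site_lung", "Onco", "binary", "lesion"),
        spec("lesion_size", "Path", "numeric", "lesion"),
    ]


def build_registry(config: GeneratorConfig) -> list[FeatureSpec]:
    """Structured features plus per-group pure-noise fillers.

    With the default noise counts this yields 100 patient-level features and
    104 features for the lesion-level analysis (patient features joined onto
    lesion rows plus the four lesion-only slots).
    """
    specs = _structured_specs()
    for group in ("Onco", "Path", "Imm", "Lab"):
        n = config.n_noise.get(group, 0)
        for i in range(n):
            dtype = "binary" if i % 2 == 0 else "numeric"
            specs.append(
                FeatureSpec(
                    name=f"noise_{group.lower()}_{i + 1:02d}",
                    group=group,
                    dtype=dtype,
                    level="patient",
                    missing_rate=config.noise_missing_rate,
                    role="noise",
                )
            )
    return specs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_patients(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    # disjoint one-hot origin levels: the configured GEP mass is split into
    # the gastrointestinal-tract and pancreatic levels
    p_gep, p_lung, p_unknown, p_other = config.origin_probs
    probs = np.array(
        [
            p_gep * (1.0 - config.pancreas_given_gep),  # gi (non-pancreatic)
            p_gep * config.pancreas_given_gep,  # pancreas
            p_lung,
            p_unknown,
            p_other,
        ]
    )
    origin = rng.choice(5, size=n, p=probs / probs.sum())
    gi = (origin == 0).astype(float)
    pancreas = (origin == 1).astype(float)
    lung = (origin == 2).astype(float)
    unknown = (origin == 3).astype(float)
    other = (origin == 4).astype(float)
    gep = gi + pancreas  # anatomical gastroenteropancreatic membership
    nec_idx = np.where(origin <= 1, 0, origin - 1)  # both GEP levels share a prior
    nec = rng.binomial(1, np.asarray(config.nec_given_origin)[nec_idx]).astype(float)
    ck7 = rng.binomial(
        1, np.where(gep == 1, config.ck7_pos_given_gep, config.ck7_pos_otherwise)
    ).astype(float)

    grade = rng.choice([1.0, 2.0, 3.0], size=n, p=np.asarray(config.grade_probs))
    ki67_mu = np.log(np.choose(grade.astype(int) - 1, [2.0, 10.0, 40.0]))
    ki67 = np.clip(np.exp(ki67_mu + rng.normal(0, 0.5, n)), 0.5, 95.0).round(1)

    def lab(base_log: float, sd: float, extra: np.ndarray = 0.0) -> np.ndarray:
        loading = config.lab_grade_loading * (grade - 2.0)
        return np.exp(base_log + loading + extra + rng.normal(0, sd, n)).round(2)

    cga = lab(np.log(120.0), 1.0)
    nse = lab(np.log(14.0), 0.6)
    cea = lab(np.log(3.0), 0.8, extra=0.2 * lung)
    ca19_9 = lab(np.log(20.0), 0.9, extra=0.2 * pancreas)
    afp = lab(np.log(4.0), 0.7)

    cols: dict[str, np.ndarray] = {
        "origin_gi": gi,
        "origin_pancreas": pancreas,
        "origin_lung": lung,
        "origin_unknown": unknown,
        "origin_other": other,
        "prior_treatment": rng.binomial(1, config.prior_treatment_p, n).astype(float),
        "ssa_therapy": rng.binomial(1, config.ssa_therapy_p, n).astype(float),
        "multi_organ_disease": rng.binomial(1, config.multi_organ_p, n).astype(float),
        "age": np.clip(rng.normal(61.0, 11.0, n), 25.0, 84.0).round(1),
        "n_lymph_node_mets": rng.poisson(2.0, n).astype(float),
        "nec": nec,
        "grade": grade,
        "ki67": ki67,
        "t_stage_advanced": rng.binomial(1, 0.68, n).astype(float),
        "tumor_size_primary": np.exp(rng.normal(np.log(30.0), 0.5, n)).round(1),
        "ck7_positive": ck7,
        "ck20_positive": rng.binomial(1, np.where(gep == 1, 0.35, 0.15), n).astype(float),
        "ttf1_positive": rng.binomial(1, np.where(lung == 1, 0.60, 0.10), n).astype(float),
        "synaptophysin_positive": rng.binomial(1, 0.93, n).astype(float),
        "chromogranin_ihc_positive": rng.binomial(1, 0.90, n).astype(float),
        "chromogranin_a_serum": cga,
        "nse": nse,
        "cea": cea,
        "ca19_9": ca19_9,
        "afp": afp,
        "chromogranin_a_elevated": (cga > LAB_CUTOFFS["chromogranin_a_serum"]).astype(float),
        "cea_elevated": (cea > LAB_CUTOFFS["cea"]).astype(float),
        "ca19_9_elevated": (ca19_9 > LAB_CUTOFFS["ca19_9"]).astype(float),
        "afp_elevated": (afp > LAB_CUTOFFS["afp"]).astype(float),
    }
    return pd.DataFrame(cols)


# site draw: ~72% of patients contribute one detected primary tumor; the
# metastatic sites follow the emulated cohort's liver/nodal/other frequencies
_PRIMARY_P = 47 / 65
_MET_SITES = ("liver", "lymph_node_or_bone", "lung", "other")
_MET_PROBS = (147 / 345, 160 / 345, 15 / 345, 23 / 345)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a complete synthetic cohort; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    registry = build_registry(config)
    n = config.n_patients

    patients = _draw_patients(config, rng)
    # pure-noise features, independent of everything
    for s in registry:
        if s.role == "noise":
            if s.dtype == "binary":
                patients[s.name] = rng.binomial(1, 0.3, n).astype(float)
            else:
                patients[s.name] = rng.normal(0.0, 1.0, n).round(4)
    patients.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(n)])

    # latent patient log-uptake
    mu = np.full(n, config.baseline_log_uptake)
    patient_effects = [e for e in config.effects if e.level == "patient"]
    for e in patient_effects:
        if e.name not in patients.columns:
            raise CohortError(f"effect feature {e.name!r} not in registry")
        mu = mu + e.effect * patients[e.name].to_numpy(dtype=float)
    mu = mu + rng.normal(0.0, config.patient_noise_sd, n)

    # lesions: 1 + Poisson(rate) per patient, one shared deviation per lesion
    n_lesions = 1 + rng.poisson(config.lesion_rate, n)
    pid = np.repeat(patients["patient_id"].to_numpy(), n_lesions)
    total = int(n_lesions.sum())
    lesion_rows = {
        "patient_id": pid,
        "lesion_id": [
            f"{p}_L{j + 1:02d}"
            for p, k in zip(patients["patient_id"], n_lesions)
            for j in range(k)
        ],
    }
    has_primary = rng.binomial(1, _PRIMARY_P, n).astype(bool)
    site = rng.choice(_MET_SITES, size=total, p=np.asarray(_MET_PROBS))
    first_idx = np.concatenate([[0], np.cumsum(n_lesions)[:-1]])
    site[first_idx[has_primary]] = "primary"
    lesion_rows["site"] = site

    delta = rng.normal(0.0, config.lesion_noise_sd, total)
    log_uptake = np.repeat(mu, n_lesions) + delta
    lesion_effects = [e for e in config.effects if e.level == "lesion"]
    lesion_size = np.exp(rng.normal(np.log(25.0), 0.6, total)).round(1)
    lesion_feat = {
        "site_liver": (site == "liver").astype(float),
        "site_lymph_node_or_bone": (site == "lymph_node_or_bone").astype(float),
        "site_lung": (site == "lung").astype(float),
        "lesion_size": lesion_size,
    }
    for e in lesion_effects:
        if e.name not in lesion_feat:
            raise CohortError(f"lesion-level effect feature {e.name!r} unknown")
        log_uptake = log_uptake + e.effect * lesion_feat[e.name]

    ratio_liver = np.exp(log_uptake)
    ratio_spleen = np.exp(log_uptake - config.spleen_offset)
    krenning = krenning_scores(ratio_liver, ratio_spleen, config.thresholds)
    lesion_rows["ratio_liver"] = ratio_liver.round(6)
    lesion_rows["ratio_spleen"] = ratio_spleen.round(6)
    # re-score after rounding so the stored ratios and grades stay consistent
    krenning = krenning_scores(
        lesion_rows["ratio_liver"], lesion_rows["ratio_spleen"], config.thresholds
    )
    lesion_rows["krenning"] = krenning
    lesion_rows["pro_prrt"] = krenning >= 3
    lesions = pd.DataFrame(lesion_rows)
    for name, vals in lesion_feat.items():
        lesions[name] = vals

    min_k = lesions.groupby("patient_id", sort=False)["krenning"].min()
    patients.insert(
        1, "eligible", (min_k.reindex(patients["patient_id"]) >= 3).to_numpy()
    )

    table = CohortTable(
        patients=patients, lesions=lesions, registry=registry,
        thresholds=config.thresholds,
    )
    if config.apply_missingness:
        rates = config.missing_rates
        if rates is None:
            rates = {s.name: s.missing_rate for s in registry}
        table = inject_missingness(table, rates, seed=_derive_seed(config.seed))
    table.validate()
    return table


def _derive_seed(seed: int) -> int:
    # independent stream for the missingness mask, still a function of seed
    return int(np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31))


def inject_missingness(
    table: CohortTable, rates: dict, seed: int
) -> CohortTable:
    """Mask feature cells completely at random at per-feature rates.

    Identifiers, uptake ratios, Krenning grades and outcome flags are never
    masked.  Deterministic given the seed; returns a new table.
    """
    for name, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise CohortError(f"missing rate for {name!r} must lie in [0, 1]; got {rate}")
    rng = np.random.default_rng(seed)
    patients = table.patients.copy()
    lesions = table.lesions.copy()
    for s in table.registry:  # registry order fixes the mask stream
        rate = rates.get(s.name, 0.0)
        frame = patients if s.level == "patient" else lesions
        if rate == 0.0 or s.name not in frame.columns:
            continue
        mask = rng.random(len(frame)) < rate
        col = frame[s.name].astype(float).to_numpy(copy=True)
        col[mask] = np.nan
        frame[s.name] = col
    return replace(table, patients=patients, lesions=lesions)
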