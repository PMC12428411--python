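"""Core domain model for two-level (lesion / patient) somatostatin-receptor cohorts.

A cohort consists of patients with metastatic neuroendocrine neoplasms, each
carrying one or more lesions imaged by somatostatin-receptor SPECT/CT.  Lesion
radiotracer uptake is expressed as unitless ratios against two reference
organs (liver and spleen) and graded on the semiquantitative Krenning scale
(0-4).  Lesions with uptake above the liver (Krenning 3-4) are considered
candidates for peptide receptor radionuclide therapy (PRRT); a patient is
PRRT-eligible only if their *least active* lesion still reaches Krenning 3.

Features are partitioned into four variable groups:

* ``Onco`` - oncological history (origin, prior treatment, spread, age)
* ``Path`` - pathology (grade, Ki-67, differentiation)
* ``Imm``  - immunohistochemistry (CK7, CK20, TTF1, ...)
* ``Lab``  - serum laboratory markers (CEA, CA19-9, AFP, chromogranin A, ...)

This module owns the domain types, Krenning scoring, lesion-to-patient label
aggregation, variable-group bookkeeping and CSV/JSON I/O for the two cohort
tables.  Nothing here fits models; see :mod:`prrtkit.bench`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SITES",
    "CohortError",
    "KrenningThresholds",
    "FeatureSpec",
    "Lesion",
    "Patient",
    "CohortTable",
    "krenning_from_ratios",
    "krenning_scores",
    "lesion_pro_prrt",
    "patient_eligibility",
    "enumerate_group_subsets",
    "read_cohort",
    "write_cohort",
    "load_registry",
    "save_registry",
    "reference_cohort_counts",
]

#: The four variable groups every feature belongs to (exactly one each).
GROUPS: tuple[str, ...] = ("Onco", "Path", "Imm", "Lab")

#: Lesion site labels. Bone and lymph-node findings share one organ group.
SITES: tuple[str, ...] = ("liver", "lymph_node_or_bone", "lung", "other", "primary")

#: Columns in the lesion table that are identifiers/outcomes, never features.
LESION_META_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "lesion_id",
    "site",
    "ratio_liver",
    "ratio_spleen",
    "krenning",
    "pro_prrt",
)

#: Columns in the patient table that are identifiers/outcomes, never features.
PATIENT_META_COLUMNS: tuple[str, ...] = ("patient_id", "eligible")


class CohortError(ValueError):
    """Raised when a domain invariant or I/O contract is violated."""


# ---------------------------------------------------------------------------
# Krenning scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KrenningThresholds:
    """Numeric conventions behind the semiquantitative Krenning grade.

    Parameters
    ----------
    tol
        Half-width of the "uptake comparable to liver" band: a lesion whose
        liver ratio lies in ``[1 - tol, 1 + tol]`` is graded Krenning 2.
    background_cut
        Liver-ratio floor separating faint uptake (Krenning 1) from
        background (Krenning 0).  The clinical literature gives no numeric
        boundary here; 0.2 is this package's declared convention.
    """

    tol: float = 0.1
    background_cut: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.tol < 1.0):
            raise CohortError(f"tol must lie in (0, 1); got {self.tol}")
        if not (0.0 <= self.background_cut < 1.0 - self.tol):
            raise CohortError(
                "thresholds must satisfy background_cut < 1 - tol; got "
                f"background_cut={self.background_cut}, tol={self.tol}"
            )


DEFAULT_THRESHOLDS = KrenningThresholds()


def krenning_from_ratios(
    ratio_liver: float,
    ratio_spleen: float,
    thresholds: KrenningThresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Grade a lesion 0-4 on the Krenning scale from its two uptake ratios.

    Grade 4: uptake above the spleen (``ratio_spleen > 1``).
    Grade 3: uptake above the liver (``ratio_liver > 1 + tol``).
    Grade 2: uptake comparable to the liver (within ``tol``).
    Grade 1: faint uptake (``ratio_liver > background_cut``).
    Grade 0: background.

    The mapping is monotone non-decreasing in each ratio.
    """
    if not (math.isfinite(ratio_liver) and math.isfinite(ratio_spleen)):
        raise CohortError("uptake ratios must be finite")
    if ratio_liver < 0 or ratio_spleen < 0:
        raise CohortError(
            f"uptake ratios must be nonnegative; got liver={ratio_liver}, "
            f"spleen={ratio_spleen}"
        )
    if ratio_spleen > 1.0:
        return 4
    if ratio_liver > 1.0 + thresholds.tol:
        return 3
    if ratio_liver >= 1.0 - thresholds.tol:
        return 2
    if ratio_liver > thresholds.background_cut:
        return 1
    return 0


def krenning_scores(
    ratio_liver: np.ndarray,
    ratio_spleen: np.ndarray,
    thresholds: KrenningThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised :func:`krenning_from_ratios` over aligned ratio arrays."""
    rl = np.asarray(ratio_liver, dtype=float)
    rs = np.asarray(ratio_spleen, dtype=float)
    if rl.shape != rs.shape:
        raise CohortError("ratio arrays must have identical shapes")
    if not (np.isfinite(rl).all() and np.isfinite(rs).all()):
        raise CohortError("uptake ratios must be finite")
    if (rl < 0).any() or (rs < 0).any():
        raise CohortError("uptake ratios must be nonnegative")
    score = np.zeros(rl.shape, dtype=int)
    score[rl > thresholds.background_cut] = 1
    score[rl >= 1.0 - thresholds.tol] = 2
    score[rl > 1.0 + thresholds.tol] = 3
    score[rs > 1.0] = 4
    return score


def lesion_pro_prrt(krenning: int) -> bool:
    """Whether a single lesion's Krenning grade qualifies it for PRRT (>= 3)."""
    if krenning not in (0, 1, 2, 3, 4):
        raise CohortError(f"Krenning score must be an integer 0-4; got {krenning!r}")
    return krenning >= 3


def patient_eligibility(lesions: Sequence) -> bool:
    """Patient-level PRRT suitability from the least active lesion.

    A patient qualifies only if *every* lesion reaches Krenning 3, i.e. the
    minimum Krenning grade over the patient's lesions is >= 3.  Accepts a
    sequence of :class:`Lesion` objects or of integer Krenning grades.
    """
    if len(lesions) == 0:
        raise CohortError("a patient must have at least one lesion")
    scores = [l.krenning if isinstance(l, Lesion) else int(l) for l in lesions]
    for s in scores:
        if s not in (0, 1, 2, 3, 4):
            raise CohortError(f"Krenning score must be an integer 0-4; got {s!r}")
    return min(scores) >= 3


def enumerate_group_subsets(groups: Sequence[str] = GROUPS) -> list[tuple[str, ...]]:
    """All non-empty subsets of the variable groups, in deterministic order.

    Ordered by subset size, then lexicographically.  Four groups yield the
    15 combinations used in the model bench.
    """
    groups = tuple(groups)
    if len(set(groups)) != len(groups):
        raise CohortError(f"duplicate groups in {groups}")
    if not groups:
        raise CohortError("need at least one group")
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(groups) + 1):
        subsets.extend(sorted(itertools.combinations(sorted(groups), size)))
    return subsets


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    """Registry entry describing one feature column.

    ``level`` says which table carries the measurement: patient-level
    features live in the patient table (and are joined onto lesion rows for
    lesion-level analyses), lesion-level features live in the lesion table.
    ``role`` records whether the synthetic generator planted a real effect
    on uptake through this feature (``planted``), generated it with realistic
    but uptake-irrelevant structure (``structured``), or as pure noise
    (``noise``); real-data registries use ``measured``.
    """

    name: str
    group: str
    dtype: str  # "binary" | "numeric"
    level: str  # "patient" | "lesion"
    missing_rate: float = 0.0
    role: str = "measured"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group {self.group!r} for feature {self.name!r}")
        if self.dtype not in ("binary", "numeric"):
            raise CohortError(f"dtype must be binary or numeric; got {self.dtype!r}")
        if self.level not in ("patient", "lesion"):
            raise CohortError(f"level must be patient or lesion; got {self.level!r}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise CohortError(
                f"missing_rate must lie in [0, 1]; got {self.missing_rate} "
                f"for feature {self.name!r}"
            )


@dataclass
class Lesion:
    """One imaged lesion with its uptake ratios and derived Krenning grade."""

    patient_id: str
    lesion_id: str
    site: str
    ratio_liver: float
    ratio_spleen: float
    krenning: int
    pro_prrt: bool
    features: dict = field(default_factory=dict)

    def validate(self, thresholds: KrenningThresholds = DEFAULT_THRESHOLDS) -> None:
        if self.site not in SITES:
            raise CohortError(f"lesion {self.lesion_id}: unknown site {self.site!r}")
        expected = krenning_from_ratios(self.ratio_liver, self.ratio_spleen, thresholds)
        if self.krenning != expected:
            raise CohortError(
                f"lesion {self.lesion_id}: krenning={self.krenning} inconsistent "
                f"with ratios (expected {expected})"
            )
        if self.pro_prrt != lesion_pro_prrt(self.krenning):
            raise CohortError(
                f"lesion {self.lesion_id}: pro_prrt flag inconsistent with krenning"
            )


@dataclass
class Patient:
    """One patient: feature vector, lesions, and derived PRRT eligibility."""

    patient_id: str
    features: dict = field(default_factory=dict)
    lesions: list[Lesion] = field(default_factory=list)
    eligible: bool = False

    def validate(self) -> None:
        if not self.lesions:
            raise CohortError(f"patient {self.patient_id}: no lesions")
        if self.eligible != patient_eligibility(self.lesions):
            raise CohortError(
                f"patient {self.patient_id}: eligible flag inconsistent with "
                "least-active-lesion rule"
            )


@dataclass
class CohortTable:
    """The two cohort tables plus their feature registry.

    ``patients`` has columns ``patient_id, eligible`` followed by the
    patient-level feature columns; ``lesions`` has
    ``patient_id, lesion_id, site, ratio_liver, ratio_spleen, krenning,
    pro_prrt`` followed by the lesion-level feature columns.  Missing
    measurements are NaN.
    """

    patients: pd.DataFrame
    lesions: pd.DataFrame
    registry: list[FeatureSpec]
    thresholds: KrenningThresholds = field(default_factory=KrenningThresholds)

    # -- registry bookkeeping ------------------------------------------------

    def feature_names(
        self, level: str | None = None, groups: Iterable[str] | None = None
    ) -> list[str]:
        """Names of registry features, optionally filtered by level/groups.

        ``level='lesion'`` returns the full lesion-analysis feature set:
        every patient-level feature (joined by patient_id) plus the
        lesion-only features.  ``level='patient'`` returns patient-level
        features only.
        """
        groups = set(groups) if groups is not None else set(GROUPS)
        specs = [s for s in self.registry if s.group in groups]
        if level == "patient":
            specs = [s for s in specs if s.level == "patient"]
        elif level is not None and level != "lesion":
            raise CohortError(f"unknown level {level!r}")
        return [s.name for s in specs]

    def spec(self, name: str) -> FeatureSpec:
        for s in self.registry:
            if s.name == name:
                return s
        raise CohortError(f"feature {name!r} not in registry")

    # -- analysis frames -----------------------------------------------------

    def lesion_analysis_frame(self) -> pd.DataFrame:
        """Lesion rows with patient-level features joined on ``patient_id``.

        This is the design table for lesion-level models: one row per lesion,
        carrying both the lesion-only features and the patient covariates.
        """
        patient_cols = ["patient_id"] + self.feature_names(level="patient")
        return self.lesions.merge(
            self.patients[patient_cols], on="patient_id", how="left", validate="m:1"
        )

    def patient_objects(self) -> list[Patient]:
        """Materialise :class:`Patient`/:class:`Lesion` objects from the frames."""
        lesion_feats = [s.name for s in self.registry if s.level == "lesion"]
        patient_feats = self.feature_names(level="patient")
        out: list[Patient] = []
        lesions_by_pid = dict(tuple(self.lesions.groupby("patient_id", sort=False)))
        for row in self.patients.itertuples(index=False):
            pid = row.patient_id
            sub = lesions_by_pid.get(pid)
            lesions = []
            if sub is not None:
                for lrow in sub.itertuples(index=False):
                    lesions.append(
                        Lesion(
                            patient_id=pid,
                            lesion_id=lrow.lesion_id,
                            site=lrow.site,
                            ratio_liver=float(lrow.ratio_liver),
                            ratio_spleen=float(lrow.ratio_spleen),
                            krenning=int(lrow.krenning),
                            pro_prrt=bool(lrow.pro_prrt),
                            features={f: getattr(lrow, f) for f in lesion_feats},
                        )
                    )
            out.append(
                Patient(
                    patient_id=pid,
                    features={f: getattr(row, f) for f in patient_feats},
                    lesions=lesions,
                    eligible=bool(row.eligible),
                )
            )
        return out

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        """Enforce every cross-table and per-row invariant; raise on violation."""
        names = [s.name for s in self.registry]
        if len(set(names)) != len(names):
            raise CohortError("duplicate feature names in registry")
        for col in PATIENT_META_COLUMNS:
            if col not in self.patients.columns:
                raise CohortError(f"patient table missing column {col!r}")
        for col in LESION_META_COLUMNS:
            if col not in self.lesions.columns:
                raise CohortError(f"lesion table missing column {col!r}")
        for s in self.registry:
            table = self.patients if s.level == "patient" else self.lesions
            if s.name not in table.columns:
                raise CohortError(f"feature column {s.name!r} absent from {s.level} table")
        if self.patients["patient_id"].duplicated().any():
            raise CohortError("duplicate patient_id in patient table")
        known = set(self.patients["patient_id"])
        orphans = self.lesions.loc[~self.lesions["patient_id"].isin(known), "lesion_id"]
        if len(orphans):
            raise CohortError(
                f"lesion(s) {sorted(orphans.tolist())} reference unknown patient_id"
            )
        bad_site = set(self.lesions["site"]) - set(SITES)
        if bad_site:
            raise CohortError(f"unknown lesion site(s) {sorted(bad_site)}")
        expected = krenning_scores(
            self.lesions["ratio_liver"].to_numpy(),
            self.lesions["ratio_spleen"].to_numpy(),
            self.thresholds,
        )
        if not (self.lesions["krenning"].to_numpy() == expected).all():
            raise CohortError("krenning column inconsistent with uptake ratios")
        if not (
            self.lesions["pro_prrt"].astype(bool).to_numpy() == (expected >= 3)
        ).all():
            raise CohortError("pro_prrt column inconsistent with krenning")
        min_k = self.lesions.groupby("patient_id")["krenning"].min()
        missing = known - set(min_k.index)
        if missing:
            raise CohortError(f"patient(s) {sorted(missing)} have no lesions")
        elig = self.patients.set_index("patient_id")["eligible"].astype(bool)
        if not (elig == (min_k.reindex(elig.index) >= 3)).all():
            raise CohortError("eligible column inconsistent with least-active-lesion rule")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_registry(registry: Sequence[FeatureSpec], path: str | Path) -> None:
    """Write the feature registry as JSON (name -> group/dtype/level/...)."""
    payload = {
        s.name: {
            "group": s.group,
            "dtype": s.dtype,
            "level": s.level,
            "missing_rate": s.missing_rate,
            "role": s.role,
        }
        for s in registry
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False))


def load_registry(path: str | Path) -> list[FeatureSpec]:
    payload = json.loads(Path(path).read_text())
    return [FeatureSpec(name=name, **attrs) for name, attrs in payload.items()]


def write_cohort(table: CohortTable, out_dir: str | Path) -> dict[str, Path]:
    """Write ``lesions.csv``, ``patients.csv`` and ``registry.json``.

    Missing values are written as empty cells; binary features are 0/1.
    Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lesions": out / "lesions.csv",
        "patients": out / "patients.csv",
        "registry": out / "registry.json",
    }
    lesion_cols = list(LESION_META_COLUMNS) + [
        s.name for s in table.registry if s.level == "lesion"
    ]
    patient_cols = list(PATIENT_META_COLUMNS) + [
        s.name for s in table.registry if s.level == "patient"
    ]
    table.lesions[lesion_cols].to_csv(paths["lesions"], index=False)
    table.patients[patient_cols].to_csv(paths["patients"], index=False)
    save_registry(table.registry, paths["registry"])
    return paths


def _read_feature_columns(
    df: pd.DataFrame, specs: list[FeatureSpec], path: str
) -> pd.DataFrame:
    for s in specs:
        if s.name not in df.columns:
            raise CohortError(f"{path}: missing feature column {s.name!r}")
        try:
            df[s.name] = pd.to_numeric(df[s.name], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CohortError(f"{path}: non-numeric value in column {s.name!r}: {exc}")
    return df


def read_cohort(
    lesion_csv: str | Path,
    patient_csv: str | Path,
    registry: Sequence[FeatureSpec] | str | Path,
    thresholds: KrenningThresholds = DEFAULT_THRESHOLDS,
    validate: bool = True,
) -> CohortTable:
    """Read the two cohort CSVs back into a validated :class:`CohortTable`.

    ``registry`` may be a list of :class:`FeatureSpec` or a path to
    ``registry.json``.  Empty cells become NaN (explicit missingness); they
    are never imputed here.  Round-trips losslessly with :func:`write_cohort`.
    """
    if isinstance(registry, (str, Path)):
        registry = load_registry(registry)
    registry = list(registry)
    lesion_specs = [s for s in registry if s.level == "lesion"]
    patient_specs = [s for s in registry if s.level == "patient"]

    lesions = pd.read_csv(lesion_csv, dtype={"patient_id": str, "lesion_id": str})
    patients = pd.read_csv(patient_csv, dtype={"patient_id": str})

    for col in LESION_META_COLUMNS:
        if col not in lesions.columns:
            raise CohortError(f"{lesion_csv}: missing required column {col!r}")
    for col in PATIENT_META_COLUMNS:
        if col not in patients.columns:
            raise CohortError(f"{patient_csv}: missing required column {col!r}")
    known_cols = set(LESION_META_COLUMNS) | {s.name for s in lesion_specs}
    unknown = set(lesions.columns) - known_cols
    if unknown:
        raise CohortError(f"{lesion_csv}: unknown column(s) {sorted(unknown)}")
    known_cols = set(PATIENT_META_COLUMNS) | {s.name for s in patient_specs}
    unknown = set(patients.columns) - known_cols
    if unknown:
        raise CohortError(f"{patient_csv}: unknown column(s) {sorted(unknown)}")

    for col in ("ratio_liver", "ratio_spleen"):
        try:
            lesions[col] = pd.to_numeric(lesions[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise CohortError(f"{lesion_csv}: non-numeric {col}: {exc}")
        if lesions[col].isna().any():
            row = int(lesions.index[lesions[col].isna()][0])
            raise CohortError(f"{lesion_csv}: missing {col} at row {row}")
    lesions["krenning"] = lesions["krenning"].astype(int)
    lesions["pro_prrt"] = lesions["pro_prrt"].astype(bool)
    patients["eligible"] = patients["eligible"].astype(bool)
    lesions = _read_feature_columns(lesions, lesion_specs, str(lesion_csv))
    patients = _read_feature_columns(patients, patient_specs, str(patient_csv))

    table = CohortTable(
        patients=patients, lesions=lesions, registry=registry, thresholds=thresholds
    )
    if validate:
        table.validate()
    return table


# ---------------------------------------------------------------------------
# Reference cohort constants
# ---------------------------------------------------------------------------


def reference_cohort_counts() -> dict[str, int]:
    """Headline counts of the single-center NEN cohort the generator emulates.

    Used as fixture constants when sizing synthetic cohorts and as a sanity
    surface in the pipeline summary.
    """
    return {
        "patients": 65,
        "patients_eligible": 21,
        "patients_not_eligible": 44,
        "lesions": 392,
        "lesions_primary": 47,
        "lesions_metastatic": 345,
        "krenning_3_4": 197,
        "krenning_2": 35,
        "krenning_0_1": 160,
        "net": 51,
        "nec": 14,
    }
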