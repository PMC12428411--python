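"""Classical statistical confirmation of the consensus features.

Selected features are re-tested with nonparametric tests at alpha = 0.05:
at the lesion level the continuous outcome is the lesion-to-liver uptake
ratio (Mann-Whitney U for two groups, Kruskal-Wallis for more); at the
patient level PRRT eligibility is cross-tabulated against each binary
feature with a Chi-square test.  Raw p-values are used (no multiplicity
correction by default, matching the framework; a Benjamini-Hochberg flag is
available).  Numeric features are dichotomised at clinical cut-offs
(age 55 years; serum-marker normal ranges) before two-group testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, CohortTable

__all__ = [
    "ALPHA",
    "DEFAULT_CUTOFFS",
    "ValidationResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_square_test",
    "validate_features",
]

ALPHA = 0.05

#: Dichotomisation cut-offs for numeric features (value > cutoff -> group 1).
DEFAULT_CUTOFFS: dict[str, float] = {
    "age": 55.0,
    "cea": 5.0,
    "ca19_9": 37.0,
    "afp": 10.0,
    "chromogranin_a_serum": 100.0,
    "nse": 16.0,
    "ki67": 20.0,
    "tumor_size_primary": 40.0,
    "lesion_size": 40.0,
}


def mann_whitney_u(
    sample_a, sample_b, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates the null distribution (valid only without
    ties); ``'normal_approx'`` uses the tie-corrected normal approximation
    with continuity correction; ``'auto'`` picks exact when both samples have
    at most 8 observations and no ties.  Returns (U, p) with U counted for
    the first sample (number of (a, b) pairs with a > b, plus half-ties).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("Mann-Whitney requires two non-empty samples")
    if np.isnan(a).any() or np.isnan(b).any():
        raise CohortError("samples must not contain missing values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        mode = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise CohortError("exact Mann-Whitney p is undefined with ties")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal_approx":
        if has_ties and len(np.unique(np.concatenate([a, b]))) == 1:
            # all observations identical: no evidence either way
            return float(a.size * b.size / 2.0), 1.0
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise CohortError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test over two or more samples (tie-corrected).

    All-identical observations yield H = 0, p = 1 with a ties warning.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise CohortError("Kruskal-Wallis requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise CohortError("all groups must be non-empty")
    if sum(g.size for g in arrays) < 3:
        raise CohortError("Kruskal-Wallis requires a total of at least 3 observations")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        warnings.warn("all observations identical; H = 0", stacklevel=2)
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(
    table, correction: bool = False
) -> tuple[float, float]:
    """Pearson Chi-square test of independence on an r x c contingency table.

    No continuity correction by default.  A zero row/column margin is a
    validation error; expected counts below 5 raise a warning only.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any() or not np.isfinite(tab).all():
        raise CohortError("contingency table must be a nonnegative 2-D array")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise CohortError("contingency table has a zero row or column margin")
    chi2, p, _, expected = stats.chi2_contingency(tab, correction=correction)
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; Chi-square approximation is weak",
                      stacklevel=2)
    return float(chi2), float(p)


@dataclass
class ValidationResult:
    """Outcome of one classical test on one selected feature."""

    feature: str
    level: str  # "lesion" | "patient"
    test: str  # "mann_whitney" | "kruskal_wallis" | "chi_square"
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _dichotomize(values: np.ndarray, name: str, cutoffs: dict[str, float]) -> np.ndarray:
    cut = cutoffs.get(name, float(np.nanmedian(values)))
    return (values > cut).astype(float)


@dataclass
class _Routing:
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    max_categories: int = 4  # integer-valued numerics with <= this many levels -> KW


def validate_features(
    selected: list[str],
    cohort: CohortTable,
    cutoffs: dict[str, float] | None = None,
    bh_correction: bool = False,
) -> list[ValidationResult]:
    """Confirm selected features with rank / Chi-square tests at both levels.

    Lesion level: the lesion-to-liver uptake ratio is compared between
    feature groups (Mann-Whitney for binary / dichotomised features,
    Kruskal-Wallis for few-level categorical numerics).  Patient level:
    eligibility x binary feature on a 2x2 table with Chi-square.  Missing
    values are excluded pairwise; features with fewer than two observed
    levels are skipped with a warning.  With ``bh_correction`` p-values are
    Benjamini-Hochberg adjusted within each level.
    """
    routing = _Routing(cutoffs={**DEFAULT_CUTOFFS, **(cutoffs or {})})
    lesion_frame = cohort.lesion_analysis_frame()
    results: list[ValidationResult] = []
    for name in selected:
        spec = cohort.spec(name)
        # ---- lesion level: uptake ratio across feature groups -------------
        vals = lesion_frame[name].to_numpy(dtype=float)
        outcome = lesion_frame["ratio_liver"].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        v, out = vals[obs], outcome[obs]
        res = _lesion_test(name, spec.dtype, v, out, routing)
        if res is not None:
            results.append(res)
        # ---- patient level: eligibility x dichotomised feature ------------
        if spec.level == "patient":
            pvals = cohort.patients[name].to_numpy(dtype=float)
            elig = cohort.patients["eligible"].astype(int).to_numpy()
            obs = ~np.isnan(pvals)
            res = _patient_test(name, spec.dtype, pvals[obs], elig[obs], routing)
            if res is not None:
                results.append(res)
    if bh_correction:
        results = _bh_adjust(results)
    return results


def _lesion_test(
    name: str, dtype: str, values: np.ndarray, outcome: np.ndarray, routing: _Routing
) -> ValidationResult | None:
    levels = np.unique(values)
    if levels.size < 2:
        warnings.warn(f"feature {name!r}: fewer than two observed levels; skipped",
                      stacklevel=3)
        return None
    is_categorical = (
        dtype == "binary"
        or (np.allclose(values, np.round(values)) and levels.size <= routing.max_categories)
    )
    if is_categorical and levels.size > 2:
        groups = [outcome[values == lv] for lv in levels]
        h, p = kruskal_wallis(*groups)
        return ValidationResult(
            name, "lesion", "kruskal_wallis", h, p, tuple(len(g) for g in groups)
        )
    if not is_categorical:
        values = _dichotomize(values, name, routing.cutoffs)
        levels = np.unique(values)
        if levels.size < 2:
            warnings.warn(f"feature {name!r}: degenerate after dichotomisation; skipped",
                          stacklevel=3)
            return None
    lo = outcome[values == levels.min()]
    hi = outcome[values == levels.max()]
    u, p = mann_whitney_u(hi, lo, mode="normal_approx")
    return ValidationResult(
        name, "lesion", "mann_whitney", u, p, (len(hi), len(lo)),
        note="U counted for the high/positive group",
    )


def _patient_test(
    name: str, dtype: str, values: np.ndarray, eligible: np.ndarray, routing: _Routing
) -> ValidationResult | None:
    if dtype != "binary":
        values = _dichotomize(values, name, routing.cutoffs)
    levels = np.unique(values)
    if levels.size < 2 or np.unique(eligible).size < 2:
        warnings.warn(
            f"feature {name!r}: degenerate patient-level table; skipped", stacklevel=3
        )
        return None
    tab = np.array(
        [
            [np.sum((values == lv) & (eligible == e)) for e in (0, 1)]
            for lv in levels
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2, p = chi_square_test(tab)
    return ValidationResult(
        name, "patient", "chi_square", chi2, p, tuple(int(t) for t in tab.sum(axis=1))
    )


def _bh_adjust(results: list[ValidationResult]) -> list[ValidationResult]:
    from statsmodels.stats.multitest import multipletests

    out: list[ValidationResult] = []
    for level in ("lesion", "patient"):
        sub = [r for r in results if r.level == level]
        if not sub:
            continue
        _, adj, _, _ = multipletests([r.p_value for r in sub], method="fdr_bh")
        for r, q in zip(sub, adj):
            out.append(
                ValidationResult(
                    r.feature, r.level, r.test, r.statistic, float(q),
                    r.group_sizes, note=(r.note + " BH-adjusted").strip(),
                )
            )
    return out


def results_frame(results: list[ValidationResult]) -> pd.DataFrame:
    """Tabular view of validation results (one row per feature x test)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "level": r.level,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "group_sizes": "/".join(str(n) for n in r.group_sizes),
                "note": r.note,
            }
            for r in results
        ]
    )
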