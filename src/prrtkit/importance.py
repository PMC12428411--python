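"""F1-weighted permutation-importance consensus feature ranking.

The ranking framework proceeds, per analysis level (lesion / patient):

1.  permutation importance (PI): for each fitted grid cell and each feature,
    the mean decrease in test-set F1 over ``n_perm`` random permutations of
    that feature's column (all other columns untouched);
2.  correlation filtering: features whose mean |PI| is below ``eps`` in every
    configuration are dropped, and a feature-feature Spearman rank-correlation
    triangle is emitted as a report artifact;
3.  stabilisation: per configuration, |PI| is averaged across the repeated
    random splits;
4.  model weighting: each configuration's mean F1 is normalised by the mean
    F1 over all configurations, so stronger models carry proportionally more
    weight;
5.  aggregation: the final feature importance (FI) is the weight-normalised
    average of stabilised PI across configurations, max-normalised to 1;
6.  selection: the top fraction (default 10%) of retained features;
7.  consensus: features selected at *both* the lesion and the patient level.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bench import TARGET_AVERAGING, BenchCell, BenchResult, f1
from .cohort import CohortError

__all__ = [
    "FIRanking",
    "permutation_importance",
    "compute_pi_table",
    "correlation_filter",
    "stabilize_pi",
    "model_weights",
    "aggregate_fi",
    "select_top",
    "consensus",
    "rank_features",
]


def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    columns: list[int],
    n_perm: int = 100,
    seed: int = 0,
    averaging: str = "binary",
) -> float:
    """Mean decrease in F1 when one feature's test column(s) are permuted.

    ``columns`` are the encoded-matrix column indices belonging to the
    feature (a value column plus, when present, its missing-indicator; the
    same row permutation is applied to all of them, which is equivalent to
    permuting the raw feature before encoding).  May be negative.  A constant
    column yields 0 with a warning, since permutation cannot change it.
    """
    X_test = np.asarray(X_test, dtype=float)
    n = len(X_test)
    sub = X_test[:, columns]
    if all((sub[:, j] == sub[0, j]).all() for j in range(sub.shape[1])):
        warnings.warn("permutation importance of a constant column is 0", stacklevel=2)
        return 0.0
    baseline = f1(y_test, model.predict(X_test), averaging)
    rng = np.random.default_rng(seed)
    # one batched predict over all permutations
    big = np.tile(X_test, (n_perm, 1))
    for r in range(n_perm):
        perm = rng.permutation(n)
        big[r * n : (r + 1) * n, columns] = sub[perm]
    preds = model.predict(big)
    scores = [
        f1(y_test, preds[r * n : (r + 1) * n], averaging) for r in range(n_perm)
    ]
    return baseline - float(np.mean(scores))


def compute_pi_table(
    bench: BenchResult, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """PI records for every (config, split, feature) of the retained cells.

    Features are the registry-level features of each cell (indicator columns
    are permuted jointly with their value column, never scored separately).
    """
    if not bench.cells:
        raise CohortError("bench result holds no fitted cells; rerun with keep_models=True")
    rows = []
    for cell in bench.cells:
        averaging = TARGET_AVERAGING[cell.config.target]
        # process-independent per-cell seed (python's hash() is salted)
        cell_seed = (
            zlib.crc32(f"{cell.config.config_id}|{cell.split}|{seed}".encode())
            % (2**31)
        )
        rng = np.random.default_rng(cell_seed)
        n = len(cell.X_test)
        big = np.tile(cell.X_test, (n_perm, 1))  # shared batch buffer
        baseline = f1(cell.y_test, cell.model.predict(cell.X_test), averaging)
        for feat in sorted(cell.feature_cols):
            cols = cell.feature_cols[feat]
            sub = cell.X_test[:, cols]
            feat_seed = int(rng.integers(2**31))
            if all((sub[:, j] == sub[0, j]).all() for j in range(sub.shape[1])):
                pi = 0.0
            else:
                perm_rng = np.random.default_rng(feat_seed)
                for r in range(n_perm):
                    big[r * n : (r + 1) * n, cols] = sub[perm_rng.permutation(n)]
                preds = cell.model.predict(big)
                pi = baseline - float(
                    np.mean(
                        [
                            f1(cell.y_test, preds[r * n : (r + 1) * n], averaging)
                            for r in range(n_perm)
                        ]
                    )
                )
                # restore the buffer for the next feature
                for r in range(n_perm):
                    big[r * n : (r + 1) * n, cols] = sub
            rows.append(
                {
                    "config_id": cell.config.config_id,
                    "split": cell.split,
                    "feature": feat,
                    "pi": pi,
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


def correlation_filter(
    pi_table: pd.DataFrame,
    feature_frame: pd.DataFrame | None = None,
    eps: float = 1e-6,
) -> tuple[list[str], pd.DataFrame | None]:
    """Drop features with negligible PI everywhere; emit the rank-correlation triangle.

    A feature is retained if its mean |PI| reaches ``eps`` in at least one
    configuration.  ``eps=0`` disables the filter.  The optional
    ``feature_frame`` (raw feature columns) yields a lower-triangular
    Spearman correlation matrix returned as a report artifact.
    """
    if eps < 0:
        raise CohortError("eps must be nonnegative")
    stab = stabilize_pi(pi_table)
    keep = stab.groupby("feature")["stabilized_pi"].max()
    retained = sorted(keep.index[keep >= eps]) if eps > 0 else sorted(keep.index)
    if not retained:
        raise CohortError(
            f"correlation filter dropped every feature (eps={eps}); decrease eps"
        )
    triangle = None
    if feature_frame is not None:
        cols = [c for c in feature_frame.columns if c in set(keep.index)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(feature_frame[cols], nan_policy="omit").statistic
        rho = np.atleast_2d(rho)
        tri = np.tril(rho)
        triangle = pd.DataFrame(tri, index=cols, columns=cols)
    return retained, triangle


def stabilize_pi(pi_table: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute PI per (configuration, feature) across splits."""
    needed = {"config_id", "split", "feature", "pi"}
    if not needed <= set(pi_table.columns):
        raise CohortError(f"PI table must have columns {sorted(needed)}")
    out = (
        pi_table.assign(abs_pi=pi_table["pi"].abs())
        .groupby(["config_id", "feature"], sort=False)["abs_pi"]
        .mean()
        .rename("stabilized_pi")
        .reset_index()
    )
    return out


def model_weights(mean_f1: pd.Series) -> pd.Series:
    """Per-configuration weight: F1 normalised by the mean F1 of all configs."""
    mean_f1 = mean_f1.astype(float)
    if ((mean_f1 < 0) | (mean_f1 > 1)).any():
        raise CohortError("mean F1 values must lie in [0, 1]")
    overall = mean_f1.mean()
    if overall <= 0:
        raise CohortError("all configurations scored F1 = 0; weights undefined")
    return mean_f1 / overall


@dataclass
class FIRanking:
    """Aggregated feature-importance ranking for one analysis level.

    ``table`` columns: feature, fi (max-normalised to 1), rank (1 = most
    important), coverage (number of configurations containing the feature),
    selected (top-fraction flag, set by :func:`select_top`).
    """

    level: str
    table: pd.DataFrame

    @property
    def selected(self) -> list[str]:
        t = self.table
        return t.loc[t["selected"], "feature"].tolist()


def aggregate_fi(
    stabilized: pd.DataFrame,
    weights: pd.Series,
    level: str = "lesion",
    retained: list[str] | None = None,
) -> FIRanking:
    """Weight-averaged stabilised PI -> final feature importance ranking.

    ``fi_f = sum_m w_m s_{m,f} / sum_m w_m`` over the configurations m whose
    group subset contains feature f (coverage is reported).  Values are
    max-normalised for reporting; ties in rank break lexicographically.
    """
    stab = stabilized
    if retained is not None:
        stab = stab[stab["feature"].isin(set(retained))]
    missing = set(stab["config_id"]) - set(weights.index)
    if missing:
        raise CohortError(f"no weight for config(s) {sorted(missing)}")
    stab = stab.assign(w=weights.reindex(stab["config_id"]).to_numpy())
    grouped = stab.groupby("feature", sort=False)
    fi = grouped.apply(
        lambda g: np.average(g["stabilized_pi"], weights=g["w"]),
        include_groups=False,
    ).rename("fi")
    coverage = grouped.size().rename("coverage")
    table = pd.concat([fi, coverage], axis=1).reset_index()
    top = table["fi"].max()
    if top > 0:
        table["fi"] = table["fi"] / top
    table = table.sort_values(
        ["fi", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = False
    return FIRanking(level=level, table=table)


def select_top(ranking: FIRanking, fraction: float = 0.10) -> list[str]:
    """Mark and return the top ``ceil(fraction * n)`` features by rank."""
    if not (0.0 < fraction <= 1.0):
        raise CohortError("fraction must lie in (0, 1]")
    n = len(ranking.table)
    if n == 0:
        raise CohortError("empty ranking")
    k = math.ceil(fraction * n)
    ranking.table["selected"] = ranking.table["rank"] <= k
    return ranking.table.loc[ranking.table["selected"], "feature"].tolist()


def consensus(lesion: FIRanking, patient: FIRanking) -> pd.DataFrame:
    """Features selected at both levels, ordered by mean normalised FI.

    Returns a frame with columns feature, fi_lesion, fi_patient, fi_mean.
    Empty (with a warning) when the selected sets are disjoint.
    """
    if not set(lesion.table["feature"]) & set(patient.table["feature"]):
        warnings.warn("lesion and patient rankings share no feature names", stacklevel=2)
    les = lesion.table[lesion.table["selected"]][["feature", "fi"]]
    pat = patient.table[patient.table["selected"]][["feature", "fi"]]
    merged = les.merge(pat, on="feature", suffixes=("_lesion", "_patient"))
    merged["fi_mean"] = (merged["fi_lesion"] + merged["fi_patient"]) / 2.0
    return merged.sort_values(
        ["fi_mean", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def rank_features(
    bench: BenchResult,
    level: str,
    feature_frame: pd.DataFrame | None = None,
    n_perm: int = 100,
    fraction: float = 0.10,
    eps: float = 1e-6,
    seed: int = 0,
) -> tuple[FIRanking, pd.DataFrame, pd.DataFrame | None]:
    """Run PI -> filter -> stabilise -> weight -> aggregate -> select for one level.

    Uses the bench's retained cells whose target belongs to ``level``
    (the linear baseline is excluded from importance, per the framework).
    Returns the ranking (with selection applied), the raw PI table, and the
    correlation triangle artifact.
    """
    cells = [
        c
        for c in bench.cells
        if c.config.level == level and c.config.learner != "linear"
    ]
    if not cells:
        raise CohortError(f"no fitted non-linear cells at level {level!r}")
    sub = BenchResult(records=bench.records, cells=cells)
    pi_table = compute_pi_table(sub, n_perm=n_perm, seed=seed)
    retained, triangle = correlation_filter(pi_table, feature_frame, eps=eps)
    stab = stabilize_pi(pi_table)
    ids = sorted({c.config.config_id for c in cells})
    weights = model_weights(sub.mean_f1().reindex(ids).dropna())
    ranking = aggregate_fi(stab, weights, level=level, retained=retained)
    select_top(ranking, fraction)
    return ranking, pi_table, triangle
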