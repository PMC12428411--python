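"""Model bench: learner x SMOTE x variable-group-subset x repeated-split grid.

Runs the classification bench at both analysis levels: predicting each
lesion's PRRT flag (or its 3-bin Krenning grade) and each patient's overall
eligibility.  For every configuration the data are randomly re-split into
80% training / 20% test many times; minority oversampling (SMOTE), imputation
and encoding are fit on training rows only, and performance is the F1 score
on the untouched test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .cohort import GROUPS, CohortError, CohortTable

__all__ = [
    "LEARNERS",
    "TARGETS",
    "ModelConfig",
    "BenchCell",
    "BenchResult",
    "split_indices",
    "smote_oversample",
    "split_indices_grouped",
    "impute_and_encode",
    "f1",
    "train_model",
    "build_design",
    "run_bench",
    "default_grid",
]

LEARNERS = ("linear", "bagged_trees", "boosted_trees")
TARGETS = ("krenning_bin", "pro_prrt_lesion", "pro_prrt_patient")

#: F1 averaging per target: binary (positive class = PRRT-suitable) for the
#: two-class flags, unweighted macro for the 3-bin Krenning grade.
TARGET_AVERAGING = {
    "krenning_bin": "macro",
    "pro_prrt_lesion": "binary",
    "pro_prrt_patient": "binary",
}


@dataclass(frozen=True)
class ModelConfig:
    """One cell family of the bench grid."""

    learner: str
    smote: bool
    target: str
    groups: tuple[str, ...]
    n_splits: int = 100
    train_frac: float = 0.8
    smote_k: int = 5
    seed: int = 0
    n_trees: int = 500
    max_depth: int = 3
    learning_rate: float = 0.1
    #: lesion-level sensitivity option: split by patient so no patient's
    #: lesions straddle the train/test boundary (default: plain row-wise)
    patient_grouped: bool = False

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise CohortError(f"unknown learner {self.learner!r}")
        if self.target not in TARGETS:
            raise CohortError(f"unknown target {self.target!r}")
        if not self.groups or set(self.groups) - set(GROUPS):
            raise CohortError(f"groups must be a non-empty subset of {GROUPS}")
        if not (0.0 < self.train_frac < 1.0):
            raise CohortError("train_frac must lie in (0, 1)")
        if self.n_splits < 1 or self.smote_k < 1:
            raise CohortError("n_splits and smote_k must be positive")

    @property
    def level(self) -> str:
        return "patient" if self.target == "pro_prrt_patient" else "lesion"

    @property
    def config_id(self) -> str:
        smote = "smote" if self.smote else "raw"
        return f"{self.learner}|{smote}|{'+'.join(self.groups)}|{self.target}"


def split_indices(
    n_rows: int, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One random, disjoint, exhaustive train/test row partition."""
    if n_rows < 5:
        raise CohortError(f"need at least 5 rows to split; got {n_rows}")
    n_train = int(round(train_frac * n_rows))
    if n_rows - n_train < 2 or n_train < 2:
        raise CohortError(
            f"train_frac={train_frac} leaves a degenerate partition of {n_rows} rows"
        )
    perm = np.random.default_rng(seed).permutation(n_rows)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_indices_grouped(
    group_ids: np.ndarray, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row partition that keeps all rows of one group on the same side.

    Groups (patients) are shuffled and assigned to training until the target
    row fraction is reached; the remaining groups form the test partition.
    """
    group_ids = np.asarray(group_ids)
    n_rows = len(group_ids)
    if n_rows < 5:
        raise CohortError(f"need at least 5 rows to split; got {n_rows}")
    uniq = np.unique(group_ids)
    if len(uniq) < 3:
        raise CohortError("grouped split needs at least 3 distinct groups")
    order = np.random.default_rng(seed).permutation(uniq)
    target = round(train_frac * n_rows)
    counts = pd.Series(group_ids).value_counts()
    train_groups = []
    total = 0
    for g in order:
        if total >= target:
            break
        train_groups.append(g)
        total += int(counts[g])
    train_groups = set(train_groups)
    mask = np.array([g in train_groups for g in group_ids])
    train, test = np.where(mask)[0], np.where(~mask)[0]
    if len(train) < 2 or len(test) < 2:
        raise CohortError("grouped split produced a degenerate partition")
    return train, test


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority interpolation (SMOTE).

    Every synthetic sample is ``x + lam * (x_nn - x)`` with ``lam ~ U[0, 1)``
    and ``x_nn`` one of the ``k`` nearest minority-class neighbours of ``x``
    (Euclidean).  Original rows are retained unchanged; every class is topped
    up to the majority-class count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise CohortError("X must be 2-D and aligned with y")
    if not np.isfinite(X).all():
        raise CohortError("SMOTE requires fully imputed numeric features")
    classes, counts = np.unique(y, return_counts=True)
    n_major = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = n_major - count
        if need == 0:
            continue
        if count < 2:
            raise CohortError(
                f"class {cls!r} has a single training sample; SMOTE needs >= 2 "
                "(reduce k or skip oversampling)"
            )
        k_eff = min(k, count - 1)
        if k_eff < k:
            warnings.warn(
                f"SMOTE: k reduced from {k} to {k_eff} for class {cls!r} "
                f"({count} samples)",
                stacklevel=2,
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, count, size=need)
        pick = neigh[base, rng.integers(0, k_eff, size=need)]
        lam = rng.random(need)[:, None]
        synth = Xc[base] + lam * (Xc[pick] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def impute_and_encode(
    train: pd.DataFrame,
    test: pd.DataFrame,
    dtypes: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, list[int]]]:
    """Fit imputation on training rows only and apply it to both partitions.

    Numeric columns are filled with the training median; binary columns with
    the training mode plus an appended missing-indicator column (only when
    the training column actually has gaps).  Columns that are entirely
    missing in training are dropped with a warning.

    Returns the two numeric matrices, the encoded column names, and a map
    from each input feature to the indices of its encoded column(s).
    """
    cols: list[np.ndarray] = []
    tcols: list[np.ndarray] = []
    names: list[str] = []
    feature_cols: dict[str, list[int]] = {}
    for name in train.columns:
        tr = train[name].to_numpy(dtype=float)
        te = test[name].to_numpy(dtype=float)
        miss_tr = np.isnan(tr)
        if miss_tr.all():
            warnings.warn(f"column {name!r} entirely missing in training; dropped",
                          stacklevel=2)
            continue
        dtype = dtypes.get(name, "numeric")
        if dtype == "binary":
            vals, cnts = np.unique(tr[~miss_tr], return_counts=True)
            fill = float(vals[np.argmax(cnts)])
        else:
            fill = float(np.nanmedian(tr))
        idx = [len(names)]
        cols.append(np.where(miss_tr, fill, tr))
        tcols.append(np.where(np.isnan(te), fill, te))
        names.append(name)
        if dtype == "binary" and miss_tr.any():
            idx.append(len(names))
            cols.append(miss_tr.astype(float))
            tcols.append(np.isnan(te).astype(float))
            names.append(f"{name}__missing")
        feature_cols[name] = idx
    if not names:
        raise CohortError("no usable feature columns after imputation")
    return (
        np.column_stack(cols),
        np.column_stack(tcols),
        names,
        feature_cols,
    )


def _f1_one_class(y_true: np.ndarray, y_pred: np.ndarray, cls) -> float:
    tp = np.count_nonzero((y_true == cls) & (y_pred == cls))
    fp = np.count_nonzero((y_true != cls) & (y_pred == cls))
    fn = np.count_nonzero((y_true == cls) & (y_pred != cls))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def f1(y_true: np.ndarray, y_pred: np.ndarray, averaging: str = "binary") -> float:
    """F1 score: harmonic mean of positive predictive value and sensitivity.

    ``binary`` scores the PRRT-suitable class (label 1); ``macro`` averages
    per-class F1 without weighting.  Degenerate cases (no predicted and no
    true positives) score 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise CohortError("y_true and y_pred must have the same length")
    if averaging == "binary":
        if set(np.unique(y_true)) - {0, 1} or set(np.unique(y_pred)) - {0, 1}:
            raise CohortError("binary averaging requires 0/1 labels")
        return float(_f1_one_class(y_true, y_pred, 1))
    if averaging == "macro":
        classes = np.union1d(np.unique(y_true), np.unique(y_pred))
        return float(np.mean([_f1_one_class(y_true, y_pred, c) for c in classes]))
    raise CohortError(f"unknown averaging {averaging!r}")


def train_model(
    learner: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
    max_depth: int = 3,
    learning_rate: float = 0.1,
):
    """Fit a deterministic-given-seed classifier of the requested kind.

    ``linear``: L2-regularised logistic regression (the discontinued
    baseline); ``bagged_trees``: random forest; ``boosted_trees``: gradient
    boosting with sequential additive trees.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise CohortError("training labels contain a single class")
    if learner == "linear":
        model = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    elif learner == "bagged_trees":
        model = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
    elif learner == "boosted_trees":
        model = XGBClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    else:
        raise CohortError(f"unknown learner {learner!r}")
    model.fit(X, y.astype(int))
    return model


def build_design(
    cohort: CohortTable, target: str, groups: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature frame (per the group subset) and integer label vector."""
    frame, y, _ = build_design_with_ids(cohort, target, groups)
    return frame, y


def build_design_with_ids(
    cohort: CohortTable, target: str, groups: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Like :func:`build_design` but also returns the per-row patient ids."""
    groups = tuple(groups)
    if target == "pro_prrt_patient":
        frame = cohort.patients
        y = frame["eligible"].astype(int).to_numpy()
        feats = cohort.feature_names(level="patient", groups=groups)
    else:
        frame = cohort.lesion_analysis_frame()
        if target == "pro_prrt_lesion":
            y = frame["pro_prrt"].astype(int).to_numpy()
        elif target == "krenning_bin":
            k = frame["krenning"].to_numpy()
            y = np.where(k <= 1, 0, np.where(k == 2, 1, 2))
        else:
            raise CohortError(f"unknown target {target!r}")
        feats = cohort.feature_names(level="lesion", groups=groups)
    return frame[feats].astype(float), y, frame["patient_id"].to_numpy()


@dataclass
class BenchCell:
    """One fitted grid cell retained for the importance stage."""

    config: ModelConfig
    split: int
    model: object
    X_test: np.ndarray
    y_test: np.ndarray
    columns: list[str]
    feature_cols: dict[str, list[int]]
    f1: float


@dataclass
class BenchResult:
    """Per-cell F1 records plus (optionally) the fitted cells themselves."""

    records: pd.DataFrame
    cells: list[BenchCell] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean/SD F1 per configuration over its non-failed splits."""
        ok = self.records[~self.records["failed"]]
        agg = (
            ok.groupby(
                ["config_id", "learner", "smote", "target", "groups"], sort=False
            )["f1"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_f1", "std": "sd_f1", "count": "n_splits"})
        )
        failed = (
            self.records.groupby("config_id", sort=False)["failed"].sum().rename("n_failed")
        )
        return agg.merge(failed, on="config_id")

    def mean_f1(self) -> pd.Series:
        """Config-id indexed mean F1 (the model-weight input)."""
        ok = self.records[~self.records["failed"]]
        return ok.groupby("config_id", sort=False)["f1"].mean()


def default_grid(
    learners: Sequence[str] = ("bagged_trees", "boosted_trees"),
    smote_options: Sequence[bool] = (True, False),
    targets: Sequence[str] = TARGETS,
    subsets: Sequence[tuple[str, ...]] | None = None,
    **kwargs,
) -> list[ModelConfig]:
    """The full bench grid: learners x SMOTE x 15 group subsets x targets."""
    from .cohort import enumerate_group_subsets

    if subsets is None:
        subsets = enumerate_group_subsets()
    return [
        ModelConfig(learner=l, smote=s, target=t, groups=tuple(g), **kwargs)
        for t in targets
        for l in learners
        for s in smote_options
        for g in subsets
    ]


def run_bench(
    cohort: CohortTable,
    configs: Sequence[ModelConfig],
    keep_models: bool = False,
) -> BenchResult:
    """Execute the grid; failed cells are recorded and skipped, never fatal."""
    if not configs:
        raise CohortError("empty config grid")
    records = []
    cells: list[BenchCell] = []
    dtypes = {s.name: s.dtype for s in cohort.registry}
    design_cache: dict[tuple, tuple[pd.DataFrame, np.ndarray]] = {}
    for cfg in configs:
        key = (cfg.target, cfg.groups)
        if key not in design_cache:
            design_cache[key] = build_design_with_ids(cohort, cfg.target, cfg.groups)
        frame, y, pids = design_cache[key]
        averaging = TARGET_AVERAGING[cfg.target]
        for split in range(cfg.n_splits):
            rec = {
                "config_id": cfg.config_id,
                "learner": cfg.learner,
                "smote": cfg.smote,
                "target": cfg.target,
                "groups": "+".join(cfg.groups),
                "split": split,
                "f1": np.nan,
                "failed": False,
                "error": "",
            }
            try:
                seed = cfg.seed + split
                if cfg.patient_grouped and cfg.level == "lesion":
                    tr_idx, te_idx = split_indices_grouped(pids, cfg.train_frac, seed)
                else:
                    tr_idx, te_idx = split_indices(len(frame), cfg.train_frac, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    X_tr, X_te, columns, fcols = impute_and_encode(
                        frame.iloc[tr_idx], frame.iloc[te_idx], dtypes
                    )
                    y_tr, y_te = y[tr_idx], y[te_idx]
                    if cfg.smote:
                        X_tr, y_tr = smote_oversample(X_tr, y_tr, cfg.smote_k, seed)
                model = train_model(
                    cfg.learner, X_tr, y_tr, seed=seed, n_trees=cfg.n_trees,
                    max_depth=cfg.max_depth, learning_rate=cfg.learning_rate,
                )
                score = f1(y_te, model.predict(X_te), averaging)
                rec["f1"] = score
                if keep_models:
                    cells.append(
                        BenchCell(cfg, split, model, X_te, y_te, columns, fcols, score)
                    )
            except CohortError as exc:
                rec["failed"] = True
                rec["error"] = str(exc)
            records.append(rec)
    return BenchResult(records=pd.DataFrame(records), cells=cells)
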