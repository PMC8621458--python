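"""Feature selection and cross-validated multiple linear regression of FAS.

Per-feature Pearson correlations with the FAS totals are tested with the
exact two-tailed t test (``t = r * sqrt((m-2) / (1-r^2))`` on m-2 degrees of
freedom); features with p below the significance level are kept and ranked by
ascending p (ties: |r| descending, then name).  Reciprocal power-ratio pairs
on the same channel (e.g. alpha/theta vs theta/alpha at O2) are perfectly
anti-informative duplicates; the non-redundant variant drops the higher-p
member of each pair.

Models are ordinary least squares fitted by the normal equation with a
Moore-Penrose pseudo-inverse (rank-deficient systems, reachable under
leave-one-out with many features, fall back to the minimum-norm solution).
Evaluation runs a grid over model variant x subject-level split scheme x
feature count x AO duration, repeating each random split ten times; selection
statistics are computed on the training subjects only unless the global
"paper_faithful" selection mode is requested.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EXTREME, NO_FATIGUE, SUBSTANTIAL

logger = logging.getLogger(__name__)

#: the six wristband features used by the wristband-only model variant
E4_MODEL_FEATURES = ("st", "lf", "tp", "hf", "lfnu", "lf_hf")

VARIANTS = ("EEG", "NR-EEG", "E4")
SPLITS = ("70:30", "80:20", "LOO")

_RATIO_RE = re.compile(r"^ratio_([a-z]+)_([a-z]+)_(\w+)$")


@dataclass(frozen=True)
class FeatureMatrix:
    """Complete subjects x named features, plus their FAS totals."""

    X: pd.DataFrame  # index: subject ids, columns: feature names
    fas: pd.Series  # index: subject ids

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            dupes = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if not self.X.index.equals(self.fas.index):
            raise ValueError("feature matrix and FAS vector must share subjects")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if len(self.X) < 3:
            raise ValueError("need at least 3 complete subjects")

    @property
    def m(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


def assemble_feature_matrix(
    features_by_subject: dict[str, dict[str, float] | None],
    fas_by_subject: dict[str, float],
) -> FeatureMatrix:
    """Align per-subject feature rows into a matrix, excluding incomplete
    subjects (``None`` rows).  Column names must agree across subjects."""
    complete = {s: row for s, row in features_by_subject.items() if row is not None}
    excluded = sorted(set(features_by_subject) - set(complete))
    if excluded:
        logger.info("excluded %d incomplete subjects: %s", len(excluded), excluded)
    if len(complete) < 3:
        raise ValueError("need at least 3 complete subjects")
    names = None
    for s, row in complete.items():
        if names is None:
            names = list(row)
        elif list(row) != names:
            raise ValueError(f"feature names of subject {s} do not match the first subject")
    X = pd.DataFrame.from_dict(complete, orient="index")[names]
    fas = pd.Series({s: float(fas_by_subject[s]) for s in complete}, name="fas")
    return FeatureMatrix(X=X, fas=fas.loc[X.index])


def pearson_r_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r of each column of X with y, and the two-tailed
    p-value from the exact t distribution with m-2 degrees of freedom.
    Zero-variance columns get r = 0, p = 1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    # treat numerically constant columns (variation at rounding level) as
    # zero-variance: their "correlation" is arithmetic noise
    x_scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    degenerate = (sx <= 1e-10 * np.sqrt(m) * x_scale) | (sy == 0)
    sx_safe = np.where(degenerate, 1.0, sx)
    r = (xc * yc[:, None]).sum(axis=0) / (sx_safe * (sy if sy > 0 else 1.0))
    r = np.clip(np.where(degenerate, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((m - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df=m - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(degenerate, 1.0, p)
    return r, p


@dataclass(frozen=True)
class SelectionResult:
    """Ranked significant features: rows of (feature, r, p), p ascending."""

    table: pd.DataFrame  # columns: feature, r, p
    alpha: float

    @property
    def K(self) -> int:
        return len(self.table)

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()


def select_features(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    universe: list[str] | None = None,
    significance_filter: bool = True,
) -> SelectionResult:
    """Correlation-based selection against the FAS totals.

    Keeps features with p < alpha (unless ``significance_filter`` is off, in
    which case all candidates are ranked), sorted by ascending p; ties are
    broken by descending |r| and then by name so the ranking is deterministic.
    """
    cols = list(matrix.X.columns) if universe is None else [
        c for c in universe if c in matrix.X.columns]
    r, p = pearson_r_p(matrix.X[cols].to_numpy(), matrix.fas.to_numpy())
    degenerate = [c for c, pv, rv in zip(cols, p, r) if pv == 1.0 and rv == 0.0]
    if degenerate:
        logger.info("zero-variance/degenerate columns assigned p=1: %d", len(degenerate))
    table = pd.DataFrame({"feature": cols, "r": r, "p": p})
    if significance_filter:
        table = table[table["p"] < alpha]
    table = (
        table.assign(_abs_r=lambda d: d["r"].abs())
        .sort_values(["p", "_abs_r", "feature"], ascending=[True, False, True],
                     kind="mergesort")
        .drop(columns="_abs_r")
        .reset_index(drop=True)
    )
    return SelectionResult(table=table, alpha=alpha)


def drop_redundant(sel: SelectionResult) -> SelectionResult:
    """Remove the higher-p member of every reciprocal ratio pair (b1/b2 vs
    b2/b1 on the same channel).  Non-ratio features are untouched."""
    seen: dict[tuple[str, str, str], int] = {}
    keep_rows = []
    for _, row in sel.table.iterrows():
        match = _RATIO_RE.match(row["feature"])
        if match:
            b1, b2, ch = match.groups()
            key = (min(b1, b2), max(b1, b2), ch)
            if key in seen:
                continue  # rows are p-ascending: the first seen member wins
            seen[key] = 1
        keep_rows.append(row)
    table = pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else sel.table.iloc[:0]
    return SelectionResult(table=table, alpha=sel.alpha)


@dataclass(frozen=True)
class MLRModel:
    """Ordinary least squares fit: intercept plus one weight per feature."""

    feature_names: tuple[str, ...]
    weights: np.ndarray  # (k + 1,), weights[0] is the intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return self.weights[0] + X @ self.weights[1:]


def fit_mlr(X: np.ndarray, y: np.ndarray,
            feature_names: tuple[str, ...] | None = None) -> MLRModel:
    """Normal-equation least squares with a Moore-Penrose pseudo-inverse."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        raise ValueError("X and y must have matching rows")
    if len(y) < 2:
        raise ValueError("need at least two training rows")
    X1 = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        logger.warning("rank-deficient design (%d rows, %d columns); "
                       "using minimum-norm solution", X1.shape[0], X1.shape[1])
    weights = np.linalg.pinv(X1.T @ X1) @ (X1.T @ y)
    names = feature_names if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1]))
    return MLRModel(feature_names=tuple(names), weights=weights)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error ``sqrt(mean((y - yhat)**2))``."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size == 0:
        raise ValueError("need at least one example")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


#: continuous class bins: midpoint extension of the integer FAS bins
_CLASS_EDGES = (21.5, 35.5)


def fatigue_class_of_score(score: float) -> str:
    """Map a real-valued (predicted) FAS score to the three fatigue classes
    using midpoint bin edges 21.5 and 35.5."""
    if score < _CLASS_EDGES[0]:
        return NO_FATIGUE
    if score < _CLASS_EDGES[1]:
        return SUBSTANTIAL
    return EXTREME


def _test_size(split: str, m: int) -> int:
    if split == "LOO":
        return 1
    try:
        train_pct, test_pct = (int(x) for x in split.split(":"))
    except ValueError as err:
        raise ValueError(f"unknown split scheme {split!r}") from err
    return max(1, int(round(m * test_pct / 100)))


def _variant_universe(variant: str, names: tuple[str, ...]) -> list[str]:
    if variant in ("EEG", "NR-EEG"):
        return [n for n in names if n.startswith(("p300_", "np_", "ratio_"))]
    if variant == "E4":
        return [n for n in names if n in E4_MODEL_FEATURES]
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass(frozen=True)
class EvalGrid:
    """Tidy per-cell evaluation results.

    One row per (variant, split, duration, k): mean accuracy (percent of test
    subjects classified into the correct fatigue class), mean RMSE, and their
    standard errors across cross-validation repeats.
    """

    table: pd.DataFrame
    seed: int
    repeats: int

    def best_cell(self) -> dict:
        t = self.table.dropna(subset=["accuracy_mean"])
        row = t.sort_values(["accuracy_mean", "rmse_mean"],
                            ascending=[False, True], kind="mergesort").iloc[0]
        return {
            "variant": row["variant"], "split": row["split"],
            "duration_s": row["duration_s"], "k": int(row["k"]),
            "accuracy_pct": float(row["accuracy_mean"]),
            "rmse": float(row["rmse_mean"]),
        }


def _draw_partition(rng: np.random.Generator, m: int, n_test: int) -> np.ndarray:
    """Indices of the test subjects for one repeat (train = complement)."""
    return rng.permutation(m)[:n_test]


def evaluate_grid(
    matrices: FeatureMatrix | dict[float, FeatureMatrix],
    variant: str = "EEG",
    splits: tuple[str, ...] = SPLITS,
    k_max: int = 15,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    selection_mode: str = "per_fold",
) -> EvalGrid:
    """Cross-validated accuracy/RMSE over split scheme x feature count x AO
    duration for one model variant.

    ``matrices`` maps AO duration (seconds) to the feature matrix extracted
    at that duration; a single matrix is used for every duration.  Train and
    test sets are disjoint at the subject level in every repeat.  In the
    default ``per_fold`` selection mode the correlation ranking is computed
    on the training subjects only; ``paper_faithful`` ranks once on all
    subjects before splitting.
    """
    if selection_mode not in ("per_fold", "paper_faithful"):
        raise ValueError(f"unknown selection mode {selection_mode!r}")
    if isinstance(matrices, FeatureMatrix):
        matrices = {float("nan"): matrices}
    rows = []
    rng = np.random.default_rng(seed)
    for duration, matrix in matrices.items():
        m = matrix.m
        universe = _variant_universe(variant, matrix.feature_names)
        sig_filter = variant != "E4"  # wristband variant uses its fixed six
        Xall = matrix.X
        y = matrix.fas.to_numpy()
        y_class = np.array([fatigue_class_of_score(v) for v in y])

        global_ranked: list[str] | None = None
        if selection_mode == "paper_faithful":
            sel = select_features(matrix, alpha, universe, significance_filter=sig_filter)
            if variant == "NR-EEG":
                sel = drop_redundant(sel)
            global_ranked = sel.features

        for split in splits:
            n_test = _test_size(split, m)
            if split == "LOO":
                order = rng.permutation(m)
                heldout = [np.array([order[i % m]]) for i in range(repeats)]
                if repeats > m:
                    heldout[m:] = [np.array([rng.integers(m)]) for _ in range(repeats - m)]
            else:
                heldout = [_draw_partition(rng, m, n_test) for _ in range(repeats)]

            acc = np.full((repeats, k_max), np.nan)
            err = np.full((repeats, k_max), np.nan)
            for rep, test_idx in enumerate(heldout):
                train_mask = np.ones(m, bool)
                train_mask[test_idx] = False
                if global_ranked is not None:
                    ranked = global_ranked
                else:
                    train_matrix = FeatureMatrix(
                        X=Xall.iloc[train_mask], fas=matrix.fas.iloc[train_mask])
                    sel = select_features(train_matrix, alpha, universe,
                                          significance_filter=sig_filter)
                    if variant == "NR-EEG":
                        sel = drop_redundant(sel)
                    ranked = sel.features
                for k in range(1, k_max + 1):
                    if k > len(ranked):
                        break  # cell unavailable for this fold
                    cols = ranked[:k]
                    model = fit_mlr(Xall.iloc[train_mask][cols].to_numpy(),
                                    y[train_mask], tuple(cols))
                    pred = model.predict(Xall.iloc[test_idx][cols].to_numpy())
                    pred_class = np.array([fatigue_class_of_score(v) for v in pred])
                    acc[rep, k - 1] = 100.0 * np.mean(pred_class == y_class[test_idx])
                    err[rep, k - 1] = rmse(y[test_idx], pred)

            for k in range(1, k_max + 1):
                a = acc[:, k - 1]
                e = err[:, k - 1]
                n_ok = int(np.sum(~np.isnan(a)))
                if n_ok < repeats:
                    logger.info("%s/%s/k=%d/dur=%s: %d of %d repeats available",
                                variant, split, k, duration, n_ok, repeats)
                rows.append({
                    "variant": variant, "split": split, "duration_s": duration, "k": k,
                    "accuracy_mean": float(np.nanmean(a)) if n_ok else np.nan,
                    "accuracy_se": float(np.nanstd(a, ddof=1) / np.sqrt(n_ok))
                    if n_ok > 1 else np.nan,
                    "rmse_mean": float(np.nanmean(e)) if n_ok else np.nan,
                    "rmse_se": float(np.nanstd(e, ddof=1) / np.sqrt(n_ok))
                    if n_ok > 1 else np.nan,
                    "n_repeats_available": n_ok,
                })
    return EvalGrid(table=pd.DataFrame(rows), seed=seed, repeats=repeats)
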