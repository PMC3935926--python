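"""Fixed-panel verification and nearest-shrunken-centroid re-ranking.

verify_panel repeats stratified train/test splits, training a random forest
restricted to the panel features each time, and summarizes accuracy,
sensitivity (ALS = positive class) and specificity. nsc_rank ranks every
feature by its standardized centroid difference and picks a shrinkage level
by cross-validation. build_panel_report assembles the per-feature report:
group medians on the raw scale, selection frequency, NSC rank position, and
independently computed M-score / t-test p-values with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import IntegrityError
from .preprocess import IntensityMatrix
from .selection import FrequencyTable, _fit_rf, derive_seed, stratified_split
from .stats_core import bh_fdr, m_score_matrix, rank_features, welch_t_matrix


@dataclass
class VerificationSummary:
    accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificities.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(1, self.n_runs + 1),
                "accuracy": self.accuracies,
                "sensitivity": self.sensitivities,
                "specificity": self.specificities,
            }
        )


def verify_panel(
    matrix: IntensityMatrix,
    panel: list[str],
    n_runs: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    n_test_per_group: int = 6,
) -> VerificationSummary:
    """Repeated redrawn-split random-forest classification of a fixed panel."""
    if not panel:
        raise ValueError("panel is empty")
    missing = set(panel) - set(matrix.feature_ids)
    if missing:
        raise IntegrityError(f"panel features absent from matrix: {sorted(missing)[:5]}")

    values = matrix.values.loc[panel]
    acc = np.empty(n_runs)
    sens = np.empty(n_runs)
    spec = np.empty(n_runs)
    for r in range(n_runs):
        split_seed = derive_seed(seed, r, 0)
        rf_seed = derive_seed(seed, r, 1)
        train_ids, test_ids = stratified_split(
            matrix.sample_ids, matrix.groups, split_seed, n_test_per_group
        )
        rf = _fit_rf(
            values[train_ids].to_numpy().T,
            matrix.groups[train_ids].to_numpy(),
            n_trees,
            rf_seed,
            oob=False,
        )
        pred = rf.predict(values[test_ids].to_numpy().T)
        truth = matrix.groups[test_ids].to_numpy()
        pos = truth == "ALS"
        acc[r] = float((pred == truth).mean())
        sens[r] = float((pred[pos] == "ALS").mean())
        spec[r] = float((pred[~pos] == "NDC").mean())
    return VerificationSummary(accuracies=acc, sensitivities=sens, specificities=spec)


# ---------------------------------------------------------------------------
# nearest shrunken centroids
# ---------------------------------------------------------------------------

@dataclass
class NscModel:
    feature_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # (m,)
    class_centroids: np.ndarray  # (m, K)
    s: np.ndarray  # pooled within-class sd, (m,)
    s0: float
    m_k: np.ndarray  # (K,)
    d: np.ndarray  # standardized differences, (m, K)
    rank_position: pd.Series = field(default=None)  # feature_id -> 1..m
    delta: float = 0.0
    selection_level: int = 0
    cv_errors: np.ndarray | None = None
    deltas: np.ndarray | None = None


def _nsc_stats(X: np.ndarray, y: np.ndarray, classes: list[str]):
    """Centroids, pooled sd and standardized differences d_jk for a
    features x samples matrix."""
    n = X.shape[1]
    K = len(classes)
    xbar = X.mean(axis=1)
    centroids = np.empty((X.shape[0], K))
    ss = np.zeros(X.shape[0])
    n_k = np.empty(K)
    for k, cls in enumerate(classes):
        cols = y == cls
        n_k[k] = cols.sum()
        centroids[:, k] = X[:, cols].mean(axis=1)
        ss += ((X[:, cols] - centroids[:, [k]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    s0 = float(np.median(s))
    d = (centroids - xbar[:, None]) / (m_k[None, :] * (s + s0)[:, None])
    return xbar, centroids, s, s0, m_k, d, n_k


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _nsc_predict(
    Xtest: np.ndarray,
    xbar: np.ndarray,
    s: np.ndarray,
    s0: float,
    m_k: np.ndarray,
    d_shrunk: np.ndarray,
    priors: np.ndarray,
) -> np.ndarray:
    """Class index per test sample by shrunken-centroid discriminant score."""
    shrunk_centroids = xbar[:, None] + (m_k[None, :] * (s + s0)[:, None]) * d_shrunk
    denom = (s + s0) ** 2
    scores = np.empty((Xtest.shape[1], d_shrunk.shape[1]))
    for k in range(d_shrunk.shape[1]):
        diff = Xtest - shrunk_centroids[:, [k]]
        scores[:, k] = (diff ** 2 / denom[:, None]).sum(axis=0) - 2.0 * np.log(priors[k])
    return scores.argmin(axis=1)


def nsc_rank(
    matrix: IntensityMatrix,
    cv_folds: int = 10,
    seed: int = 0,
    n_deltas: int = 30,
) -> NscModel:
    """Rank all features by descending max-over-classes |d_jk| and choose a
    shrinkage threshold by cross-validated error minimization (smallest
    surviving feature set among the error minima)."""
    X = matrix.values.to_numpy()
    y = matrix.groups.to_numpy()
    classes = sorted(set(y))
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    if np.allclose(X.var(axis=1), 0):
        raise ValueError("matrix has zero variance everywhere")

    xbar, centroids, s, s0, m_k, d, n_k = _nsc_stats(X, y, classes)
    score = np.abs(d).max(axis=1)
    ids = matrix.feature_ids
    order = sorted(range(len(ids)), key=lambda i: (-score[i], ids[i]))
    positions = pd.Series(0, index=ids, dtype=int)
    for pos, i in enumerate(order, start=1):
        positions.iloc[i] = pos

    deltas = np.linspace(0.0, float(score.max()), n_deltas)
    priors = n_k / n_k.sum()
    errors = np.zeros(n_deltas)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**32 - 1))
    for train_idx, test_idx in skf.split(X.T, y):
        xb_t, _, s_t, s0_t, mk_t, d_t, nk_t = _nsc_stats(
            X[:, train_idx], y[train_idx], classes
        )
        pr_t = nk_t / nk_t.sum()
        truth = np.array([classes.index(c) for c in y[test_idx]])
        for di, delta in enumerate(deltas):
            pred = _nsc_predict(
                X[:, test_idx], xb_t, s_t, s0_t, mk_t,
                _soft_threshold(d_t, delta), pr_t,
            )
            errors[di] += int((pred != truth).sum())

    best_err = errors.min()
    # among minima, largest delta = fewest surviving features
    best_delta = float(deltas[np.flatnonzero(errors == best_err)[-1]])
    surviving = int((np.abs(_soft_threshold(d, best_delta)).max(axis=1) > 0).sum())

    return NscModel(
        feature_ids=list(ids),
        classes=classes,
        overall_centroid=xbar,
        class_centroids=centroids,
        s=s,
        s0=s0,
        m_k=m_k,
        d=d,
        rank_position=positions,
        delta=best_delta,
        selection_level=surviving,
        cv_errors=errors,
        deltas=deltas,
    )


# ---------------------------------------------------------------------------
# panel report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "database_id", "gene_name", "ndc_median", "als_median", "frequency_pct",
    "pam_position", "m_p", "m_fdr", "m_position", "t_p", "t_fdr",
]


def build_panel_report(
    matrix_raw: pd.DataFrame,
    matrix_log: IntensityMatrix,
    panel: list[str],
    freq: FrequencyTable,
    nsc: NscModel,
    names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-panel-feature report over the full cohort (no splitting).

    M-score and t-test p-values are computed over every feature and BH-
    adjusted over the full feature list; rank positions likewise cover all
    features. Group medians are on the raw (pre-log) scale. Rows are sorted
    by descending selection frequency.
    """
    ids = matrix_log.feature_ids
    missing = set(panel) - set(ids)
    if missing or set(matrix_raw.index) != set(ids) or set(nsc.feature_ids) != set(ids):
        raise IntegrityError("panel / raw / log / NSC feature sets are inconsistent")

    case_mask = matrix_log.case_mask()
    logvals = matrix_log.values.to_numpy()
    m_p = m_score_matrix(logvals, case_mask)
    t_p = welch_t_matrix(logvals, case_mask)
    m_fdr = bh_fdr(m_p)
    t_fdr = bh_fdr(t_p)
    m_pos = rank_features(m_p, ids)
    idx_of = {f: i for i, f in enumerate(ids)}

    als_cols = matrix_log.group_columns("ALS")
    ndc_cols = matrix_log.group_columns("NDC")

    rows = []
    for fid in panel:
        i = idx_of[fid]
        rows.append(
            {
                "database_id": fid,
                "gene_name": (names or {}).get(fid, fid),
                "ndc_median": float(matrix_raw.loc[fid, ndc_cols].median()),
                "als_median": float(matrix_raw.loc[fid, als_cols].median()),
                "frequency_pct": 100.0 * freq.counts.get(fid, 0) / freq.n_subruns,
                "pam_position": int(nsc.rank_position[fid]),
                "m_p": float(m_p[i]),
                "m_fdr": float(m_fdr[i]),
                "m_position": int(m_pos[i]),
                "t_p": float(t_p[i]),
                "t_fdr": float(t_fdr[i]),
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = report.sort_values(
        ["frequency_pct", "m_p", "database_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return report
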