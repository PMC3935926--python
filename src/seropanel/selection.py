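"""Resampling feature-selection protocol.

Each subrun: stratified train/test split -> univariate preselection of the
k best features by M score (train only) -> random-forest backward
elimination ("gene shaving", train only) -> train a fresh forest on the
surviving features and score the held-out test samples. Repeated over many
subruns; the final panel collects the most frequently selected features.

All randomness flows from a single master seed through counter-based
seed sequences, so results are reproducible regardless of execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .preprocess import IntensityMatrix
from .stats_core import m_score_matrix

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed from a master seed and an index path."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class EngineParams:
    """Tunable knobs of the subrun engine.

    Tree counts follow the backward-elimination RF literature defaults;
    tests and quick runs may scale them down without changing behavior
    qualitatively.
    """

    k_preselect: int = 300
    n_test_per_group: int = 6
    drop_frac: float = 0.2
    c_se: float = 1.0
    n_trees_init: int = 500
    n_trees_iter: int = 200


@dataclass
class ShaveTrace:
    """Per-iteration record of the backward elimination."""

    sizes: list[int] = field(default_factory=list)
    oob_errors: list[float] = field(default_factory=list)
    dropped: list[list[str]] = field(default_factory=list)  # dropped AFTER each fit
    initial_features: list[str] = field(default_factory=list)

    def features_at(self, size: int) -> list[str]:
        """Reconstruct the feature set evaluated at a recorded size."""
        feats = list(self.initial_features)
        for s, drop in zip(self.sizes, self.dropped):
            if s == size:
                return feats
            feats = [f for f in feats if f not in set(drop)]
        raise ValueError(f"size {size} was never evaluated")


@dataclass
class SubrunResult:
    subrun_index: int
    seed: int
    train_ids: list[str]
    test_ids: list[str]
    preselected: list[str]
    cutoff_p: float
    selected: list[str]
    test_accuracy: float
    trace: ShaveTrace | None = None


@dataclass
class FrequencyTable:
    """Per-feature selection counts over all subruns (features never
    selected are implicit zeros)."""

    counts: dict[str, int]
    n_subruns: int

    def fraction(self, feature_id: str) -> float:
        return self.counts.get(feature_id, 0) / self.n_subruns

    @property
    def n_selected_at_least_once(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["feature_id", "count"])


@dataclass
class SelectionResult:
    subruns: list[SubrunResult]
    frequency: FrequencyTable

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([s.test_accuracy for s in self.subruns])

    def summary(self) -> dict[str, float]:
        acc = self.accuracies
        return {
            "n_subruns": len(self.subruns),
            "mean_accuracy": float(acc.mean()),
            "min_accuracy": float(acc.min()),
            "max_accuracy": float(acc.max()),
            "n_selected_at_least_once": self.frequency.n_selected_at_least_once,
            "mean_cutoff_p": float(np.mean([s.cutoff_p for s in self.subruns])),
        }


def stratified_split(
    sample_ids: list[str],
    groups: pd.Series,
    seed: int,
    n_test_per_group: int = 6,
) -> tuple[list[str], list[str]]:
    """Draw a stratified test set of ``n_test_per_group`` per group uniformly
    at random; the remainder is the training set. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    test: list[str] = []
    levels = sorted(set(groups[sample_ids]))
    for level in levels:
        members = [s for s in sample_ids if groups[s] == level]
        if len(members) <= n_test_per_group:
            raise ValueError(
                f"group {level!r} has {len(members)} samples; need more than "
                f"{n_test_per_group} to split"
            )
        test.extend(rng.choice(members, size=n_test_per_group, replace=False))
    test_set = set(test)
    train = [s for s in sample_ids if s not in test_set]
    test = [s for s in sample_ids if s in test_set]
    return train, test


def preselect_m(train: IntensityMatrix, k: int = 300) -> tuple[list[str], float]:
    """Keep the k features with the smallest M scores (ties by id).

    Returns the selected ids and the k-th smallest p (the subrun's cutoff).
    """
    if k > len(train.feature_ids):
        raise ValueError(f"k={k} exceeds feature count {len(train.feature_ids)}")
    p = m_score_matrix(train.values.to_numpy(), train.case_mask())
    ids = train.feature_ids
    order = sorted(range(len(ids)), key=lambda i: (p[i], ids[i]))
    chosen = [ids[i] for i in order[:k]]
    cutoff = float(p[order[k - 1]])
    return chosen, cutoff


def _fit_rf(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int, oob: bool
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=oob, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    return rf


def gene_shave(
    train_values: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    params: EngineParams = EngineParams(),
) -> tuple[list[str], ShaveTrace]:
    """Random-forest backward elimination.

    Repeatedly fit a forest (recording its out-of-bag error), drop the
    ``ceil(drop_frac * m)`` least-important features, down to 2 features.
    The selection is the smallest evaluated set whose OOB error is within
    ``c_se`` standard errors of the minimum, SE = sqrt(e(1-e)/n_train) at
    the minimum error e.
    """
    y = labels.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("gene shaving needs both classes in the training labels")
    feats = list(train_values.index)
    if len(feats) < 2:
        raise ValueError("gene shaving needs at least 2 features")

    trace = ShaveTrace(initial_features=list(feats))
    n_train = train_values.shape[1]
    Xfull = train_values.to_numpy().T  # samples x features
    col_of = {f: i for i, f in enumerate(feats)}

    current = list(feats)
    iteration = 0
    while True:
        n_trees = params.n_trees_init if iteration == 0 else params.n_trees_iter
        rf = _fit_rf(
            Xfull[:, [col_of[f] for f in current]], y, n_trees,
            derive_seed(seed, iteration), oob=True,
        )
        oob_err = 1.0 - float(rf.oob_score_)
        trace.sizes.append(len(current))
        trace.oob_errors.append(oob_err)
        if len(current) == 2:
            trace.dropped.append([])
            break
        n_drop = math.ceil(params.drop_frac * len(current))
        n_drop = min(n_drop, len(current) - 2)
        # least-important first; stable order makes ties deterministic
        imp_order = np.argsort(rf.feature_importances_, kind="stable")
        drop = [current[i] for i in imp_order[:n_drop]]
        trace.dropped.append(drop)
        dropset = set(drop)
        current = [f for f in current if f not in dropset]
        iteration += 1

    errs = np.array(trace.oob_errors)
    e_min = float(errs.min())
    se = math.sqrt(e_min * (1.0 - e_min) / n_train)
    ok_sizes = [s for s, e in zip(trace.sizes, errs) if e <= e_min + params.c_se * se]
    chosen_size = min(ok_sizes)
    return trace.features_at(chosen_size), trace


def run_subrun(
    matrix: IntensityMatrix,
    subrun_index: int,
    seed: int,
    params: EngineParams = EngineParams(),
    keep_trace: bool = False,
) -> SubrunResult:
    """Execute one subrun: split, preselect, shave, verify on the test set."""
    split_seed = derive_seed(seed, 0)
    shave_seed = derive_seed(seed, 1)
    rf_seed = derive_seed(seed, 2)

    train_ids, test_ids = stratified_split(
        matrix.sample_ids, matrix.groups, split_seed, params.n_test_per_group
    )
    train = matrix.subset_samples(train_ids)
    preselected, cutoff_p = preselect_m(train, params.k_preselect)
    selected, trace = gene_shave(
        train.values.loc[preselected], train.groups, shave_seed, params
    )

    rf = _fit_rf(
        train.values.loc[selected].to_numpy().T,
        train.groups.to_numpy(),
        params.n_trees_init,
        rf_seed,
        oob=False,
    )
    test = matrix.subset_samples(test_ids)
    pred = rf.predict(test.values.loc[selected].to_numpy().T)
    accuracy = float((pred == test.groups.to_numpy()).mean())

    return SubrunResult(
        subrun_index=subrun_index,
        seed=seed,
        train_ids=train_ids,
        test_ids=test_ids,
        preselected=preselected,
        cutoff_p=cutoff_p,
        selected=selected,
        test_accuracy=accuracy,
        trace=trace if keep_trace else None,
    )


def run_selection(
    matrix: IntensityMatrix,
    n_subruns: int = 100,
    master_seed: int = 0,
    params: EngineParams = EngineParams(),
) -> SelectionResult:
    """Run the full resampling protocol and tally selection frequencies."""
    subruns: list[SubrunResult] = []
    counts: dict[str, int] = {}
    for i in range(1, n_subruns + 1):
        result = run_subrun(matrix, i, derive_seed(master_seed, i), params)
        subruns.append(result)
        for fid in result.selected:
            counts[fid] = counts.get(fid, 0) + 1
        logger.debug(
            "subrun %d: |selected|=%d accuracy=%.3f",
            i, len(result.selected), result.test_accuracy,
        )
    freq = FrequencyTable(counts=counts, n_subruns=n_subruns)
    return SelectionResult(subruns=subruns, frequency=freq)


def final_panel(
    freq: FrequencyTable,
    threshold: float = 0.10,
    panel_size: int = 20,
    m_p: pd.Series | None = None,
) -> list[str]:
    """Features selected in at least ``threshold`` of subruns, ordered by
    descending frequency (ties by ascending whole-cohort M score, then id),
    truncated to ``panel_size``."""
    def tie_key(fid: str) -> tuple:
        m = float(m_p[fid]) if m_p is not None and fid in m_p.index else float("inf")
        return (-freq.counts[fid], m, fid)

    qualifying = [
        f for f, c in freq.counts.items() if c / freq.n_subruns >= threshold
    ]
    qualifying.sort(key=tie_key)
    if not qualifying:
        logger.warning("no feature reached the %.0f%% selection threshold", threshold * 100)
    return qualifying[:panel_size]
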