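"""Spot-level raw intensities -> preprocessed feature x sample matrix.

Pipeline: background subtraction (floored at 1) -> replicate averaging ->
log2 -> joint quantile normalization over all arrays. Also provides the
technical-replicate QC metrics (pairwise Pearson r on log data, average
per-spot CV on raw data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError
from .gpr_io import ArrayLayout, SpotCohort

logger = logging.getLogger(__name__)


@dataclass
class IntensityMatrix:
    """Feature x sample intensity grid with group labels.

    The central object of the pipeline; ``log_scale`` records whether values
    are log2-transformed.
    """

    values: pd.DataFrame  # features x samples
    groups: pd.Series  # index: sample_id, values in {"ALS", "NDC"}
    log_scale: bool = True

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise IntegrityError("every sample column needs a group label")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def case_mask(self) -> np.ndarray:
        return (self.groups == "ALS").to_numpy()

    def subset_samples(self, sample_ids: list[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values[sample_ids], groups=self.groups[sample_ids],
            log_scale=self.log_scale,
        )

    def subset_features(self, feature_ids: list[str]) -> "IntensityMatrix":
        missing = set(feature_ids) - set(self.values.index)
        if missing:
            raise IntegrityError(f"features absent from matrix: {sorted(missing)[:5]}")
        return IntensityMatrix(
            values=self.values.loc[feature_ids], groups=self.groups,
            log_scale=self.log_scale,
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class QCReport:
    """Replicate-reproducibility metrics for one stratum of pairs."""

    stratum: str  # intra_lot | inter_lot | overall
    pairwise_r: list[float] = field(default_factory=list)
    avg_cv: float = float("nan")  # percent

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.pairwise_r))


def background_correct(cohort: SpotCohort) -> pd.DataFrame:
    """Background-subtract spot intensities with floor 1.

    Spots carrying a negative flag are replaced by the mean of the feature's
    unflagged replicates in the same sample, or by 1 if every replicate of
    the feature is flagged (logged as a warning).
    """
    corrected = np.maximum(cohort.fg.to_numpy() - cohort.bg.to_numpy(), 1.0)
    flagged = cohort.flag.to_numpy() < 0
    if flagged.any():
        df = pd.DataFrame(
            np.where(flagged, np.nan, corrected),
            index=cohort.fg.index, columns=cohort.fg.columns,
        )
        fallback = df.groupby(level="feature_id", sort=False).transform("mean")
        n_dead = int((fallback.isna() & pd.DataFrame(flagged, index=df.index,
                                                     columns=df.columns)).any(axis=None))
        if n_dead:
            logger.warning("all replicates flagged for some feature/sample; imputing 1")
        out = df.fillna(fallback).fillna(1.0)
        return out
    return pd.DataFrame(corrected, index=cohort.fg.index, columns=cohort.fg.columns)


def aggregate_duplicates(
    spot_values: pd.DataFrame, layout: ArrayLayout | None = None
) -> pd.DataFrame:
    """Average replicate spots into one row per feature (arithmetic mean)."""
    agg = spot_values.groupby(level="feature_id", sort=False).mean()
    if layout is not None:
        missing = set(layout.feature_ids) - set(agg.index)
        if missing:
            raise IntegrityError(
                f"features with no usable spots: {sorted(missing)[:5]}"
            )
        agg = agg.loc[layout.feature_ids]
    return agg


def quantile_normalize(log_values: pd.DataFrame) -> pd.DataFrame:
    """Joint quantile normalization: every column's sorted vector is mapped
    onto the mean of sorted columns; ties share the mean of the reference
    values they span."""
    arr = log_values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        rmin = stats.rankdata(arr[:, j], method="min").astype(int)
        rmax = stats.rankdata(arr[:, j], method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=log_values.index, columns=log_values.columns)


def log_quantile_normalize(feature_values: pd.DataFrame, groups: pd.Series) -> IntensityMatrix:
    """log2-transform positive feature-level intensities and quantile-
    normalize all samples jointly."""
    arr = feature_values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("log_quantile_normalize requires strictly positive values")
    logged = pd.DataFrame(
        np.log2(arr), index=feature_values.index, columns=feature_values.columns
    )
    return IntensityMatrix(values=quantile_normalize(logged), groups=groups, log_scale=True)


def replicate_qc(
    pairs: list[tuple[np.ndarray, np.ndarray]], stratum: str = "overall"
) -> QCReport:
    """Pearson r on log2 data per replicate pair, and the average per-spot
    coefficient of variation (sample sd / mean, percent) on raw data."""
    if not pairs:
        raise ValueError("no replicate pairs given")
    rs: list[float] = []
    cvs: list[np.ndarray] = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("replicate arrays differ in length")
        lx, ly = np.log2(x), np.log2(y)
        if np.ptp(lx) == 0 or np.ptp(ly) == 0:
            raise ValueError("constant replicate array: Pearson r undefined")
        rs.append(float(stats.pearsonr(lx, ly)[0]))
        stacked = np.stack([x, y])
        cvs.append(stacked.std(axis=0, ddof=1) / stacked.mean(axis=0))
    avg_cv = float(np.concatenate(cvs).mean() * 100.0)
    return QCReport(stratum=stratum, pairwise_r=rs, avg_cv=avg_cv)


def preprocess_cohort(cohort: SpotCohort) -> tuple[pd.DataFrame, IntensityMatrix]:
    """Full preprocessing path; returns (raw feature-level matrix,
    preprocessed log2 IntensityMatrix)."""
    corrected = background_correct(cohort)
    raw_features = aggregate_duplicates(corrected, cohort.layout)
    matrix = log_quantile_normalize(raw_features, cohort.groups)
    return raw_features, matrix
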