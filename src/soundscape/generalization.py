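"""Within- and cross-dataset regression of richness on acoustic features.

Each dataset is split once into a 70/30 train/test partition.  A regressor
(random forest by default, behind a fit/predict contract) is trained on each
dataset's training split and scored with the coefficient of determination
R^2 = 1 - SS_res/SS_tot on every dataset's *test* split, filling a
train-by-test generalization matrix whose diagonal is within-dataset skill.
R^2 is negative whenever the model predicts worse than the test-set mean.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .types import AnalysisConfig, FeatureTable

__all__ = [
    "SplitSpec",
    "GeneralizationMatrix",
    "SampleSizeCorrelation",
    "split",
    "r_squared",
    "default_regressor",
    "generalization_matrix",
    "sample_size_correlation",
    "GeneralizationStudy",
    "GeneralizationResults",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """One dataset's train/test partition."""

    dataset_id: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test overlap")


def split(
    point_count_ids: Sequence[str],
    fraction: float = 0.7,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> SplitSpec:
    """Uniform random train/test partition, deterministic given the seed.

    The train size is ``fraction * n`` rounded half-up.
    """
    ids = list(point_count_ids)
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 point counts to split, got {n}")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitSpec(dataset_id, train, test, fraction, seed)


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination; unbounded below, 1 for perfect fits."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    ss_res = float(((yt - yp) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def default_regressor(seed: int = 0):
    """Random-forest regression with a fixed seed, library defaults otherwise."""
    return RandomForestRegressor(random_state=seed)


@dataclass(frozen=True)
class GeneralizationMatrix:
    """Train-dataset x test-dataset R^2 grid (diagonal = within-dataset)."""

    dataset_ids: tuple[str, ...]
    values: np.ndarray
    splits: Mapping[str, SplitSpec]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.dataset_ids), columns=list(self.dataset_ids)
        )

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def cross_means(self) -> np.ndarray:
        """Row means excluding the diagonal (mean cross-dataset skill)."""
        n = len(self.dataset_ids)
        mask = ~np.eye(n, dtype=bool)
        return np.array(
            [self.values[i, mask[i]].mean() for i in range(n)]
        )


@dataclass(frozen=True)
class SampleSizeCorrelation:
    """Pearson link between dataset sizes and within/cross-dataset skill.

    ``r_within``/``r_cross`` are NaN (flagged) when the scores are constant.
    """

    r_within: float
    p_within: float
    r_cross: float
    p_cross: float


def _dataset_xy(features: FeatureTable, richness, feature_set: str):
    table = features.select_family(feature_set)
    return table, np.asarray(richness, dtype=float)


def generalization_matrix(
    datasets: Mapping[str, tuple[FeatureTable, Sequence[int]]],
    config: AnalysisConfig | None = None,
    regressor_factory: Callable[[int], object] = default_regressor,
) -> GeneralizationMatrix:
    """Fit one regressor per training dataset; score on every test split.

    All datasets must share the same feature-name set (after restriction to
    ``config.feature_set``).  Train/test disjointness is asserted before
    every fit; cross-dataset cells are evaluated on the *target* dataset's
    held-out test split, never its full data.
    """
    config = config or AnalysisConfig()
    if len(datasets) < 1:
        raise ValueError("no datasets supplied")
    ids = list(datasets)
    prepared: dict[str, tuple[FeatureTable, np.ndarray]] = {
        d: _dataset_xy(*datasets[d], config.feature_set) for d in ids
    }
    names0 = prepared[ids[0]][0].feature_names
    for d in ids[1:]:
        if prepared[d][0].feature_names != names0:
            raise ValueError(f"feature names of dataset {d!r} do not match")

    splits = {
        d: split(
            prepared[d][0].point_count_ids,
            config.train_fraction,
            seed=config.seed + k,
            dataset_id=d,
        )
        for k, d in enumerate(ids)
    }
    values = np.empty((len(ids), len(ids)))
    for i, train_d in enumerate(ids):
        table, y = prepared[train_d]
        sp = splits[train_d]
        assert not set(sp.train_ids) & set(sp.test_ids)
        train_tbl = table.restrict(sp.train_ids)
        pos = {p: k for k, p in enumerate(table.point_count_ids)}
        y_train = y[[pos[p] for p in sp.train_ids]]
        model = regressor_factory(config.seed)
        model.fit(train_tbl.values, y_train)
        for j, test_d in enumerate(ids):
            t_table, t_y = prepared[test_d]
            t_sp = splits[test_d]
            test_tbl = t_table.restrict(t_sp.test_ids)
            t_pos = {p: k for k, p in enumerate(t_table.point_count_ids)}
            y_test = t_y[[t_pos[p] for p in t_sp.test_ids]]
            values[i, j] = r_squared(y_test, model.predict(test_tbl.values))
        log.info("generalization: trained on %s, diagonal R^2 = %.3f",
                 train_d, values[i, i])
    return GeneralizationMatrix(tuple(ids), values, splits)


def sample_size_correlation(
    matrix: GeneralizationMatrix, ns: Mapping[str, int]
) -> SampleSizeCorrelation:
    """Pearson r/p of dataset size against within- and mean cross-dataset R^2."""
    ids = matrix.dataset_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 datasets")
    n = np.array([ns[d] for d in ids], dtype=float)

    def _corr(scores: np.ndarray) -> tuple[float, float]:
        if np.ptp(scores) == 0 or np.ptp(n) == 0:
            log.warning("sample_size_correlation: constant input, r undefined")
            return float("nan"), float("nan")
        r, p = stats.pearsonr(n, scores)
        return float(r), float(p)

    r_w, p_w = _corr(matrix.diagonal)
    r_c, p_c = _corr(matrix.cross_means())
    return SampleSizeCorrelation(r_w, p_w, r_c, p_c)


class GeneralizationStudy:
    """Model object over a collection of (feature table, richness) datasets."""

    def __init__(
        self,
        datasets: Mapping[str, tuple[FeatureTable, Sequence[int]]],
        config: AnalysisConfig | None = None,
        regressor_factory: Callable[[int], object] = default_regressor,
    ) -> None:
        self.datasets = dict(datasets)
        self.config = config or AnalysisConfig()
        self.regressor_factory = regressor_factory

    def fit(self) -> "GeneralizationResults":
        matrix = generalization_matrix(
            self.datasets, self.config, self.regressor_factory
        )
        return GeneralizationResults(self, matrix)


@dataclass
class GeneralizationResults:
    model: GeneralizationStudy
    matrix: GeneralizationMatrix

    def sample_sizes(self) -> dict[str, int]:
        return {
            d: self.model.datasets[d][0].n_point_counts
            for d in self.matrix.dataset_ids
        }

    def sample_size_correlation(self) -> SampleSizeCorrelation:
        return sample_size_correlation(self.matrix, self.sample_sizes())

    def summary(self) -> str:
        df = self.matrix.to_frame()
        lines = [
            "Cross-dataset richness regression "
            f"(feature set {self.model.config.feature_set}, "
            f"train fraction {self.model.config.train_fraction})",
            "R^2, rows = training dataset, columns = test dataset:",
            df.round(3).to_string(),
            f"within-dataset mean R^2  {self.matrix.diagonal.mean():.3f}",
            f"cross-dataset mean R^2   {self.matrix.cross_means().mean():.3f}",
        ]
        if len(self.matrix.dataset_ids) >= 3:
            ssc = self.sample_size_correlation()
            lines.append(
                f"sample-size correlation  within r={ssc.r_within:.3f} "
                f"(p={ssc.p_within:.3f}), cross r={ssc.r_cross:.3f} "
                f"(p={ssc.p_cross:.3f})"
            )
        return "\n".join(lines)
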