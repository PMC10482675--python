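"""Univariate feature-richness screening against a pooled permutation null.

Per dataset, every acoustic feature is Pearson-correlated with point-count
species richness.  Significance is judged against an empirical null built by
repeatedly shuffling each feature column against the fixed richness vector
and pooling the absolute null coefficients across shuffles and features
(e.g. 100 shuffles x 188 features = 18,800 null values).  The Bonferroni
correction is applied as a rank cut in the sorted pooled null: with N null
values, significance level ``alpha`` and divisor ``m``, the threshold is the
value at 1-based position ``N - ceil(N * alpha / m)`` of the ascending sort,
and a feature is significant iff ``|r|`` strictly exceeds it.

The divisor defaults to the number of features scanned (standard
Bonferroni); ``paper_mode`` configs use divisor 60, which for N = 18,800
puts the cut at position 18,784.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AnalysisConfig, FeatureTable

__all__ = [
    "CorrelationScan",
    "NullDistribution",
    "ThresholdResult",
    "SignificanceCounts",
    "LineFit",
    "correlation_scan",
    "build_null_distribution",
    "significance_threshold",
    "count_across_datasets",
    "fit_line",
    "UnivariateScan",
    "UnivariateScanResults",
]

log = logging.getLogger(__name__)


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of ``x`` against ``y``; constant columns NaN."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    valid = (sx > 0) & (sy > 0)
    r = np.full(x.shape[1], np.nan)
    if sy > 0:
        np.divide(xc.T @ yc, sx * sy, out=r, where=valid)
    return np.clip(r, -1.0, 1.0, out=r), valid


@dataclass(frozen=True)
class CorrelationScan:
    """Per-feature Pearson r against richness for one dataset."""

    dataset_id: str
    feature_names: tuple[str, ...]
    family: tuple[str, ...]
    r: np.ndarray  # NaN where undefined (constant feature or richness)
    valid: np.ndarray  # bool mask, False = flagged undefined
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": list(self.feature_names),
                "family": list(self.family),
                "r": self.r,
                "valid": self.valid,
            }
        )


@dataclass(frozen=True)
class NullDistribution:
    """Pooled absolute null correlation coefficients for one dataset."""

    dataset_id: str
    values: np.ndarray  # |r| under column shuffling, pooled
    n_shuffles: int
    n_features: int
    seed: int

    @property
    def size(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ThresholdResult:
    """Rank-based significance cut in the sorted pooled null."""

    alpha: float
    bonferroni_divisor: int
    n_null: int
    cut_count: int
    position: int  # 1-based index into the ascending sort
    threshold_value: float

    def is_significant(self, r: np.ndarray | float) -> np.ndarray:
        """Strict exceedance: |r| > threshold (NaN never significant)."""
        with np.errstate(invalid="ignore"):
            return np.abs(np.asarray(r, dtype=float)) > self.threshold_value


@dataclass(frozen=True)
class SignificanceCounts:
    """Per-feature number of datasets (0..k) in which it was significant."""

    feature_names: tuple[str, ...]
    family: tuple[str, ...]
    counts: np.ndarray
    n_datasets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": list(self.feature_names),
                "family": list(self.family),
                "n_datasets_significant": self.counts,
            }
        )

    def histogram(self) -> pd.DataFrame:
        """Count of features per (family, number-of-datasets) cell."""
        df = self.to_frame()
        return (
            df.groupby(["family", "n_datasets_significant"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=range(self.n_datasets + 1), fill_value=0)
        )

    def n_significant_in(self, k_min: int, k_max: int | None = None,
                         family: str | None = None) -> int:
        """Features significant in between k_min and k_max datasets."""
        k_max = k_min if k_max is None else k_max
        mask = (self.counts >= k_min) & (self.counts <= k_max)
        if family is not None:
            mask &= np.asarray(self.family) == family
        return int(mask.sum())


@dataclass(frozen=True)
class LineFit:
    """First-order polynomial of one feature against richness."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, richness: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(richness, dtype=float) + self.intercept


def correlation_scan(
    features: FeatureTable, richness: Sequence[int], dataset_id: str | None = None
) -> CorrelationScan:
    """Pearson r of every feature column against the richness vector.

    Constant columns (or constant richness) are flagged as undefined rather
    than silently zeroed.
    """
    y = np.asarray(richness, dtype=float)
    if y.shape[0] != features.n_point_counts:
        raise ValueError("features and richness disagree on point-count count")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 point counts for a correlation scan")
    r, valid = _pearson_columns(features.values, y)
    n_flagged = int((~valid).sum())
    if n_flagged:
        log.info("correlation_scan: %d feature(s) flagged undefined", n_flagged)
    return CorrelationScan(
        dataset_id=dataset_id or "dataset",
        feature_names=features.feature_names,
        family=features.family,
        r=r,
        valid=valid,
        n=int(y.shape[0]),
    )


def build_null_distribution(
    features: FeatureTable,
    richness: Sequence[int],
    n_shuffles: int = 100,
    seed: int = 0,
    dataset_id: str | None = None,
) -> NullDistribution:
    """Pooled permutation null of absolute correlation coefficients.

    For each shuffle every feature column is permuted independently against
    the fixed richness vector; the |r| values are pooled across shuffles and
    features.  Flagged-constant columns are excluded from the pool (their
    null r is undefined), with a logged count.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    y = np.asarray(richness, dtype=float)
    if y.shape[0] != features.n_point_counts:
        raise ValueError("features and richness disagree on point-count count")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 point counts")
    _, valid = _pearson_columns(features.values, y)
    if not valid.any():
        raise ValueError("no non-constant feature column to shuffle")
    if not valid.all():
        log.info(
            "build_null_distribution: excluding %d constant feature(s) from pool",
            int((~valid).sum()),
        )
    x = features.values[:, valid]
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_shuffles, x.shape[1]))
    for s in range(n_shuffles):
        shuffled = rng.permuted(x, axis=0)  # each column independently
        r, _ = _pearson_columns(shuffled, y)
        pooled[s] = np.abs(r)
    return NullDistribution(
        dataset_id=dataset_id or "dataset",
        values=pooled.ravel(),
        n_shuffles=n_shuffles,
        n_features=int(valid.sum()),
        seed=seed,
    )


def significance_threshold(
    null: NullDistribution | np.ndarray,
    alpha: float = 0.05,
    bonferroni_divisor: int = 1,
) -> ThresholdResult:
    """Bonferroni rank cut in the ascending sorted pooled null.

    ``cut_count = ceil(N * alpha / divisor)`` top-ranked null values are cut;
    the threshold is the value at 1-based position ``N - cut_count``.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    n = values.size
    if n == 0:
        raise ValueError("empty null distribution")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if bonferroni_divisor < 1:
        raise ValueError("bonferroni_divisor must be a positive integer")
    cut_count = math.ceil(n * alpha / bonferroni_divisor)
    if cut_count >= n:
        raise ValueError(
            f"alpha/divisor too permissive: cut {cut_count} >= pool size {n}"
        )
    position = n - cut_count
    ordered = np.sort(values)
    return ThresholdResult(
        alpha=alpha,
        bonferroni_divisor=bonferroni_divisor,
        n_null=n,
        cut_count=cut_count,
        position=position,
        threshold_value=float(ordered[position - 1]),
    )


def count_across_datasets(
    scans: Mapping[str, CorrelationScan],
    thresholds: Mapping[str, ThresholdResult],
) -> SignificanceCounts:
    """Per feature, in how many datasets |r| clears that dataset's threshold."""
    if not scans:
        raise ValueError("no scans supplied")
    if set(scans) != set(thresholds):
        raise ValueError("scans and thresholds must cover the same datasets")
    ids = sorted(scans)
    first = scans[ids[0]]
    for d in ids[1:]:
        if scans[d].feature_names != first.feature_names:
            raise ValueError(f"feature names of dataset {d!r} do not match")
    counts = np.zeros(len(first.feature_names), dtype=int)
    for d in ids:
        sig = thresholds[d].is_significant(scans[d].r) & scans[d].valid
        counts += sig.astype(int)
    return SignificanceCounts(
        feature_names=first.feature_names,
        family=first.family,
        counts=counts,
        n_datasets=len(ids),
    )


def fit_line(richness: Sequence[int], feature_values: Sequence[float]) -> LineFit:
    """Least-squares line with richness as predictor; r^2 = squared Pearson r."""
    x = np.asarray(richness, dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("richness is constant; line fit undefined")
    slope, intercept = np.polyfit(x, y, deg=1)
    if np.ptp(y) == 0:
        r2 = 0.0
    else:
        r = np.corrcoef(x, y)[0, 1]
        r2 = float(r * r)
    return LineFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


class UnivariateScan:
    """Model object: one dataset's feature table + richness vector.

    ``fit()`` runs the scan, builds the pooled permutation null and derives
    the rank threshold from the analysis config.
    """

    def __init__(
        self,
        features: FeatureTable,
        richness: Sequence[int],
        config: AnalysisConfig | None = None,
        dataset_id: str | None = None,
    ) -> None:
        self.features = features
        self.richness = np.asarray(richness, dtype=float)
        self.config = config or AnalysisConfig()
        self.dataset_id = dataset_id or "dataset"

    def fit(self) -> "UnivariateScanResults":
        cfg = self.config
        scan = correlation_scan(self.features, self.richness, self.dataset_id)
        null = build_null_distribution(
            self.features, self.richness, cfg.n_shuffles, cfg.seed, self.dataset_id
        )
        divisor = cfg.bonferroni_divisor or int(scan.valid.sum())
        threshold = significance_threshold(null, cfg.alpha, divisor)
        return UnivariateScanResults(self, scan, null, threshold)


@dataclass
class UnivariateScanResults:
    model: UnivariateScan
    scan: CorrelationScan
    null: NullDistribution
    threshold: ThresholdResult
    _significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self._significant = (
            self.threshold.is_significant(self.scan.r) & self.scan.valid
        )

    @property
    def significant(self) -> np.ndarray:
        return self._significant

    @property
    def n_significant(self) -> int:
        return int(self._significant.sum())

    def line_fit(self, feature_name: str) -> LineFit:
        j = self.scan.feature_names.index(feature_name)
        return fit_line(self.model.richness, self.model.features.values[:, j])

    def to_frame(self) -> pd.DataFrame:
        df = self.scan.to_frame()
        df["significant"] = self._significant
        return df

    def summary(self) -> str:
        by_family = self.to_frame().groupby("family")["significant"].sum()
        lines = [
            f"Univariate richness scan: dataset {self.scan.dataset_id!r}",
            f"  point counts            {self.scan.n}",
            f"  features scanned        {len(self.scan.feature_names)}"
            f" ({int((~self.scan.valid).sum())} flagged undefined)",
            f"  null pool               {self.null.size} "
            f"({self.null.n_shuffles} shuffles x {self.null.n_features} features)",
            f"  threshold |r|           {self.threshold.threshold_value:.4f} "
            f"(alpha={self.threshold.alpha}, divisor={self.threshold.bonferroni_divisor}, "
            f"position {self.threshold.position}/{self.threshold.n_null})",
            f"  significant features    {self.n_significant}",
        ]
        for fam, k in by_family.items():
            lines.append(f"    {fam:<4} {int(k)}")
        return "\n".join(lines)
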