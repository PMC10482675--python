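"""Soundscape change vs community change: distance matrices and Mantel tests.

Community change between two point counts is the Jaccard distance between
their species sets (0 = identical, 1 = no shared species); soundscape change
is the Euclidean distance between their mean acoustic feature vectors.  The
association between the two pairwise matrices is measured by a one-tailed
(positive) Spearman Mantel test: the observed rank correlation of the
upper-triangle entries is compared against the distribution obtained by
jointly permuting the rows and columns of one matrix, with
``p = (1 + #{rho_perm >= rho_obs}) / (1 + n_permutations)``.

Because a symmetric matrix's multiset of off-diagonal values is invariant
under joint row/column permutation, ranks are computed once and re-indexed
per permutation, making the permutation loop O(pairs) per draw.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .types import AnalysisConfig, FeatureTable, OccurrenceMatrix

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "jaccard_matrix",
    "euclidean_matrix",
    "richness_change_matrix",
    "mantel",
    "per_site_mantel",
    "turnover_asymmetry",
    "TurnoverAnalysis",
    "TurnoverResults",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric hollow non-negative pairwise distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        v = np.maximum((v + v.T) / 2.0, 0.0)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in row-major order."""
        return self.values[np.triu_indices(self.n, k=1)]

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        labels = list(labels)
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


@dataclass(frozen=True)
class MantelResult:
    """One-tailed Spearman Mantel outcome."""

    rho: float
    p: float
    n_permutations: int
    seed: int
    n: int
    alternative: str = "greater"

    def summary(self) -> str:
        return (
            f"Mantel (Spearman, one-tailed greater): rho = {self.rho:.4f}, "
            f"p = {self.p:.4g} ({self.n_permutations} permutations, "
            f"n = {self.n} labels)"
        )


def jaccard_matrix(occurrence: OccurrenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between point-count species sets.

    ``d = 1 - |intersection| / |union|``; two empty communities are defined
    as identical (distance 0), empty vs non-empty as complete turnover (1).
    """
    if occurrence.n_point_counts < 2:
        raise ValueError("need at least 2 point counts")
    x = occurrence.values.astype(float)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(occurrence.point_count_ids, d)


def euclidean_matrix(
    features: FeatureTable, feature_set: str = "ALL", zscore: bool = False
) -> DistanceMatrix:
    """Pairwise L2 distances between mean feature vectors.

    Distances are taken in the raw feature space of the selected family
    (all features, the learned-feature block, or the index block);
    ``zscore`` optionally standardizes columns first.
    """
    table = features.select_family(feature_set)
    if table.n_point_counts < 2:
        raise ValueError("need at least 2 point counts")
    x = table.values
    if zscore:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(table.point_count_ids, d)


def richness_change_matrix(
    richness: Sequence[int], labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Absolute richness differences |richness_i - richness_j| (control)."""
    y = np.asarray(richness, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 point counts")
    if labels is None:
        labels = tuple(f"pc{i}" for i in range(y.size))
    d = np.abs(y[:, None] - y[None, :])
    return DistanceMatrix(tuple(labels), d)


def _check_pair(dx: DistanceMatrix, dy: DistanceMatrix) -> None:
    if dx.labels != dy.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if dx.n < 4:
        raise ValueError("need at least 4 labels for a Mantel test")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-tailed Spearman Mantel test of positive association.

    ``dy``'s labels are jointly re-shuffled over rows and columns for each
    permutation draw; the empirical p includes the observed statistic in
    numerator and denominator, so ``p >= 1/(n_permutations + 1)``.
    """
    _check_pair(dx, dy)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = dx.n
    iu = np.triu_indices(n, k=1)
    rank_x = rankdata(dx.values[iu])
    # ranks of dy pairs are permutation-invariant as a multiset: rank once,
    # store symmetrically, re-index per draw
    rank_y_mat = squareform(rankdata(dy.values[iu]))

    xc = rank_x - rank_x.mean()
    xnorm = np.sqrt((xc**2).sum())

    def _rho(yv: np.ndarray) -> float:
        yc = yv - yv.mean()
        denom = xnorm * np.sqrt((yc**2).sum())
        if denom == 0:
            return 0.0
        return float((xc @ yc) / denom)

    rho_obs = _rho(rank_y_mat[iu])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        sigma = rng.permutation(n)
        perm = rank_y_mat[np.ix_(sigma, sigma)][iu]
        if _rho(perm) >= rho_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MantelResult(rho=rho_obs, p=float(p), n_permutations=n_permutations,
                        seed=seed, n=n)


def per_site_mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    site_of: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    min_n: int = 4,
) -> dict[str, MantelResult]:
    """Run the Mantel test separately within each site.

    Sites with fewer than ``min_n`` point counts are skipped with a warning.
    Results do not depend on site processing order (each site draws from a
    site-specific seed stream).
    """
    _check_pair(dx, dy)
    sites: dict[str, list[str]] = {}
    for label in dx.labels:
        sites.setdefault(site_of[label], []).append(label)
    results: dict[str, MantelResult] = {}
    for site in sorted(sites):
        labels = sites[site]
        if len(labels) < min_n:
            log.warning("site %s: only %d point counts, skipped", site, len(labels))
            continue
        site_seed = np.random.SeedSequence(
            [seed, sum(map(ord, site))]
        ).generate_state(1)[0] % (2**31)
        results[site] = mantel(
            dx.restrict(labels), dy.restrict(labels), n_permutations, int(site_seed)
        )
    return results


def turnover_asymmetry(
    soundscape: DistanceMatrix, community: DistanceMatrix, decile: float = 0.1
) -> tuple[float, float]:
    """Spread of one change axis where the other is near zero.

    Both matrices are min-max normalized to [0, 1]; returns
    ``(community-range among bottom-decile soundscape pairs,
    soundscape-range among bottom-decile community pairs)``.  A larger first
    element means communities often change while soundscapes do not — more
    often than the converse.
    """
    _check_pair(soundscape, community)
    s = soundscape.condensed()
    c = community.condensed()

    def _norm(v: np.ndarray) -> np.ndarray:
        rng_ = np.ptp(v)
        return (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)

    s_n, c_n = _norm(s), _norm(c)
    low_s = s_n <= np.quantile(s_n, decile)
    low_c = c_n <= np.quantile(c_n, decile)
    return float(np.ptp(c_n[low_s])), float(np.ptp(s_n[low_c]))


class TurnoverAnalysis:
    """Model object: does soundscape change track community change?

    Built from one dataset's occurrence matrix and feature table (sharing
    point-count order); ``fit()`` computes both pairwise-change matrices,
    runs the Mantel test and the richness-change control.
    """

    def __init__(
        self,
        occurrence: OccurrenceMatrix,
        features: FeatureTable,
        config: AnalysisConfig | None = None,
        feature_set: str | None = None,
        zscore: bool = False,
    ) -> None:
        if occurrence.point_count_ids != features.point_count_ids:
            raise ValueError("occurrence and features must share point-count order")
        self.occurrence = occurrence
        self.features = features
        self.config = config or AnalysisConfig()
        self.feature_set = feature_set or self.config.feature_set
        self.zscore = zscore

    def fit(self, control: bool = True) -> "TurnoverResults":
        cfg = self.config
        community = jaccard_matrix(self.occurrence)
        soundscape = euclidean_matrix(self.features, self.feature_set, self.zscore)
        result = mantel(soundscape, community, cfg.mantel_permutations, cfg.seed)
        control_result = None
        if control:
            richness = richness_change_matrix(
                self.occurrence.richness(), self.occurrence.point_count_ids
            )
            control_result = mantel(
                soundscape, richness, cfg.mantel_permutations, cfg.seed
            )
        return TurnoverResults(self, community, soundscape, result, control_result)


@dataclass
class TurnoverResults:
    model: TurnoverAnalysis
    community_distance: DistanceMatrix
    soundscape_distance: DistanceMatrix
    mantel_result: MantelResult
    richness_control: MantelResult | None = None

    def per_site(self, site_of: Mapping[str, str]) -> dict[str, MantelResult]:
        cfg = self.model.config
        return per_site_mantel(
            self.soundscape_distance,
            self.community_distance,
            site_of,
            cfg.mantel_permutations,
            cfg.seed,
        )

    def scatter_table(self) -> pd.DataFrame:
        """One row per point-count pair: soundscape vs community distance."""
        n = self.community_distance.n
        iu = np.triu_indices(n, k=1)
        labels = self.community_distance.labels
        return pd.DataFrame(
            {
                "point_count_a": [labels[i] for i in iu[0]],
                "point_count_b": [labels[j] for j in iu[1]],
                "soundscape_distance": self.soundscape_distance.values[iu],
                "community_distance": self.community_distance.values[iu],
            }
        )

    def asymmetry(self, decile: float = 0.1) -> tuple[float, float]:
        return turnover_asymmetry(
            self.soundscape_distance, self.community_distance, decile
        )

    def summary(self) -> str:
        lines = [
            f"Turnover analysis (feature set {self.model.feature_set}, "
            f"n = {self.community_distance.n} point counts)",
            "  soundscape vs community change: " + self.mantel_result.summary(),
        ]
        if self.richness_control is not None:
            lines.append(
                "  soundscape vs richness change (control): "
                + self.richness_control.summary()
            )
        return "\n".join(lines)
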