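"""End-to-end study runner over a collection of datasets.

A *collection* is a directory with one subdirectory per dataset, each
holding a ``community.csv`` and a ``features.csv`` (+ metadata sidecar) in
the package's CSV schemas — the layout the ``synth`` subcommand writes and
the layout a converted copy of a published deposit should follow.  The
runner executes all three analyses (univariate scan, generalization matrix,
turnover Mantel) and collects their headline numbers in one report.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as sio
from .community import build_occurrence_matrix
from .generalization import GeneralizationResults, GeneralizationStudy
from .turnover import TurnoverAnalysis, TurnoverResults
from .types import AnalysisConfig, FeatureTable, OccurrenceMatrix, PointCount
from .univariate import UnivariateScan, UnivariateScanResults, count_across_datasets

__all__ = ["DatasetBundle", "StudyReport", "load_collection", "run_study"]

log = logging.getLogger(__name__)


@dataclass
class DatasetBundle:
    """One dataset's aligned occurrence matrix and feature table."""

    dataset_id: str
    occurrence: OccurrenceMatrix
    features: FeatureTable
    site_of: dict[str, str]

    @property
    def richness(self) -> np.ndarray:
        return self.occurrence.richness()


def bundle_from_tables(
    dataset_id: str,
    point_counts: list[PointCount],
    features: FeatureTable,
) -> DatasetBundle:
    """Align community and feature tables on their shared point counts.

    Point counts missing from either table are dropped with a warning (a
    point count without matched audio cannot enter feature-based analyses).
    """
    feat_ids = set(features.point_count_ids)
    kept = [pc for pc in point_counts if pc.id in feat_ids]
    dropped = len(point_counts) - len(kept)
    if dropped:
        log.warning("%s: dropped %d point count(s) without features",
                    dataset_id, dropped)
    if not kept:
        raise ValueError(f"{dataset_id}: no point count has features")
    occurrence = build_occurrence_matrix(kept)
    features = features.restrict(occurrence.point_count_ids)
    site_of = {pc.id: pc.site_id for pc in kept}
    return DatasetBundle(dataset_id, occurrence, features, site_of)


def load_collection(root: str | Path) -> dict[str, DatasetBundle]:
    """Load every dataset subdirectory of a collection directory."""
    root = Path(root)
    bundles: dict[str, DatasetBundle] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        community = sub / "community.csv"
        features = sub / "features.csv"
        if not community.exists() or not features.exists():
            continue
        point_counts = sio.read_community_table(community)
        table = sio.read_feature_table(features)
        bundles[sub.name] = bundle_from_tables(sub.name, point_counts, table)
    if not bundles:
        raise FileNotFoundError(
            f"{root}: no dataset subdirectory with community.csv + features.csv"
        )
    return bundles


@dataclass
class StudyReport:
    """Headline numbers of the full three-stage analysis."""

    config: AnalysisConfig
    univariate: dict[str, UnivariateScanResults]
    counts: object  # SignificanceCounts
    generalization: GeneralizationResults | None
    turnover: dict[str, TurnoverResults]
    per_site: dict[str, dict[str, object]]

    def to_dict(self) -> dict:
        out: dict = {"datasets": {}}
        for d, res in self.univariate.items():
            out["datasets"][d] = {
                "n_point_counts": res.scan.n,
                "n_features": len(res.scan.feature_names),
                "null_pool_size": res.null.size,
                "threshold_position": res.threshold.position,
                "threshold_value": res.threshold.threshold_value,
                "n_significant": res.n_significant,
                "mantel_rho": self.turnover[d].mantel_result.rho,
                "mantel_p": self.turnover[d].mantel_result.p,
            }
            ctrl = self.turnover[d].richness_control
            if ctrl is not None:
                out["datasets"][d]["richness_control_p"] = ctrl.p
        nd = self.counts.n_datasets
        out["significance_counts"] = {
            "lf_all_datasets": self.counts.n_significant_in(nd, nd, "LF"),
            "ssi_all_datasets": self.counts.n_significant_in(nd, nd, "SSI"),
            "lf_one_or_two": self.counts.n_significant_in(1, 2, "LF"),
            "ssi_one_or_two": self.counts.n_significant_in(1, 2, "SSI"),
        }
        if self.generalization is not None:
            m = self.generalization.matrix
            out["generalization"] = {
                "r2_matrix": m.to_frame().to_dict(),
                "within_mean": float(m.diagonal.mean()),
                "cross_mean": float(m.cross_means().mean()),
            }
            if len(m.dataset_ids) >= 3:
                ssc = self.generalization.sample_size_correlation()
                out["generalization"]["sample_size_correlation"] = {
                    "r_within": ssc.r_within, "p_within": ssc.p_within,
                    "r_cross": ssc.r_cross, "p_cross": ssc.p_cross,
                }
        if self.per_site:
            out["per_site"] = {
                d: {s: {"rho": r.rho, "p": r.p} for s, r in sites.items()}
                for d, sites in self.per_site.items()
            }
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        parts = [res.summary() for res in self.univariate.values()]
        parts += [res.summary() for res in self.turnover.values()]
        if self.generalization is not None:
            parts.append(self.generalization.summary())
        nd = self.counts.n_datasets
        parts.append(
            f"Features significant in all {nd} datasets: "
            f"{self.counts.n_significant_in(nd, nd, 'LF')} LF, "
            f"{self.counts.n_significant_in(nd, nd, 'SSI')} SSI; "
            f"in one or two: {self.counts.n_significant_in(1, 2, 'LF')} LF, "
            f"{self.counts.n_significant_in(1, 2, 'SSI')} SSI"
        )
        return "\n\n".join(parts)


def run_study(
    bundles: Mapping[str, DatasetBundle],
    config: AnalysisConfig | None = None,
    per_site_datasets: tuple[str, ...] = (),
) -> StudyReport:
    """Run univariate, generalization and turnover stages on a collection."""
    config = config or AnalysisConfig()
    univariate: dict[str, UnivariateScanResults] = {}
    turnover: dict[str, TurnoverResults] = {}
    per_site: dict[str, dict[str, object]] = {}
    for d, b in bundles.items():
        features = b.features.select_family(config.feature_set)
        univariate[d] = UnivariateScan(
            features, b.richness, config, dataset_id=d
        ).fit()
        turnover[d] = TurnoverAnalysis(
            b.occurrence, b.features, config,
            feature_set="LF" if config.feature_set == "ALL" else config.feature_set,
        ).fit()
        if d in per_site_datasets:
            per_site[d] = turnover[d].per_site(b.site_of)
    counts = count_across_datasets(
        {d: res.scan for d, res in univariate.items()},
        {d: res.threshold for d, res in univariate.items()},
    )
    generalization = None
    if all(b.features.n_point_counts >= 4 for b in bundles.values()):
        study = GeneralizationStudy(
            {d: (b.features, b.richness) for d, b in bundles.items()}, config
        )
        generalization = study.fit()
    return StudyReport(config, univariate, counts, generalization, turnover, per_site)
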