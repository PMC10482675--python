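"""Core data types shared by every analysis stage.

The unit of observation throughout is the *point count*: a timed survey at a
site during which every bird species detected is recorded.  Acoustic data
enter as recordings paired (1:1 or by time-window matching) with point
counts; community data enter either as expert point counts or, for
citizen-science collections, as filtered checklists merged into pseudo point
counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "PointCount",
    "Checklist",
    "OccurrenceMatrix",
    "FeatureTable",
    "AnalysisConfig",
    "FeatureFamily",
    "SchemaError",
]

FeatureFamily = Literal["LF", "SSI"]


class SchemaError(ValueError):
    """Raised when a table violates the on-disk schema (names the offender)."""


@dataclass(frozen=True)
class Recording:
    """A single audio recording (WAV on disk or synthesized in memory)."""

    id: str
    dataset_id: str
    site_id: str
    start_time: datetime
    duration: float  # seconds
    sample_rate: float  # Hz
    n_channels: int = 1
    audio_path: Path | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"recording {self.id}: duration must be > 0")
        if self.sample_rate <= 0:
            raise ValueError(f"recording {self.id}: sample_rate must be > 0")
        if self.n_channels < 1:
            raise ValueError(f"recording {self.id}: n_channels must be >= 1")

    @property
    def end_time(self) -> datetime:
        return self.start_time + pd.Timedelta(seconds=self.duration)


@dataclass(frozen=True)
class PointCount:
    """A timed avifaunal survey; ``species`` is the set of detected labels."""

    id: str
    dataset_id: str
    site_id: str
    start_time: datetime
    duration: float  # minutes
    species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"point count {self.id}: duration must be > 0")
        object.__setattr__(self, "species", frozenset(self.species))

    @property
    def richness(self) -> int:
        """Alpha diversity: number of unique species in this point count."""
        return len(self.species)


@dataclass(frozen=True)
class Checklist:
    """A citizen-science checklist with protocol metadata used for filtering."""

    id: str
    protocol: Literal["travelling", "stationary", "other"]
    complete: bool
    distance_to_recorder: float  # metres
    duration: float  # minutes
    start_time: datetime
    species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.distance_to_recorder < 0:
            raise ValueError(f"checklist {self.id}: distance must be >= 0")
        object.__setattr__(self, "species", frozenset(self.species))


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary point-counts x species presence/absence table.

    Row sums are per-point-count species richness; columns are the union of
    observed species, one per label.
    """

    point_count_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    values: np.ndarray  # (n_point_counts, n_species), entries in {0, 1}

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_count_ids", tuple(self.point_count_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        v = np.asarray(self.values)
        if v.shape != (len(self.point_count_ids), len(self.species_ids)):
            raise ValueError(
                f"occurrence shape {v.shape} does not match labels "
                f"({len(self.point_count_ids)}, {len(self.species_ids)})"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("occurrence entries must be binary (0/1)")
        _check_unique(self.point_count_ids, "point_count_id")
        _check_unique(self.species_ids, "species_id")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_point_counts(self) -> int:
        return len(self.point_count_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Per-row species richness (row sums)."""
        return self.values.sum(axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.point_count_ids),
            columns=list(self.species_ids),
        )

    def restrict(self, point_count_ids: Iterable[str]) -> "OccurrenceMatrix":
        ids = list(point_count_ids)
        pos = {p: i for i, p in enumerate(self.point_count_ids)}
        idx = [pos[p] for p in ids]
        return OccurrenceMatrix(tuple(ids), self.species_ids, self.values[idx])


@dataclass(frozen=True)
class FeatureTable:
    """Point-counts x named acoustic features, each tagged LF or SSI.

    LF = learned features (fixed-length embeddings of audio patches);
    SSI = soundscape indices (analytic scalar summaries of a recording).
    """

    point_count_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    family: tuple[FeatureFamily, ...]
    values: np.ndarray  # (n_point_counts, n_features), finite reals

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_count_ids", tuple(self.point_count_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "family", tuple(self.family))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.point_count_ids), len(self.feature_names)):
            raise ValueError(
                f"feature shape {v.shape} does not match labels "
                f"({len(self.point_count_ids)}, {len(self.feature_names)})"
            )
        if len(self.family) != len(self.feature_names):
            raise ValueError("one family tag required per feature")
        bad = set(self.family) - {"LF", "SSI"}
        if bad:
            raise ValueError(f"unknown feature family: {sorted(bad)}")
        if not np.isfinite(v).all():
            j = int(np.argwhere(~np.isfinite(v).all(axis=0)).ravel()[0])
            raise SchemaError(
                f"non-finite value in feature column {self.feature_names[j]!r}"
            )
        _check_unique(self.point_count_ids, "point_count_id")
        _check_unique(self.feature_names, "feature_name")
        object.__setattr__(self, "values", v)

    @property
    def n_point_counts(self) -> int:
        return len(self.point_count_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.point_count_ids),
            columns=list(self.feature_names),
        )

    def select_family(self, feature_set: str) -> "FeatureTable":
        """Restrict to one feature family (``'LF'``/``'SSI'``) or ``'ALL'``."""
        if feature_set == "ALL":
            return self
        if feature_set not in ("LF", "SSI"):
            raise ValueError(f"feature_set must be LF, SSI or ALL, got {feature_set!r}")
        keep = [i for i, f in enumerate(self.family) if f == feature_set]
        if not keep:
            raise ValueError(f"no features of family {feature_set!r}")
        return FeatureTable(
            self.point_count_ids,
            tuple(self.feature_names[i] for i in keep),
            tuple(self.family[i] for i in keep),
            self.values[:, keep],
        )

    def restrict(self, point_count_ids: Iterable[str]) -> "FeatureTable":
        ids = list(point_count_ids)
        pos = {p: i for i, p in enumerate(self.point_count_ids)}
        idx = [pos[p] for p in ids]
        return FeatureTable(tuple(ids), self.feature_names, self.family, self.values[idx])


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs shared across stages.

    ``bonferroni_divisor=None`` means "number of features scanned" (standard
    Bonferroni); ``paper_mode()`` switches the divisor to 60, which
    reproduces the published rank threshold for a 18,800-value pooled null.
    """

    seed: int = 0
    n_shuffles: int = 100
    alpha: float = 0.05
    bonferroni_divisor: int | None = None
    mantel_permutations: int = 999
    train_fraction: float = 0.7
    window_minutes: float = 60.0
    feature_set: Literal["LF", "SSI", "ALL"] = "ALL"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.mantel_permutations < 1:
            raise ValueError("mantel_permutations must be >= 1")
        if self.bonferroni_divisor is not None and self.bonferroni_divisor < 1:
            raise ValueError("bonferroni_divisor must be a positive integer")
        if self.window_minutes < 0:
            raise ValueError("window_minutes must be >= 0")

    @classmethod
    def paper_mode(cls, **overrides) -> "AnalysisConfig":
        """Preset using Bonferroni divisor 60 (the published rank threshold)."""
        overrides.setdefault("bonferroni_divisor", 60)
        return cls(**overrides)

    def replace(self, **changes) -> "AnalysisConfig":
        return replace(self, **changes)
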