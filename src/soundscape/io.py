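"""CSV/YAML persistence for community tables, feature tables and configs.

Schemas
-------
community CSV
    ``point_count_id, dataset_id, site_id, start_time, duration_min, species``
    with species as a ``;``-separated label list (empty string = no species).
feature CSV
    first column ``point_count_id``, remaining columns one feature each; a
    sidecar metadata CSV maps ``feature_name -> family`` (LF or SSI).
checklist CSV
    ``checklist_id, protocol, complete, distance_m, duration_min,
    start_time, species``.
occurrence CSV
    first column ``point_count_id``, remaining columns one species each,
    entries strictly 0/1.

All errors raised on malformed input are :class:`~soundscape.types.SchemaError`
and name the offending column.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    Checklist,
    FeatureTable,
    OccurrenceMatrix,
    PointCount,
    SchemaError,
)

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_feature_table",
    "write_feature_table",
    "read_checklist_table",
    "write_checklist_table",
    "read_occurrence_matrix",
    "write_occurrence_matrix",
    "read_config",
    "write_config",
]

log = logging.getLogger(__name__)

COMMUNITY_COLUMNS = [
    "point_count_id",
    "dataset_id",
    "site_id",
    "start_time",
    "duration_min",
    "species",
]
CHECKLIST_COLUMNS = [
    "checklist_id",
    "protocol",
    "complete",
    "distance_m",
    "duration_min",
    "start_time",
    "species",
]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _split_species(cell) -> frozenset[str]:
    if pd.isna(cell) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def read_community_table(path: str | Path) -> list[PointCount]:
    """Read point counts from a community CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"species": str}, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, COMMUNITY_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PointCount(
                id=str(row.point_count_id),
                dataset_id=str(row.dataset_id),
                site_id=str(row.site_id),
                start_time=pd.Timestamp(row.start_time).to_pydatetime(),
                duration=float(row.duration_min),
                species=_split_species(row.species),
            )
        )
    log.info("read %d point counts from %s", len(out), path)
    return out


def write_community_table(point_counts: list[PointCount], path: str | Path) -> None:
    rows = [
        {
            "point_count_id": pc.id,
            "dataset_id": pc.dataset_id,
            "site_id": pc.site_id,
            "start_time": pc.start_time.isoformat(),
            "duration_min": pc.duration,
            "species": ";".join(sorted(pc.species)),
        }
        for pc in point_counts
    ]
    pd.DataFrame(rows, columns=COMMUNITY_COLUMNS).to_csv(path, index=False)


def read_checklist_table(path: str | Path) -> list[Checklist]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"species": str}, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, CHECKLIST_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        complete = row.complete
        if isinstance(complete, str):
            complete = complete.strip().lower() in ("true", "1", "yes")
        out.append(
            Checklist(
                id=str(row.checklist_id),
                protocol=str(row.protocol),
                complete=bool(complete),
                distance_to_recorder=float(row.distance_m),
                duration=float(row.duration_min),
                start_time=pd.Timestamp(row.start_time).to_pydatetime(),
                species=_split_species(row.species),
            )
        )
    return out


def write_checklist_table(checklists: list[Checklist], path: str | Path) -> None:
    rows = [
        {
            "checklist_id": c.id,
            "protocol": c.protocol,
            "complete": c.complete,
            "distance_m": c.distance_to_recorder,
            "duration_min": c.duration,
            "start_time": c.start_time.isoformat(),
            "species": ";".join(sorted(c.species)),
        }
        for c in checklists
    ]
    pd.DataFrame(rows, columns=CHECKLIST_COLUMNS).to_csv(path, index=False)


def _metadata_path(path: Path) -> Path:
    return path.with_name(path.stem + "_metadata.csv")


def read_feature_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> FeatureTable:
    """Read a feature CSV plus its ``feature_name -> family`` sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns.empty or df.columns[0] != "point_count_id":
        raise SchemaError(f"{path}: first column must be 'point_count_id'")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: no feature columns present")
    meta_path = Path(metadata_path) if metadata_path else _metadata_path(path)
    meta = pd.read_csv(meta_path)
    _require_columns(meta, ["feature_name", "family"], meta_path)
    family_map = dict(zip(meta["feature_name"].astype(str), meta["family"]))
    names = [str(c) for c in df.columns[1:]]
    missing = [n for n in names if n not in family_map]
    if missing:
        raise SchemaError(f"{meta_path}: no family tag for column(s) {missing}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        raise SchemaError(f"{path}: NaN/inf in feature column {names[bad[0, 1]]!r}")
    return FeatureTable(
        point_count_ids=tuple(df["point_count_id"].astype(str)),
        feature_names=tuple(names),
        family=tuple(family_map[n] for n in names),
        values=values,
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    path = Path(path)
    df = table.to_frame()
    df.insert(0, "point_count_id", list(table.point_count_ids))
    df.to_csv(path, index=False)
    meta = pd.DataFrame(
        {"feature_name": list(table.feature_names), "family": list(table.family)}
    )
    meta.to_csv(Path(metadata_path) if metadata_path else _metadata_path(path),
                index=False)


def read_occurrence_matrix(path: str | Path) -> OccurrenceMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns.empty or df.columns[0] != "point_count_id":
        raise SchemaError(f"{path}: first column must be 'point_count_id'")
    values = df.iloc[:, 1:].to_numpy()
    species = [str(c) for c in df.columns[1:]]
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        j = int(np.argwhere(bad)[0, 1])
        raise SchemaError(
            f"{path}: non-binary occurrence entry in column {species[j]!r}"
        )
    return OccurrenceMatrix(
        tuple(df["point_count_id"].astype(str)), tuple(species),
        values.astype(np.int8),
    )


def write_occurrence_matrix(matrix: OccurrenceMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "point_count_id", list(matrix.point_count_ids))
    df.to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
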