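"""Synthetic multi-dataset landscapes with known community-feature coupling.

The generator emulates the statistical structure the downstream analyses
assume, without modelling real birdsong:

* Sites lie on a one-dimensional habitat axis ``h_s``; species ``j`` has a
  Gaussian niche centred at ``c_j`` (evenly spaced on [0, 1]) of width ``w``,
  giving an occupancy surface ``p_js = p_max * exp(-(h_s - c_j)^2 / (2 w^2))``.
  A point count at site ``s`` records species ``j`` independently with
  probability ``p_js * detection_prob`` — richness and composition therefore
  turn over along the gradient.
* Acoustic features are a noisy dataset-specific linear read-out of the
  occurrence row: ``f_i = beta * W x_i + eta * u_i * v + eps_i`` with a
  standard-normal mixing map ``W`` drawn from ``map_seed``, a smooth
  time-of-day nuisance ``u_i`` (standing in for non-biotic sound such as
  motors), a fixed unit nuisance direction ``v`` and iid Gaussian noise.
  Sharing ``map_seed`` across datasets makes feature semantics transferable;
  independent maps make cross-dataset generalization fail by construction.
* Optionally each point count can be rendered to audio: every present
  species emits a tone train at a species-specific frequency plus white
  noise, so richer communities occupy more spectrogram bands.

All randomness flows from seeds in the configs; there is no global state.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Literal

import numpy as np

from .audio import AudioBuffer
from .community import build_occurrence_matrix
from .types import FeatureTable, OccurrenceMatrix, PointCount

__all__ = [
    "LandscapeConfig",
    "FeatureMapConfig",
    "AudioRenderConfig",
    "SyntheticDataset",
    "generate_community",
    "generate_features",
    "generate_dataset",
    "generate_collection",
    "render_audio",
    "expected_richness",
]

log = logging.getLogger(__name__)

_BASE_TIME = datetime(2020, 1, 1, 6, 0, 0)


@dataclass(frozen=True)
class LandscapeConfig:
    """Community-side knobs: survey size, niche geometry, detectability."""

    n_sites: int = 20
    n_species: int = 50
    n_point_counts: int = 200
    niche_width: float = 0.15
    detection_prob: float = 0.8
    max_occupancy: float = 0.9
    habitat_distribution: Literal["uniform", "gradient-block"] = "gradient-block"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_sites < 1 or self.n_point_counts < 1:
            raise ValueError("n_sites and n_point_counts must be >= 1")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        for name in ("detection_prob", "max_occupancy"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class FeatureMapConfig:
    """Feature-side knobs: map size, coupling beta, noise, nuisance."""

    n_lf: int = 128
    n_ssi: int = 60
    coupling: float = 1.0
    noise_sd: float = 0.5
    nuisance_amp: float = 1.0
    map_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lf + self.n_ssi < 1:
            raise ValueError("need at least one feature")
        if min(self.coupling, self.noise_sd, self.nuisance_amp) < 0:
            raise ValueError("coupling, noise_sd and nuisance_amp must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_lf + self.n_ssi


@dataclass(frozen=True)
class AudioRenderConfig:
    sample_rate: int = 16_000
    duration: float = 5.0  # seconds
    noise_amp: float = 0.05
    tone_amp: float = 0.2
    seed: int = 0


@dataclass
class SyntheticDataset:
    """One (occurrence, features) pair plus the generating latents."""

    dataset_id: str
    point_counts: list[PointCount]
    occurrence: OccurrenceMatrix
    features: FeatureTable
    truth: dict = field(default_factory=dict)

    @property
    def richness(self) -> np.ndarray:
        return self.occurrence.richness()


def _habitat_axis(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    if config.habitat_distribution == "uniform":
        return rng.random(config.n_sites)
    # gradient-block: sites evenly spaced along the axis
    return (np.arange(config.n_sites) + 0.5) / config.n_sites


def occupancy_surface(config: LandscapeConfig, habitat: np.ndarray) -> np.ndarray:
    """(n_sites, n_species) occupancy probabilities from the Gaussian niches."""
    centres = np.linspace(0.0, 1.0, config.n_species)
    d2 = (habitat[:, None] - centres[None, :]) ** 2
    return config.max_occupancy * np.exp(-d2 / (2.0 * config.niche_width**2))


def expected_richness(config: LandscapeConfig, habitat: np.ndarray) -> np.ndarray:
    """Closed-form expected richness per site: sum_j p_js * detection_prob."""
    return occupancy_surface(config, habitat).sum(axis=1) * config.detection_prob


def generate_community(
    config: LandscapeConfig, dataset_id: str = "synthetic"
) -> tuple[list[PointCount], OccurrenceMatrix, dict]:
    """Draw point counts along the habitat gradient.

    Returns the point counts, their occurrence matrix, and a ``truth`` dict
    with the latents (habitat axis, occupancy surface, site assignment and
    time-of-day fraction per point count) used downstream.
    """
    rng = np.random.default_rng(config.seed)
    habitat = _habitat_axis(config, rng)
    occupancy = occupancy_surface(config, habitat)

    site_of = np.arange(config.n_point_counts) % config.n_sites
    # surveys spread over the 06:00-10:00 activity window on successive days
    tod = rng.random(config.n_point_counts)
    present = rng.random((config.n_point_counts, config.n_species)) < (
        occupancy[site_of] * config.detection_prob
    )

    species_labels = [f"sp{j:03d}" for j in range(config.n_species)]
    width = max(3, len(str(config.n_point_counts - 1)))
    point_counts = []
    for i in range(config.n_point_counts):
        start = _BASE_TIME + timedelta(
            days=int(i // config.n_sites), hours=4.0 * float(tod[i])
        )
        point_counts.append(
            PointCount(
                id=f"{dataset_id}-pc{i:0{width}d}",
                dataset_id=dataset_id,
                site_id=f"site{site_of[i]:02d}",
                start_time=start,
                duration=20.0,
                species=frozenset(
                    species_labels[j] for j in np.flatnonzero(present[i])
                ),
            )
        )
    occurrence = _occurrence_from_bool(point_counts, species_labels, present)
    truth = {
        "habitat": habitat,
        "occupancy": occupancy,
        "site_of": site_of,
        "time_of_day": tod,
        "seed": config.seed,
        "config": config,
    }
    log.info(
        "generate_community: %d point counts, %d sites, mean richness %.1f",
        config.n_point_counts, config.n_sites, occurrence.richness().mean(),
    )
    return point_counts, occurrence, truth


def _occurrence_from_bool(point_counts, species_labels, present) -> OccurrenceMatrix:
    # columns must be the sorted union of *observed* species
    observed = np.flatnonzero(present.any(axis=0))
    if observed.size == 0:
        # degenerate all-absent draw: keep a single empty column set
        return build_occurrence_matrix(point_counts)
    labels = sorted(species_labels[j] for j in observed)
    order = np.argsort([species_labels[j] for j in observed])
    values = present[:, observed[order]].astype(np.int8)
    return OccurrenceMatrix(
        tuple(pc.id for pc in point_counts), tuple(labels), values
    )


def feature_names_for(config: FeatureMapConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Canonical feature names/families for a map config (LF block then SSI)."""
    ssi_named = ["temporal_entropy", "spectral_entropy",
                 "acoustic_complexity", "spectrogram_cover"]
    names = [f"LF_{k:03d}" for k in range(config.n_lf)]
    names += [ssi_named[k] if k < len(ssi_named) else f"SSI_{k:02d}"
              for k in range(config.n_ssi)]
    family = ("LF",) * config.n_lf + ("SSI",) * config.n_ssi
    return tuple(names), family


def generate_features(
    occurrence: OccurrenceMatrix,
    truth: dict,
    config: FeatureMapConfig,
    noise_seed: int | None = None,
) -> FeatureTable:
    """Mix occurrence rows into acoustic features.

    ``f_i = coupling * W x_i + nuisance_amp * u_i * v + eps_i`` with ``W``
    (and the nuisance direction/site offsets) drawn from ``map_seed`` and the
    observation noise from ``noise_seed`` (defaults to the landscape seed),
    so datasets can share a map while drawing independent noise.
    """
    if occurrence.n_point_counts == 0:
        raise ValueError("occurrence matrix is empty")
    map_rng = np.random.default_rng(config.map_seed)
    mixing = map_rng.standard_normal((config.n_features, occurrence.n_species))
    direction = map_rng.standard_normal(config.n_features)
    direction /= np.linalg.norm(direction)
    n_sites = int(np.max(truth["site_of"])) + 1
    site_offset = map_rng.standard_normal(n_sites)

    nuisance = (
        np.sin(2.0 * np.pi * np.asarray(truth["time_of_day"]))
        + site_offset[truth["site_of"]]
    )
    if noise_seed is None:
        noise_seed = int(truth.get("seed", 0))
    noise_rng = np.random.default_rng([noise_seed, 0x5EED])
    eps = config.noise_sd * noise_rng.standard_normal(
        (occurrence.n_point_counts, config.n_features)
    )
    x = occurrence.values.astype(float)
    values = (
        config.coupling * x @ mixing.T
        + config.nuisance_amp * nuisance[:, None] * direction[None, :]
        + eps
    )
    truth["mixing_map"] = mixing
    truth["nuisance"] = nuisance
    truth["nuisance_direction"] = direction
    names, family = feature_names_for(config)
    return FeatureTable(occurrence.point_count_ids, names, family, values)


def generate_dataset(
    landscape: LandscapeConfig,
    feature_map: FeatureMapConfig,
    dataset_id: str = "synthetic",
) -> SyntheticDataset:
    point_counts, occurrence, truth = generate_community(landscape, dataset_id)
    features = generate_features(occurrence, truth, feature_map)
    return SyntheticDataset(dataset_id, point_counts, occurrence, features, truth)


#: survey-effort multipliers cycled across datasets so collections have the
#: heterogeneous sample sizes real multi-study campaigns do
SIZE_FACTORS = (1.0, 0.6, 1.5, 0.8)


def generate_collection(
    n_datasets: int = 4,
    seed: int = 0,
    shared_map: bool = False,
    landscape: LandscapeConfig | None = None,
    feature_map: FeatureMapConfig | None = None,
) -> list[SyntheticDataset]:
    """A multi-dataset collection mirroring a multi-study field campaign.

    Each dataset draws an independent community (seed offset by its index)
    and, unless ``shared_map`` is set, an independent dataset-specific
    feature map — the regime in which cross-dataset prediction fails.
    Survey effort varies across datasets (``SIZE_FACTORS``).
    """
    landscape = landscape or LandscapeConfig()
    feature_map = feature_map or FeatureMapConfig()
    datasets = []
    for k in range(n_datasets):
        n_pc = max(
            landscape.n_sites,
            int(round(landscape.n_point_counts
                      * SIZE_FACTORS[k % len(SIZE_FACTORS)])),
        )
        lc = LandscapeConfig(
            **{**landscape.__dict__, "seed": seed + k, "n_point_counts": n_pc}
        )
        map_seed = feature_map.map_seed + seed if shared_map else feature_map.map_seed + seed + 1000 * (k + 1)
        fm = FeatureMapConfig(**{**feature_map.__dict__, "map_seed": map_seed})
        datasets.append(generate_dataset(lc, fm, dataset_id=f"synth{k}"))
    return datasets


def render_audio(
    point_count: PointCount,
    truth: dict,
    config: AudioRenderConfig | None = None,
) -> AudioBuffer:
    """Render a point count as audio: one tone train per present species.

    Species ``spNNN`` emits an on/off gated sinusoid at a frequency unique to
    it (spread over 500-7,000 Hz), plus white noise at ``noise_amp``; with
    more species present, more spectrogram bands are occupied.
    """
    config = config or AudioRenderConfig()
    if config.duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    samples = np.zeros(n)
    n_species = truth["occupancy"].shape[1]
    freqs = np.linspace(500.0, 7000.0, n_species)
    for label in sorted(point_count.species):
        j = int(label.removeprefix("sp"))
        # intermittent call train (25% duty cycle), phase-offset per species
        gate = (np.floor(t / 0.25 + j) % 4 == 0).astype(float)
        samples += config.tone_amp * gate * np.sin(2 * np.pi * freqs[j] * t)
    if config.noise_amp > 0:
        rng = np.random.default_rng(
            [config.seed, zlib.crc32(point_count.id.encode())]
        )
        samples += config.noise_amp * rng.standard_normal(n)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples /= peak
    return AudioBuffer(samples=samples, sample_rate=config.sample_rate, n_channels=1)
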