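"""Synthetic LC-MS feature-table corpora with known ground truth.

The generator emulates the statistical structure the card method assumes,
at the scale of the real study material (several thousand ions per sample,
Rt 1–26 min, m/z 100–1500, batch drift well inside the 0.05 min / 0.05 Da
tolerance):

* a *common panel* of ions shared by every origin (the genus-wide chemistry
  that makes origins hard to tell apart),
* one *unique panel* per origin (the origin-specific chemistry the cards
  are meant to capture),
* *batch noise* ions drawn fresh for every sample (non-reproducible
  features: one-off contaminants, misintegrated peaks),
* a *blank panel* of solvent/matrix contaminants emitted both as standalone
  blank tables and injected into every sample.

Every planted ion lives in its own cell of an (Rt × m/z) grid whose spacing
exceeds twice the matching tolerance, so distinct planted ions can never
match each other and ground truth is unambiguous under jitter.  Per batch,
each panel ion is emitted with probability 1 − dropout, its coordinates get
Gaussian jitter, its intensity is the ion's log-normal base intensity times
a per-batch log-normal factor, and ions below the detection floor vanish —
which is also why a minor mixture component loses part of its fingerprint.

Everything is driven by one ``numpy`` generator seeded from the config, so
corpora are bit-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError
from .feature_model import FeatureTable

__all__ = [
    "GeneratorConfig",
    "IonPanel",
    "GroundTruth",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_mixture",
    "mix_feature_tables",
]


class IonPanel(NamedTuple):
    """Ground-truth ion panel: base coordinates and base intensities."""

    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.rt)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    Defaults reproduce the study scale: 5 origins × 6 batches, ~3,000–4,500
    ions per sample after dropout and detection-floor losses, blanks of
    ~3,500–4,000 ions, and coordinate jitter (SD 0.01 min / 0.01 Da) that
    keeps replicate drift far inside the 0.05 tolerance window.
    """

    n_origins: int = 5
    batches_per_origin: int | Sequence[int] = 6
    heldout_per_origin: int = 0
    common_panel_size: int = 2800
    unique_panel_size: int = 400
    noise_ions_per_batch: int = 1200
    blank_panel_size: int = 4500
    blank_ions_per_sample: int = 300
    n_blank_tables: int = 2
    rt_range: tuple[float, float] = (1.0, 26.0)
    mz_range: tuple[float, float] = (100.0, 1500.0)
    rt_jitter_sd: float = 0.01
    mz_jitter_sd: float = 0.01
    log_intensity_mean: float = 10.0
    log_intensity_sd: float = 1.5
    batch_log_intensity_sd: float = 0.3
    dropout_rate: float = 0.05
    detection_floor: float = 5000.0
    # grid cell sizes; must exceed 2x the matching tolerance so planted ions
    # from different cells can never match
    cell_rt: float = 0.15
    cell_mz: float = 0.15
    origin_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("common_panel_size", "unique_panel_size", "noise_ions_per_batch",
                     "blank_panel_size", "blank_ions_per_sample", "n_blank_tables",
                     "heldout_per_origin"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_origins < 1:
            raise ConfigurationError("n_origins must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.blank_ions_per_sample > self.blank_panel_size:
            raise ConfigurationError("blank_ions_per_sample exceeds blank_panel_size")
        if self.origin_labels is not None and len(self.origin_labels) != self.n_origins:
            raise ConfigurationError("origin_labels length must equal n_origins")

    @property
    def labels(self) -> list[str]:
        if self.origin_labels is not None:
            return list(self.origin_labels)
        return [f"origin-{i + 1}" for i in range(self.n_origins)]

    @property
    def batches(self) -> list[int]:
        if isinstance(self.batches_per_origin, int):
            return [self.batches_per_origin] * self.n_origins
        counts = list(self.batches_per_origin)
        if len(counts) != self.n_origins:
            raise ConfigurationError("batches_per_origin length must equal n_origins")
        return counts


@dataclass
class GroundTruth:
    """Planted panel memberships, for assertions against built cards."""

    common: IonPanel
    unique: dict[str, IonPanel]
    blank: IonPanel

    def in_unique_panel(
        self, origin: str, rt: np.ndarray, mz: np.ndarray, delta_rt: float, delta_mz: float
    ) -> np.ndarray:
        """Per query ion, does it match a planted unique ion of ``origin``."""
        from . import _join

        panel = self.unique[origin]
        idx = _join.SortedIndex(panel.rt, panel.mz)
        return _join.match_mask(np.asarray(rt, float), np.asarray(mz, float),
                                idx, delta_rt, delta_mz)


@dataclass
class SyntheticCorpus:
    """Generated corpus: build batches, blanks, held-out samples, truth."""

    batches: list[FeatureTable]
    blanks: list[FeatureTable]
    heldout: list[FeatureTable]
    truth: GroundTruth
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def all_tables(self) -> list[FeatureTable]:
        return self.batches + self.blanks + self.heldout


def _grid(config: GeneratorConfig) -> tuple[int, int]:
    n_rt = int(np.floor((config.rt_range[1] - config.rt_range[0]) / config.cell_rt))
    n_mz = int(np.floor((config.mz_range[1] - config.mz_range[0]) / config.cell_mz))
    return n_rt, n_mz


def _cells_to_coords(cells: np.ndarray, config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    _, n_mz = _grid(config)
    i_rt, i_mz = np.divmod(cells, n_mz)
    rt = config.rt_range[0] + (i_rt + 0.5) * config.cell_rt
    mz = config.mz_range[0] + (i_mz + 0.5) * config.cell_mz
    return rt, mz


def _emit(
    panel: IonPanel,
    rng: np.random.Generator,
    config: GeneratorConfig,
    dropout: float | None = None,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Realize one sample's view of a panel: dropout, jitter, intensity noise,
    detection floor.  The rng draw order is fixed for determinism."""
    n = len(panel)
    dropout = config.dropout_rate if dropout is None else dropout
    keep = rng.random(n) >= dropout
    rt = panel.rt + rng.normal(0.0, config.rt_jitter_sd, n)
    mz = panel.mz + rng.normal(0.0, config.mz_jitter_sd, n)
    intensity = panel.intensity * np.exp(rng.normal(0.0, config.batch_log_intensity_sd, n))
    intensity = intensity * scale
    keep &= (intensity >= config.detection_floor) & (intensity > 0)
    return rt[keep], mz[keep], intensity[keep]


def _base_intensities(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    return np.exp(rng.normal(config.log_intensity_mean, config.log_intensity_sd, n))


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a full corpus (build batches, blank tables, held-out samples)
    plus the planted ground truth.

    Raises a configuration error when the requested panels cannot be placed
    on the separation grid (too many ions for the Rt × m/z area at the
    required spacing).
    """
    rng = np.random.default_rng(config.seed)
    labels = config.labels
    batch_counts = config.batches
    n_noise_draws = sum(batch_counts) + config.heldout_per_origin * config.n_origins
    needed = (
        config.common_panel_size
        + config.unique_panel_size * config.n_origins
        + config.blank_panel_size
        + config.noise_ions_per_batch * n_noise_draws
    )
    n_rt, n_mz = _grid(config)
    if needed > n_rt * n_mz:
        raise ConfigurationError(
            f"panels need {needed} grid cells but only {n_rt * n_mz} are available; "
            "shrink the panels or the cell spacing"
        )
    cells = rng.choice(n_rt * n_mz, size=needed, replace=False)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = cells[pos:pos + k]
        pos += k
        return out

    def make_panel(k: int) -> IonPanel:
        rt, mz = _cells_to_coords(take(k), config)
        return IonPanel(rt, mz, _base_intensities(rng, k, config))

    common = make_panel(config.common_panel_size)
    unique = {label: make_panel(config.unique_panel_size) for label in labels}
    blank = make_panel(config.blank_panel_size)

    def origin_panel(label: str) -> IonPanel:
        up = unique[label]
        return IonPanel(
            np.concatenate([common.rt, up.rt]),
            np.concatenate([common.mz, up.mz]),
            np.concatenate([common.intensity, up.intensity]),
        )

    def make_sample(label: str, sample_id: str, role: str = "sample") -> FeatureTable:
        panel = origin_panel(label)
        rt, mz, inten = _emit(panel, rng, config)
        # batch-specific noise ions: fresh cells, never repeated across samples
        n_noise = config.noise_ions_per_batch
        nrt, nmz = _cells_to_coords(take(n_noise), config)
        noise = IonPanel(nrt, nmz, _base_intensities(rng, n_noise, config))
        nrt, nmz, ninten = _emit(noise, rng, config)
        # solvent/matrix contaminants: a random subset of the blank panel
        k = config.blank_ions_per_sample
        sub = rng.choice(config.blank_panel_size, size=k, replace=False) if k else np.array([], int)
        contam = IonPanel(blank.rt[sub], blank.mz[sub], blank.intensity[sub])
        crt, cmz, cinten = _emit(contam, rng, config)
        return FeatureTable(
            sample_id,
            np.concatenate([rt, nrt, crt]),
            np.concatenate([mz, nmz, cmz]),
            np.concatenate([inten, ninten, cinten]),
            origin=label,
            role=role,
        )

    batches: list[FeatureTable] = []
    for label, count in zip(labels, batch_counts):
        for b in range(count):
            batches.append(make_sample(label, f"{label}-B{b + 1:02d}"))
    blanks: list[FeatureTable] = []
    for b in range(config.n_blank_tables):
        rt, mz, inten = _emit(blank, rng, config)
        blanks.append(FeatureTable(f"blank-{b + 1:02d}", rt, mz, inten, role="blank"))
    heldout: list[FeatureTable] = []
    for label in labels:
        for h in range(config.heldout_per_origin):
            heldout.append(make_sample(label, f"{label}-T{h + 1:02d}"))

    truth = GroundTruth(common=common, unique=unique, blank=blank)
    return SyntheticCorpus(batches=batches, blanks=blanks, heldout=heldout,
                           truth=truth, config=config)


def generate_mixture(
    authentic_panel: IonPanel,
    adulterant_panel: IonPanel,
    proportion: float,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> FeatureTable:
    """Synthesize a binary powder mixture from two ground-truth panels.

    Authentic ions are emitted with intensities scaled by (1 − proportion),
    adulterant ions scaled by proportion; jitter, dropout and the detection
    floor apply as in :func:`generate_corpus`, so at low proportions part of
    the adulterant fingerprint falls below the floor and vanishes.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ConfigurationError("proportion must lie in [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    art, amz, ai = _emit(authentic_panel, rng, config, scale=1.0 - proportion)
    brt, bmz, bi = _emit(adulterant_panel, rng, config, scale=proportion)
    return FeatureTable(
        sample_id or f"mixture-{proportion:.0%}",
        np.concatenate([art, brt]),
        np.concatenate([amz, bmz]),
        np.concatenate([ai, bi]),
        role="sample",
    )


def mix_feature_tables(
    authentic: FeatureTable,
    adulterant: FeatureTable,
    proportion: float,
    detection_floor: float = 5000.0,
    rt_jitter_sd: float = 0.01,
    mz_jitter_sd: float = 0.01,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> FeatureTable:
    """Mix two realized feature tables as a mass-proportion blend.

    Authentic intensities are scaled by (1 − proportion) and adulterant
    intensities by proportion; both sides receive fresh coordinate jitter
    (a new chromatographic run drifts again) and ions below the detection
    floor are dropped.  Intensities of coincident ions are not summed — the
    two scaled ion lists are concatenated, which matching (presence within
    tolerance) is insensitive to.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ConfigurationError("proportion must lie in [0, 1]")
    rng = np.random.default_rng(0) if rng is None else rng
    parts = []
    for table, scale in ((authentic, 1.0 - proportion), (adulterant, proportion)):
        rt = table.rt + rng.normal(0.0, rt_jitter_sd, table.n_ions)
        mz = table.mz + rng.normal(0.0, mz_jitter_sd, table.n_ions)
        inten = table.intensity * scale
        keep = (inten >= detection_floor) & (inten > 0)
        parts.append((rt[keep], mz[keep], inten[keep]))
    return FeatureTable(
        sample_id or f"mix-{proportion:.0%}-{adulterant.sample_id}-in-{authentic.sample_id}",
        np.concatenate([parts[0][0], parts[1][0]]),
        np.concatenate([parts[0][1], parts[1][1]]),
        np.concatenate([parts[0][2], parts[1][2]]),
        role="sample",
    )
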