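"""Seeded synthetic generator for microwell-array dPCR image sets.

Emulates the imaging output of a fixed-array dPCR instrument: each of the
20,000 molded wells either loads reagent (Bernoulli, ~98% success) or stays
empty; loaded wells receive target copies per probe channel from a Poisson
law with mean λ = concentration × partition volume; the array is imaged in a
passive reference channel (ROX, bright wherever reagent loaded) and in probe
channels (FAM/HEX) before and after thermal cycling.  Amplification is
all-or-none: a well with ≥1 copy renders at the full positive intensity in
the post-cycling image (endpoint-PCR assumption).  A smooth multiplicative
illumination field and additive Gaussian pixel noise are applied, and images
are quantized to the configured bit depth.

Everything is deterministic given (seed, config); occupancy and rendering use
independent seed streams so the same truth can be re-rendered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, InvalidInputError
from .geometry import DEFAULT_GEOMETRY, ArrayGeometry, PL_PER_UL
from .layout import PixelLayout
from .table import PartitionTable

ROX = "ROX"
PHASES = ("pre", "post")


@dataclass(frozen=True)
class IlluminationField:
    """Multiplicative excitation non-uniformity applied to rendered images.

    kinds
    -----
    ``flat``             constant 1 (amplitude must be 0)
    ``planar-gradient``  1 + a·(2x/(W−1) − 1): spans ±a across the width
    ``radial-vignette``  1 − a·(r/r_corner)²: falls to 1 − a at the corners
    """

    kind: str = "flat"
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "radial-vignette", "planar-gradient"):
            raise ConfigError(f"unknown illumination kind {self.kind!r}")
        if not 0.0 <= self.amplitude < 1.0:
            raise ConfigError("illumination amplitude must lie in [0, 1)")
        if self.kind == "flat" and self.amplitude != 0.0:
            raise ConfigError("flat illumination must have amplitude 0")

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        if self.kind == "flat":
            return np.ones(shape)
        if self.kind == "planar-gradient":
            x = np.arange(w)
            row = 1.0 + self.amplitude * (2.0 * x / (w - 1) - 1.0)
            return np.broadcast_to(row, shape).copy()
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        return 1.0 - self.amplitude * r2 / r2.max()


@dataclass(frozen=True)
class ChannelLevels:
    """Rendered patch intensity levels (ADU) for one channel."""

    negative_mean: float
    positive_mean: float
    noise_sd: float


def _default_levels() -> dict[str, ChannelLevels]:
    return {
        ROX: ChannelLevels(300.0, 30000.0, 200.0),
        "FAM": ChannelLevels(3000.0, 18000.0, 200.0),
        "HEX": ChannelLevels(3000.0, 18000.0, 200.0),
    }


@dataclass
class SimulationConfig:
    """All knobs of one synthetic run.

    Defaults reproduce the platform's stated operating point: 20,000 wells of
    517 pL, 2% fill failure, a 1006 copies/µL FAM target, a 20% radial
    vignette, and 16-bit images at 10 µm/px.
    """

    seed: int = 0
    geometry: ArrayGeometry = DEFAULT_GEOMETRY
    channel_concentrations: dict[str, float] = field(
        default_factory=lambda: {"FAM": 1006.0, "HEX": 0.0})
    fill_failure_rate: float = 0.02
    pixel_pitch: float = 10.0
    image_bit_depth: int = 16
    background: float = 300.0
    levels: dict[str, ChannelLevels] = field(default_factory=_default_levels)
    illumination: IlluminationField = IlluminationField("radial-vignette", 0.2)
    grid_offset: tuple[float, float] = (0.0, 0.0)
    margin_px: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_failure_rate <= 1.0:
            raise ConfigError("fill_failure_rate must lie in [0, 1]")
        if not 1 <= self.image_bit_depth <= 16:
            raise ConfigError("image_bit_depth must lie in [1, 16]")
        for ch, conc in self.channel_concentrations.items():
            if conc < 0:
                raise ConfigError(f"negative concentration for channel {ch}")
            if ch not in self.levels:
                raise ConfigError(f"no intensity levels for channel {ch}")
            lv = self.levels[ch]
            if lv.positive_mean <= lv.negative_mean + 6 * lv.noise_sd:
                raise ConfigError(
                    f"channel {ch}: positive and negative classes are not "
                    "separable (need positive > negative + 6·noise_sd)")

    @property
    def probe_channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.channel_concentrations))

    @property
    def layout(self) -> PixelLayout:
        return PixelLayout(self.geometry, self.pixel_pitch, self.margin_px,
                           self.grid_offset)

    def mean_copies(self, channel: str) -> float:
        """λ = concentration (copies/µL) × partition volume (µL)."""
        v_ul = self.geometry.nominal_volume_pl / PL_PER_UL
        return self.channel_concentrations[channel] * v_ul


@dataclass
class SimulationTruth:
    """Latent per-partition state: fill status and copy counts per channel."""

    geometry: ArrayGeometry
    row: np.ndarray
    col: np.ndarray
    filled: np.ndarray
    copies: dict[str, np.ndarray]

    def is_positive(self, channel: str) -> np.ndarray:
        return self.filled & (self.copies[channel] >= 1)

    def n_positive(self, channel: str) -> int:
        return int(self.is_positive(channel).sum())

    @property
    def n_filled(self) -> int:
        return int(self.filled.sum())

    def to_frame(self) -> pd.DataFrame:
        d = {"row": self.row, "col": self.col, "filled": self.filled}
        for ch in sorted(self.copies):
            d[f"copies_{ch}"] = self.copies[ch]
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, geometry: ArrayGeometry) -> "SimulationTruth":
        copies = {c[len("copies_"):]: df[c].to_numpy(dtype=int)
                  for c in df.columns if c.startswith("copies_")}
        return cls(geometry, df["row"].to_numpy(dtype=int),
                   df["col"].to_numpy(dtype=int),
                   df["filled"].to_numpy(dtype=bool), copies)


@dataclass
class ImageSet:
    """Pre/post-cycling rasters per channel, plus the config that made them."""

    images: dict[str, dict[str, np.ndarray]]
    config: SimulationConfig

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.images)

    def save(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for ch, phases in self.images.items():
            for phase, img in phases.items():
                p = outdir / f"{ch}_{phase}.tif"
                tifffile.imwrite(p, img)
                paths.append(p)
        return paths

    @classmethod
    def load(cls, indir: str | Path, config: SimulationConfig) -> "ImageSet":
        indir = Path(indir)
        images: dict[str, dict[str, np.ndarray]] = {}
        for ch in (ROX,) + config.probe_channels:
            images[ch] = {}
            for phase in PHASES:
                p = indir / f"{ch}_{phase}.tif"
                if not p.exists():
                    raise ConfigError(f"missing image file {p}")
                images[ch][phase] = tifffile.imread(p)
        return cls(images, config)


def simulate_occupancy(config: SimulationConfig) -> SimulationTruth:
    """Draw fill status and per-channel copy counts for every partition.

    Fill ~ Bernoulli(1 − fill_failure_rate); copies | filled ~ Poisson(λ_c)
    independently per channel; unfilled partitions carry zero copies.
    """
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0])
    n = config.geometry.n_partitions
    layout = config.layout
    rows, cols = layout.grid_indices()
    filled = rng.random(n) >= config.fill_failure_rate
    copies = {}
    for ch in config.probe_channels:
        c = rng.poisson(config.mean_copies(ch), n)
        c[~filled] = 0
        copies[ch] = c
    return SimulationTruth(config.geometry, rows, cols, filled, copies)


def render_array_images(truth: SimulationTruth, config: SimulationConfig) -> ImageSet:
    """Render the pre/post image pair for ROX and every probe channel.

    Filled partitions appear as rectangular patches; ROX shows the loaded
    level in both phases, probe channels show the negative level pre-cycling
    and the positive level post-cycling only where ≥1 target copy is present.
    The whole frame is multiplied by the illumination field, Gaussian noise
    is added, and values are clipped to the bit-depth range.
    """
    layout = config.layout
    shape = layout.image_shape
    x0, y0 = layout.patch_origins()
    hx, hy = layout.patch_half
    if x0.min() < 0 or y0.min() < 0 or (x0 + 2 * hx + 1 > shape[1]).any() \
            or (y0 + 2 * hy + 1 > shape[0]).any():
        raise ConfigError("grid (with offset) exceeds image bounds")
    xs = x0[:, None] + np.arange(2 * hx + 1)
    ys = y0[:, None] + np.arange(2 * hy + 1)
    fld = config.illumination.render(shape)
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 1])
    vmax = float(2 ** config.image_bit_depth - 1)

    images: dict[str, dict[str, np.ndarray]] = {}
    for ch in (ROX,) + config.probe_channels:
        lv = config.levels[ch]
        images[ch] = {}
        for phase in PHASES:
            if ch == ROX:
                patch = np.where(truth.filled, lv.positive_mean, config.background)
            elif phase == "pre":
                patch = np.where(truth.filled, lv.negative_mean, config.background)
            else:
                patch = np.where(
                    truth.is_positive(ch), lv.positive_mean,
                    np.where(truth.filled, lv.negative_mean, config.background))
            img = np.full(shape, config.background)
            img[ys[:, :, None], xs[:, None, :]] = patch[:, None, None]
            img = img * fld + rng.normal(0.0, lv.noise_sd, shape)
            images[ch][phase] = np.clip(np.rint(img), 0, vmax).astype(np.uint16)
    return ImageSet(images, config)


def make_ntc_imageset(config: SimulationConfig) -> tuple[ImageSet, SimulationTruth]:
    """No-template control: the same render pipeline with all concentrations 0."""
    ntc_cfg = dataclasses.replace(
        config,
        channel_concentrations={ch: 0.0 for ch in config.channel_concentrations})
    truth = simulate_occupancy(ntc_cfg)
    return render_array_images(truth, ntc_cfg), truth


def partition_table_from_truth(truth: SimulationTruth) -> PartitionTable:
    """Idealized caller: a PartitionTable read straight off the ground truth.

    Used for statistical studies of the Poisson estimator where the imaging
    stage is not under test; deltas are 0/1 indicators, ROX means are the
    fill indicator.
    """
    channels = tuple(sorted(truth.copies))
    d = {"row": truth.row, "col": truth.col, "qc_pass": truth.filled,
         "rox_post_mean": truth.filled.astype(float)}
    for ch in channels:
        pos = truth.is_positive(ch)
        d[f"{ch}_delta"] = pos.astype(float)
        d[f"{ch}_call"] = pos
    return PartitionTable(pd.DataFrame(d), channels)
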