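"""From image sets to per-partition calls.

Pipeline: locate the fixed partition grid from the ROX reference-dye image
(FFT cross-correlation against the ideal grid template), estimate the
illumination field (degree-2 polynomial fit to loaded-partition ROX means),
extract illumination-corrected pre/post patch intensities, reject unloaded
partitions (no ROX signal), derive per-channel positivity thresholds from a
no-template control, and call positives on the post − pre delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import (ConfigError, EstimationError, GridNotFoundError,
                     InvalidInputError)
from .geometry import ArrayGeometry
from .layout import PixelLayout
from .simulate import ROX, ImageSet
from .table import PartitionTable


@dataclass(frozen=True)
class PartitionGrid:
    """Located partition grid: nominal layout plus the estimated offset.

    The layout offset is quantized to whole pixels so patch windows align
    exactly with the pixel raster; ``refined_offset`` keeps the sub-pixel
    estimate for diagnostics.
    """

    layout: PixelLayout
    correlation: float
    refined_offset: tuple[float, float] = (0.0, 0.0)

    @property
    def n(self) -> int:
        return self.layout.geometry.n_partitions

    @property
    def offset(self) -> tuple[float, float]:
        return self.layout.offset

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.layout.centers()


@dataclass(frozen=True)
class ChannelThreshold:
    """Positivity threshold for one probe channel, on the delta scale."""

    channel: str
    threshold: float
    source: str  # "NTC" or "manual"
    ntc_mean: float = float("nan")
    ntc_sd: float = float("nan")
    ntc_max: float = float("nan")
    ntc_n: int = 0


def _subpixel_peak(c_m1: float, c_0: float, c_p1: float) -> float:
    """Parabolic interpolation of a correlation peak; returns offset in (-1, 1)."""
    denom = 2.0 * (2.0 * c_0 - c_p1 - c_m1)
    if denom <= 0:
        return 0.0
    return float(np.clip((c_p1 - c_m1) / denom, -0.999, 0.999))


def locate_grid(rox_post: np.ndarray, geometry: ArrayGeometry, *,
                pixel_pitch: float = 10.0, margin_px: int = 20,
                min_correlation: float = 0.1) -> PartitionGrid:
    """Find the grid translation by circular FFT cross-correlation.

    The observed ROX post image is correlated against the ideal binary grid
    template at every integer offset; the peak gives the translation, refined
    to sub-pixel by parabolic interpolation.  A normalized peak below
    ``min_correlation`` (e.g. a blank image) raises :class:`GridNotFoundError`.
    """
    layout = PixelLayout(geometry, pixel_pitch, margin_px)
    if rox_post.shape != layout.image_shape:
        raise ConfigError(
            f"image shape {rox_post.shape} does not match the layout's "
            f"expected shape {layout.image_shape}")
    a = rox_post.astype(float) - float(np.mean(rox_post))
    t = layout.template()
    b = t - t.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    norm = np.linalg.norm(a) * np.linalg.norm(b)
    score = float(corr[peak] / norm) if norm > 0 else 0.0
    if score < min_correlation:
        raise GridNotFoundError(
            f"no partition grid found (correlation {score:.3f} < {min_correlation})")
    h, w = corr.shape
    dy, dx = peak
    dy = dy - h if dy > h // 2 else dy
    dx = dx - w if dx > w // 2 else dx
    ry = _subpixel_peak(corr[(peak[0] - 1) % h, peak[1]], corr[peak],
                        corr[(peak[0] + 1) % h, peak[1]])
    rx = _subpixel_peak(corr[peak[0], (peak[1] - 1) % w], corr[peak],
                        corr[peak[0], (peak[1] + 1) % w])
    located = replace(layout, offset=(float(round(dx + rx)), float(round(dy + ry))))
    # offset must keep every patch inside the frame
    x0, y0 = located.patch_origins()
    hx, hy = located.patch_half
    if x0.min() < 0 or y0.min() < 0 or (x0 + 2 * hx + 1 > w).any() \
            or (y0 + 2 * hy + 1 > h).any():
        raise GridNotFoundError("located grid extends beyond the image bounds")
    return PartitionGrid(located, score, (dx + rx, dy + ry))


def patch_means(img: np.ndarray, grid: PartitionGrid, *, trim: float = 0.1) -> np.ndarray:
    """Trimmed mean (central 1 − 2·trim of pixels) of every patch window."""
    layout = grid.layout
    hx, hy = layout.patch_half
    x0, y0 = layout.patch_origins()
    xs = x0[:, None] + np.arange(2 * hx + 1)
    ys = y0[:, None] + np.arange(2 * hy + 1)
    patches = img.astype(float)[ys[:, :, None], xs[:, None, :]].reshape(grid.n, -1)
    if trim <= 0:
        return patches.mean(axis=1)
    return stats.trim_mean(patches, trim, axis=1)


@dataclass(frozen=True)
class PolynomialIlluminationField:
    """Degree-2 polynomial estimate of the excitation field, unit mean over centres."""

    coeffs: np.ndarray  # for terms 1, x, y, x², xy, y² in normalized coords
    image_shape: tuple[int, int]

    def _design(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        h, w = self.image_shape
        xn = 2.0 * np.asarray(x, dtype=float) / (w - 1) - 1.0
        yn = 2.0 * np.asarray(y, dtype=float) / (h - 1) - 1.0
        return np.column_stack([np.ones_like(xn), xn, yn, xn ** 2, xn * yn, yn ** 2])

    def at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Field value at pixel coordinates (x, y)."""
        return self._design(x, y) @ self.coeffs

    def field_image(self) -> np.ndarray:
        h, w = self.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        return self.at(xx.ravel(), yy.ravel()).reshape(h, w)


def _two_class_split(vals: np.ndarray) -> tuple[float, bool]:
    """Two-class intensity split: Otsu initialization refined isodata-style.

    Iterating t → midpoint of the two class means is robust to the heavily
    unbalanced classes a 2% fill-failure rate produces.  Returns the
    threshold and whether the split is genuinely bimodal (class means
    separated by ≥ 4 × the summed within-class spreads).
    """
    try:
        t = float(threshold_otsu(vals))
    except ValueError:  # constant input
        return float(vals[0]) if len(vals) else float("nan"), False
    for _ in range(100):
        lo, hi = vals[vals < t], vals[vals >= t]
        if len(lo) == 0 or len(hi) == 0:
            return t, False
        t_new = float(lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < 1e-9:
            break
        t = t_new
    lo, hi = vals[vals < t], vals[vals >= t]
    if len(lo) == 0 or len(hi) == 0:
        return t, False
    bimodal = hi.mean() - lo.mean() >= 4.0 * (lo.std() + hi.std())
    return t, bool(bimodal)


def estimate_illumination(rox_post: np.ndarray, grid: PartitionGrid, *,
                          min_partitions: int = 100) -> PolynomialIlluminationField:
    """Fit a smooth multiplicative illumination field from loaded-partition ROX means.

    Loaded partitions are selected by a two-class split of the per-partition
    ROX means (all partitions are used if the split is degenerate), a
    degree-2 2-D polynomial is least-squares fitted to their means, and the
    field is normalized to unit mean over all partition centres.
    """
    means = patch_means(rox_post, grid)
    t, bimodal = _two_class_split(means)
    loaded = means >= t if bimodal else np.ones_like(means, dtype=bool)
    if loaded.sum() < min_partitions:
        raise EstimationError(
            f"only {int(loaded.sum())} loaded partitions; need >= {min_partitions} "
            "to estimate the illumination field")
    cx, cy = grid.centers()
    proto = PolynomialIlluminationField(np.zeros(6), rox_post.shape)
    design = proto._design(cx[loaded], cy[loaded])
    coeffs, *_ = np.linalg.lstsq(design, means[loaded], rcond=None)
    field = PolynomialIlluminationField(coeffs, rox_post.shape)
    scale = float(np.mean(field.at(cx, cy)))
    if scale <= 0:
        raise EstimationError("fitted illumination field is not positive")
    field = PolynomialIlluminationField(coeffs / scale, rox_post.shape)
    if np.min(field.at(cx, cy)) <= 0:
        raise EstimationError("fitted illumination field is not strictly positive")
    return field


def extract_partition_intensities(images: ImageSet, grid: PartitionGrid,
                                  field: PolynomialIlluminationField | None = None,
                                  ) -> pd.DataFrame:
    """Per-partition corrected pre/post means and probe-channel deltas.

    Patch statistic is the central-80% trimmed mean, divided by the
    illumination-field value at the patch centre.  Patches overlapping the
    image border are flagged ``qc_pass = False`` with reason ``border``.
    One record per grid position, always.
    """
    layout = grid.layout
    rows, cols = layout.grid_indices()
    cx, cy = grid.centers()
    f = field.at(cx, cy) if field is not None else np.ones(grid.n)
    hx, hy = layout.patch_half
    x0, y0 = layout.patch_origins()
    h, w = images.images[ROX]["post"].shape
    border = (x0 < 0) | (y0 < 0) | (x0 + 2 * hx + 1 > w) | (y0 + 2 * hy + 1 > h)
    if border.any():  # clamp so extraction stays in-bounds; flagged below
        x0 = np.clip(x0, 0, w - 2 * hx - 1)
        y0 = np.clip(y0, 0, h - 2 * hy - 1)

    out: dict[str, np.ndarray] = {"row": rows, "col": cols}
    for ch in images.channels:
        pre = patch_means(images.images[ch]["pre"], grid) / f
        post = patch_means(images.images[ch]["post"], grid) / f
        out[f"{ch}_pre"] = pre
        out[f"{ch}_post"] = post
        if ch != ROX:
            out[f"{ch}_delta"] = post - pre
    out["rox_post_mean"] = out[f"{ROX}_post"]
    out["qc_pass"] = ~border
    df = pd.DataFrame(out)
    df.attrs["qc_reason"] = np.where(border, "border", "")
    # background level: median of the ROX post image outside all patches
    mask = layout.patch_mask()
    df.attrs["rox_background"] = float(
        np.median(images.images[ROX]["post"][~mask]))
    return df


def qc_filter_rox(measurements: pd.DataFrame, *,
                  rox_threshold: float | None = None,
                  background: float | None = None,
                  background_multiple: float = 5.0) -> pd.DataFrame:
    """Reject partitions without a ROX signal (no analyzable reagent).

    The threshold is an Otsu two-class split of the corrected ROX post means;
    if the distribution is effectively unimodal (all loaded or all empty) the
    fall-back is ``background_multiple`` × the off-patch image background.
    Rejected partitions are excluded from all downstream counts.
    """
    df = measurements.copy()
    df.attrs.update(measurements.attrs)
    vals = df.loc[df["qc_pass"], "rox_post_mean"].to_numpy()
    if rox_threshold is None:
        rox_threshold = _rox_threshold(vals, background
                                       if background is not None
                                       else df.attrs.get("rox_background"),
                                       background_multiple)
    df["qc_pass"] = df["qc_pass"] & (df["rox_post_mean"] >= rox_threshold)
    df.attrs["rox_threshold"] = float(rox_threshold)
    return df


def _rox_threshold(vals: np.ndarray, background: float | None,
                   background_multiple: float) -> float:
    if len(vals) == 0:
        raise InvalidInputError("no partitions to threshold")
    t, bimodal = _two_class_split(vals)
    if bimodal:
        # converged isodata threshold is the midpoint of the two class means
        return t
    if background is None:
        raise InvalidInputError(
            "ROX distribution is unimodal and no background level is available")
    warnings.warn("ROX distribution unimodal; falling back to "
                  f"{background_multiple}x image background", stacklevel=2)
    return float(background_multiple * background)


def derive_threshold_ntc(ntc_measurements: pd.DataFrame, channel: str, *,
                         n_sd: float = 5.0, min_valid: int = 1000,
                         ) -> ChannelThreshold:
    """Positivity threshold from the no-template control: mean + n_sd · sd.

    Computed over the deltas of QC-passing NTC partitions.  An NTC partition
    exceeding mean + 2·n_sd·sd triggers a contamination warning.
    """
    col = f"{channel}_delta"
    if col not in ntc_measurements.columns:
        raise ConfigError(f"NTC measurements carry no channel {channel!r}")
    deltas = ntc_measurements.loc[ntc_measurements["qc_pass"], col].to_numpy()
    if len(deltas) < min_valid:
        raise InvalidInputError(
            f"only {len(deltas)} QC-passing NTC partitions; need >= {min_valid}")
    mean, sd, mx = float(deltas.mean()), float(deltas.std()), float(deltas.max())
    if mx > mean + 2 * n_sd * sd:
        warnings.warn(f"possible NTC contamination in {channel}: max delta "
                      f"{mx:.1f} exceeds mean + {2 * n_sd:.0f} sd", stacklevel=2)
    return ChannelThreshold(channel, mean + n_sd * sd, "NTC",
                            mean, sd, mx, len(deltas))


def call_partitions(measurements: pd.DataFrame,
                    thresholds: dict[str, ChannelThreshold]) -> PartitionTable:
    """Call positives: qc_pass AND delta > threshold, per probe channel."""
    channels = tuple(sorted(
        c[: -len("_delta")] for c in measurements.columns if c.endswith("_delta")))
    missing = [ch for ch in channels if ch not in thresholds]
    if missing:
        raise ConfigError(f"no threshold for channel(s) {missing}")
    d = {"row": measurements["row"], "col": measurements["col"],
         "qc_pass": measurements["qc_pass"],
         "rox_post_mean": measurements["rox_post_mean"]}
    for ch in channels:
        delta = measurements[f"{ch}_delta"]
        d[f"{ch}_delta"] = delta
        d[f"{ch}_call"] = measurements["qc_pass"] & (delta > thresholds[ch].threshold)
    return PartitionTable(pd.DataFrame(d), channels)
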