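"""Plot-image containers, multi-band TIFF I/O and the preprocessing chain.

A *plot image* is the small multispectral chip covering one experimental
plot (nominally 11 x 22 pixels x 6 bands at 30 cm ground resolution).
Preprocessing before representation learning is: per-channel outlier
clipping at ``mean +/- k*sd``, per-channel min-max scaling into [0, 1],
then flattening each chip into a single feature vector.

Statistics are pooled over the whole dataset per channel by default (all
plots of one timepoint), because per-image scaling would destroy
cross-plot comparability; a per-image mode is available via
``per_image=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Canonical band order of the 6-band product.
BAND_NAMES: tuple[str, ...] = ("Red", "Green", "Blue", "NIR", "RedEdge", "DeepBlue")

#: Default chip shape (width, height, channels).
DEFAULT_SHAPE: tuple[int, int, int] = (11, 22, 6)

#: Dynamic range of the 12-bit sensor counts.
MAX_DN = 4095


@dataclass
class PlotImage:
    """One plot's reflectance chip plus its identity metadata.

    ``pixels`` is a ``(W, H, C)`` float array; values are finite and
    nonnegative (raw sensor counts or normalized reflectance).
    """

    pixels: np.ndarray
    plot_id: str
    genotype_id: str = ""
    environment_id: str = ""
    replicate_id: int = 0
    timepoint: str = "TP1"
    resolution_m: float = 0.3

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (W, H, C), got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 1:
            raise ValueError("all image dimensions must be >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"non-finite pixel values in plot {self.plot_id!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel summary statistics over a stated pixel population.

    ``sd`` uses the population convention (divide by n); this is recorded
    in ``ddof`` so downstream oracles can match the convention exactly.
    """

    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_pixels: int
    ddof: int = 0
    scope: str = "dataset"  # "dataset" (pooled) or "image"

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be nonnegative")
        if np.any(self.min > self.max):
            raise ValueError("channel min must not exceed channel max")

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]


def compute_channel_stats(images: Sequence[PlotImage], ddof: int = 0) -> ChannelStats:
    """Pool all pixels of all plots and compute per-channel mean/sd/min/max.

    The result is independent of image ordering.
    """
    images = list(images)
    if not images:
        raise ValueError("cannot compute channel statistics of an empty dataset")
    n_channels = images[0].n_channels
    for im in images:
        if im.n_channels != n_channels:
            raise ValueError(
                f"inconsistent channel count: {im.n_channels} in plot "
                f"{im.plot_id!r}, expected {n_channels}"
            )
    pooled = np.concatenate([im.pixels.reshape(-1, n_channels) for im in images], axis=0)
    return ChannelStats(
        mean=pooled.mean(axis=0),
        sd=pooled.std(axis=0, ddof=ddof),
        min=pooled.min(axis=0),
        max=pooled.max(axis=0),
        n_pixels=pooled.shape[0],
        ddof=ddof,
        scope="dataset",
    )


def clip_outliers(
    images: Sequence[PlotImage],
    stats: ChannelStats | None = None,
    k: float = 3.0,
    per_image: bool = False,
) -> list[PlotImage]:
    """Clip every pixel into ``mean_c +/- k * sd_c`` per channel.

    With ``per_image=True`` each image is clipped against its own
    statistics instead of the pooled dataset statistics.
    """
    if k <= 0:
        raise ValueError(f"clipping width k must be positive, got {k}")
    images = list(images)
    if per_image:
        return [clip_outliers([im], k=k)[0] for im in images]
    if stats is None:
        stats = compute_channel_stats(images)
    lo = stats.mean - k * stats.sd
    hi = stats.mean + k * stats.sd
    return [replace(im, pixels=np.clip(im.pixels, lo, hi)) for im in images]


def minmax_normalize(
    images: Sequence[PlotImage],
    stats: ChannelStats | None = None,
    per_image: bool = False,
) -> list[PlotImage]:
    """Scale each channel to [0, 1] via ``(x - min_c) / (max_c - min_c)``.

    ``stats`` must be recomputed *after* clipping. A constant channel
    (``max == min``) maps to all zeros.
    """
    images = list(images)
    if per_image:
        return [minmax_normalize([im])[0] for im in images]
    if stats is None:
        stats = compute_channel_stats(images)
    span = stats.max - stats.min
    safe_span = np.where(span > 0, span, 1.0)
    out = []
    for im in images:
        scaled = (im.pixels - stats.min) / safe_span
        scaled[..., span == 0] = 0.0
        out.append(replace(im, pixels=scaled))
    return out


def preprocess(
    images: Sequence[PlotImage], k: float = 3.0, per_image: bool = False
) -> tuple[list[PlotImage], ChannelStats, ChannelStats]:
    """Full chain: clip at ``k`` sd, then min-max normalize with re-estimated stats.

    Returns ``(normalized images, pre-clip stats, post-clip stats)``.
    """
    pre_stats = compute_channel_stats(list(images))
    clipped = clip_outliers(images, stats=None if per_image else pre_stats, k=k, per_image=per_image)
    post_stats = compute_channel_stats(clipped)
    normalized = minmax_normalize(clipped, stats=None if per_image else post_stats, per_image=per_image)
    return normalized, pre_stats, post_stats


def flatten(image: PlotImage) -> np.ndarray:
    """Flatten a ``(W, H, C)`` chip to a length ``W*H*C`` vector.

    The order is row-major over (W, H, C) with the channel axis varying
    fastest; it is fixed so that vectors are stable across save/load and
    :func:`unflatten` inverts it exactly.
    """
    return image.pixels.ravel(order="C")


def unflatten(vector: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`flatten` for a known chip shape."""
    vector = np.asarray(vector)
    expected = int(np.prod(shape))
    if vector.size != expected:
        raise ValueError(f"vector of length {vector.size} cannot fill shape {shape}")
    return vector.reshape(shape, order="C")


def feature_matrix(images: Sequence[PlotImage]) -> np.ndarray:
    """Stack flattened images into an ``(n_images, W*H*C)`` matrix."""
    return np.stack([flatten(im) for im in images], axis=0)


# ---------------------------------------------------------------------------
# Multi-band TIFF I/O
# ---------------------------------------------------------------------------

def write_plot_geotiff(image: PlotImage, path: str | Path) -> Path:
    """Write one plot as a multi-band unsigned 16-bit TIFF.

    Bands are stored pixel-interleaved in the canonical order
    (Red, Green, Blue, NIR, RedEdge, DeepBlue for 6-band data); the plot
    metadata and band names go into the TIFF description tag as JSON so a
    file round-trips without a sidecar table.
    """
    path = Path(path)
    arr = image.pixels
    if np.any(arr < 0) or np.any(arr > np.iinfo(np.uint16).max):
        raise ValueError("pixel values outside the uint16 range cannot be written")
    # TIFF rows are the image height: store as (H, W, C)
    data = np.round(arr).astype(np.uint16).transpose(1, 0, 2)
    meta = {
        "plot_id": image.plot_id,
        "genotype_id": image.genotype_id,
        "environment_id": image.environment_id,
        "replicate_id": image.replicate_id,
        "timepoint": image.timepoint,
        "resolution_m": image.resolution_m,
        "band_names": list(BAND_NAMES[: image.n_channels])
        if image.n_channels <= len(BAND_NAMES)
        else [f"band{i + 1}" for i in range(image.n_channels)],
    }
    tifffile.imwrite(path, data, photometric="minisblack", planarconfig="contig",
                     description=json.dumps(meta))
    return path


def read_plot_geotiff(path: str | Path, expected_channels: int | None = None) -> PlotImage:
    """Read a multi-band TIFF written by :func:`write_plot_geotiff`.

    Raises ``ValueError`` when the band count does not match
    ``expected_channels``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout in {path}: shape {data.shape}")
    n_bands = data.shape[2]
    if expected_channels is not None and n_bands != expected_channels:
        raise ValueError(
            f"{path} has {n_bands} bands, expected {expected_channels}"
        )
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    return PlotImage(
        pixels=data.transpose(1, 0, 2).astype(float),
        plot_id=str(meta.get("plot_id", path.stem)),
        genotype_id=str(meta.get("genotype_id", "")),
        environment_id=str(meta.get("environment_id", "")),
        replicate_id=int(meta.get("replicate_id", 0)),
        timepoint=str(meta.get("timepoint", "TP1")),
        resolution_m=float(meta.get("resolution_m", 0.3)),
    )


def attach_metadata(images: Iterable[PlotImage], table: pd.DataFrame) -> list[PlotImage]:
    """Join a metadata table (keyed by ``plot_id``) onto images.

    Every image must have a matching row; unmatched plot_ids are reported
    in the raised error.
    """
    if "plot_id" not in table.columns:
        raise ValueError("metadata table must have a 'plot_id' column")
    indexed = table.set_index("plot_id")
    out, missing = [], []
    for im in images:
        if im.plot_id not in indexed.index:
            missing.append(im.plot_id)
            continue
        row = indexed.loc[im.plot_id]
        out.append(
            replace(
                im,
                genotype_id=str(row["genotype_id"]),
                environment_id=str(row["environment_id"]),
                replicate_id=int(row["replicate_id"]),
                timepoint=str(row.get("timepoint", im.timepoint)),
            )
        )
    if missing:
        raise ValueError(f"metadata rows missing for plot_ids: {missing}")
    return out
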