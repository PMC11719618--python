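"""Whole-colony filamentation measurement pipeline.

Six deterministic stages turn one colony photomicrograph into the
filamentation index *f*:

1. ``standardize``      — resample to a fixed working resolution
                          (default 2560 x 1920), aspect-preserving with
                          background padding;
2. ``to_gray``          — Rec.601 luminance (0.299 R + 0.587 G + 0.114 B);
3. ``blur``             — Gaussian smoothing, 5 x 5 kernel by default;
4. ``binarize``         — manual or Otsu threshold, colony = foreground;
5. ``fill_voids``       — close enclosed background pockets left by
                          overlapping/merging filaments;
6. ``extract_contours`` — outer boundary (colony mass + all filamentous
                          protrusions, area A_outer) and inner boundary
                          (central mass isolated by morphological opening,
                          area A_inner).

The index is f = (A_outer - A_inner) / A_inner, a dimensionless fraction:
0 for a perfectly round colony, ~2 for strong pseudohyphal halos.

``FilamentationQuantifier`` wraps the chain as a scikit-learn style
stateless transformer so batches of images compose with sklearn tooling;
the module-level functions are the underlying stages.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage import transform as _sktransform
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RasterImage",
    "GrayImage",
    "BinaryMask",
    "ContourMeasurement",
    "FMeasureRecord",
    "PipelineConfig",
    "FilamentationQuantifier",
    "SegmentationError",
    "PipelineStageError",
    "standardize",
    "to_gray",
    "blur",
    "binarize",
    "fill_voids",
    "extract_contours",
    "f_measure",
    "process_image",
    "polygon_area",
    "read_image",
]

#: physical pixel pitch of the reference imaging setup, micrometres per pixel
DEFAULT_PIXEL_PITCH_UM = 2.2

#: standardized working resolution, (width, height) in pixels
DEFAULT_RESOLUTION = (2560, 1920)


class SegmentationError(ValueError):
    """Raised when a stage produces an unusable segmentation (empty or
    full-frame foreground, opening that erases the colony, ...)."""


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name and colony id."""

    def __init__(self, stage: str, colony_id: str | None, cause: Exception):
        self.stage = stage
        self.colony_id = colony_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for colony {colony_id!r}: {cause}")


# ---------------------------------------------------------------------------
# raster containers
# ---------------------------------------------------------------------------


@dataclass
class RasterImage:
    """A 3-channel 8-bit raster with an explicit channel-order tag.

    The channel order is recorded, never assumed: a silent BGR/RGB swap
    changes the grayscale conversion and therefore the threshold.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    channel_order: str  # "BGR" | "RGB"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if self.channel_order not in ("BGR", "RGB"):
            raise ValueError(f"unknown channel_order {self.channel_order!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_gray_array(cls, gray: np.ndarray, channel_order: str = "RGB") -> "RasterImage":
        g = np.asarray(gray, dtype=np.uint8)
        return cls(np.repeat(g[:, :, None], 3, axis=2), channel_order)


@dataclass
class GrayImage:
    pixels: np.ndarray  # H x W, uint8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected H x W gray pixels, got shape {self.pixels.shape}")


@dataclass
class BinaryMask:
    """Boolean foreground mask plus the threshold that produced it."""

    pixels: np.ndarray  # H x W, bool
    threshold_used: float
    polarity: str = "foreground-bright"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ContourMeasurement:
    """Paired boundary measurements for one colony.

    ``a_outer`` encloses the colony mass plus every filamentous protrusion;
    ``a_inner`` encloses the central mass only. Areas are filled-pixel
    counts (px^2); the polygons are the sub-pixel traced boundaries and
    agree with the counts to within discretization error.
    """

    outer_polygon: np.ndarray  # (n, 2) array of (x, y)
    inner_polygon: np.ndarray
    a_outer: float  # px^2
    a_inner: float  # px^2
    a_outer_um2: float | None = None
    a_inner_um2: float | None = None
    multi_colony_flag: bool = False

    def __post_init__(self):
        if self.a_inner <= 0:
            raise ValueError("a_inner must be positive for an accepted colony")
        if self.a_outer < self.a_inner:
            raise ValueError("a_outer must be >= a_inner")


@dataclass
class FMeasureRecord:
    colony_id: str
    strain: str
    compound: str
    concentration_uM: float
    f: float
    threshold_used: float | None = None
    a_inner_px2: float | None = None
    a_outer_px2: float | None = None
    a_inner_um2: float | None = None
    a_outer_um2: float | None = None

    def __post_init__(self):
        if self.f < 0:
            raise ValueError("f must be non-negative")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunable parameters of the measurement chain.

    ``threshold`` is an intensity in [0, 255] or ``"auto"`` (Otsu);
    ``opening_radius_px`` is the disc radius used to strip protrusions when
    isolating the central mass — protrusions thinner than about twice this
    radius are removed. ``max_void_px`` caps the size of enclosed background
    pockets that get filled (``None`` = unlimited). ``pixel_pitch_um``
    converts px^2 areas to um^2 when given.
    """

    resolution: tuple[int, int] = DEFAULT_RESOLUTION  # (width, height)
    gaussian_kernel: int = 5
    gaussian_sigma: float = 1.1
    threshold: float | str = "auto"
    polarity: str = "foreground-bright"
    max_void_px: float | None = None
    opening_radius_px: float = 8.0
    pixel_pitch_um: float | None = None

    def validate(self) -> "PipelineConfig":
        if self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd")
        if self.threshold != "auto" and not (0 <= float(self.threshold) <= 255):
            raise ValueError("threshold must be 'auto' or in [0, 255]")
        if self.polarity not in ("foreground-bright", "foreground-dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")
        w, h = self.resolution
        if w < 1 or h < 1:
            raise ValueError("resolution must be positive")
        return self

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution"] = list(self.resolution)
        return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def standardize(image: RasterImage, resolution: tuple[int, int] = DEFAULT_RESOLUTION) -> RasterImage:
    """Resample to the fixed working resolution, preserving aspect ratio.

    The image is scaled to fit inside ``resolution`` (width, height) and
    centred on a border padded with the image's own background level
    (median intensity of the one-pixel frame), so that anisotropic stretch
    cannot bias the area ratio. Already-conforming images pass through
    unchanged. Downscaling uses anti-aliased resampling; upscaling is
    bilinear, which keeps thin filaments from aliasing away.
    """
    tw, th = int(resolution[0]), int(resolution[1])
    h, w = image.pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("zero-sized input image")
    if (w, h) == (tw, th):
        return image

    scale = min(tw / w, th / h)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    anti_alias = scale < 1.0
    resized = _sktransform.resize(
        image.pixels.astype(float),
        (nh, nw, 3),
        order=1,
        anti_aliasing=anti_alias,
        preserve_range=True,
        mode="edge",
    )
    resized = np.clip(np.rint(resized), 0, 255).astype(np.uint8)

    frame = np.concatenate(
        [
            image.pixels[0, :, :].reshape(-1, 3),
            image.pixels[-1, :, :].reshape(-1, 3),
            image.pixels[:, 0, :].reshape(-1, 3),
            image.pixels[:, -1, :].reshape(-1, 3),
        ]
    )
    pad_value = np.median(frame, axis=0).astype(np.uint8)

    out = np.empty((th, tw, 3), dtype=np.uint8)
    out[:, :] = pad_value
    oy, ox = (th - nh) // 2, (tw - nw) // 2
    out[oy : oy + nh, ox : ox + nw] = resized

    meta = dict(image.meta)
    meta["standardize"] = {
        "scale": scale,
        "pad_value": [int(v) for v in pad_value],
        "offset_xy": [ox, oy],
        "resized_wh": [nw, nh],
        "source_wh": [w, h],
    }
    return RasterImage(out, image.channel_order, meta)


def to_gray(image: RasterImage) -> GrayImage:
    """Rec.601 luminance conversion, honouring the recorded channel order.

    y = 0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer.
    """
    if image.channel_order == "RGB":
        r, g, b = (image.pixels[:, :, i].astype(float) for i in range(3))
    elif image.channel_order == "BGR":
        b, g, r = (image.pixels[:, :, i].astype(float) for i in range(3))
    else:  # pragma: no cover - blocked by RasterImage validation
        raise ValueError(f"unknown channel_order {image.channel_order!r}")
    y = 0.299 * r + 0.587 * g + 0.114 * b
    return GrayImage(np.clip(np.rint(y), 0, 255).astype(np.uint8), dict(image.meta))


def _gaussian_kernel_1d(ksize: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        k = np.zeros(ksize)
        k[ksize // 2] = 1.0
        return k
    x = np.arange(ksize, dtype=float) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def blur(image: GrayImage, kernel: int = 5, sigma: float = 1.1) -> GrayImage:
    """Gaussian smoothing with a normalized square kernel.

    Borders are handled by edge replication, so a constant image maps to
    itself and mean intensity is preserved up to integer rounding.
    ``sigma <= 0`` degenerates to the identity (delta kernel).
    """
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel size must be odd and positive")
    k1 = _gaussian_kernel_1d(kernel, sigma)
    smoothed = image.pixels.astype(float)
    smoothed = ndimage.correlate1d(smoothed, k1, axis=0, mode="nearest")
    smoothed = ndimage.correlate1d(smoothed, k1, axis=1, mode="nearest")
    return GrayImage(np.clip(np.rint(smoothed), 0, 255).astype(np.uint8), dict(image.meta))


def _otsu_threshold(gray: np.ndarray) -> float:
    """Otsu's threshold by exhaustive scan of all 256 integer cuts.

    Maximizes the between-class variance w0*w1*(mu0 - mu1)^2 over cuts
    t (foreground = intensity > t). Bimodal images yield a plateau of
    equally good cuts between the modes; the plateau midpoint is returned
    so the recorded threshold sits between the class levels rather than on
    one of them.
    """
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    n = hist.sum()
    cum_n = np.cumsum(hist)
    cum_x = np.cumsum(hist * np.arange(256))
    w0 = cum_n[:-1]
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        # constant image: any cut gives an empty or full mask; let the
        # caller's empty/full check raise the segmentation failure
        return 127.5
    mu0 = np.where(valid, cum_x[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(valid, (cum_x[-1] - cum_x[:-1]) / np.maximum(w1, 1), 0.0)
    var_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = np.flatnonzero(var_b == var_b.max())
    return float(best.mean())


def binarize(
    image: GrayImage,
    threshold: float | str = "auto",
    polarity: str = "foreground-bright",
) -> BinaryMask:
    """Threshold to a colony-foreground mask.

    Manual mode takes an intensity in [0, 255]; ``"auto"`` selects the
    threshold by Otsu's between-class-variance criterion and records the
    chosen value. An empty or full-frame foreground is a segmentation
    failure, the batch analogue of rejecting an unusable photograph.
    """
    if polarity not in ("foreground-bright", "foreground-dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if threshold == "auto":
        t = _otsu_threshold(image.pixels)
    else:
        t = float(threshold)
        if not (0 <= t <= 255):
            raise ValueError("threshold must be in [0, 255]")
    if polarity == "foreground-bright":
        mask = image.pixels > t
    else:
        mask = image.pixels < t
    n = int(mask.sum())
    if n == 0:
        raise SegmentationError(f"empty foreground at threshold {t}")
    if n == mask.size:
        raise SegmentationError(f"full-frame foreground at threshold {t}")
    return BinaryMask(mask, threshold_used=t, polarity=polarity)


def _fill_voids_array(mask: np.ndarray, max_void_px: float | None = None) -> np.ndarray:
    bg_labels, n_bg = ndimage.label(~mask)
    if n_bg == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(bg_labels[border & (bg_labels > 0)])
    sizes = np.bincount(bg_labels.ravel(), minlength=n_bg + 1)
    fill_ids = [
        i
        for i in range(1, n_bg + 1)
        if i not in border_ids and (max_void_px is None or sizes[i] <= max_void_px)
    ]
    out = mask.copy()
    if fill_ids:
        out[np.isin(bg_labels, fill_ids)] = True
    return out


def fill_voids(mask: BinaryMask, max_void_px: float | None = None) -> BinaryMask:
    """Fill enclosed background pockets up to ``max_void_px`` in area.

    Only background components that do not touch the image border are
    candidates (border-connected background is agar). Foreground never
    shrinks, and the operation is idempotent.
    """
    filled = _fill_voids_array(mask.pixels, max_void_px)
    return BinaryMask(filled, mask.threshold_used, mask.polarity)


def _binary_opening_disc(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological opening with an exact Euclidean disc of ``radius``.

    Implemented through two distance transforms (erosion: keep pixels whose
    distance to background exceeds the radius; dilation: reclaim pixels
    within the radius of the eroded set), equivalent to a disc structuring
    element but fast on multi-megapixel masks.
    """
    if radius <= 0:
        return mask.copy()
    eroded = ndimage.distance_transform_edt(mask) > radius
    if not eroded.any():
        return eroded
    opened = ndimage.distance_transform_edt(~eroded) <= radius
    return opened & mask  # opening is anti-extensive


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (x, y) vertices."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of a mask, as (x, y) vertices."""
    padded = np.pad(mask.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    best = max(contours, key=lambda c: polygon_area(c[:, ::-1]))
    return best[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding


def extract_contours(
    mask: BinaryMask,
    opening_radius: float = 8.0,
    max_void_px: float | None = None,
    pixel_pitch_um: float | None = None,
) -> ContourMeasurement:
    """Measure the outer and inner colony boundaries from a binary mask.

    The largest foreground component is taken as the colony; if a second
    component of comparable size is present (likely a neighbouring colony)
    a warning is raised and the measurement is flagged for manual review.
    The outer boundary encloses the void-filled colony component
    (area ``a_outer``); the inner boundary encloses the central mass
    obtained by opening with a disc of ``opening_radius``, which strips
    protrusions thinner than about twice that radius (area ``a_inner``).
    ``opening_radius = 0`` degenerates to inner == outer, i.e. f = 0.
    """
    labels, n_comp = ndimage.label(mask.pixels)
    if n_comp == 0:
        raise SegmentationError("no foreground component in mask")
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    colony = labels == (order[0] + 1)
    multi_flag = False
    if n_comp > 1 and sizes[order[1]] >= 0.5 * sizes[order[0]]:
        multi_flag = True
        warnings.warn(
            "multiple comparable-size components; keeping the largest "
            "(image flagged for manual review)",
            stacklevel=2,
        )

    outer_mask = _fill_voids_array(colony, max_void_px)
    a_outer = float(outer_mask.sum())

    if opening_radius <= 0:
        inner_mask = outer_mask
    else:
        opened = _binary_opening_disc(outer_mask, opening_radius)
        if not opened.any():
            raise SegmentationError(
                f"opening radius {opening_radius} erased the colony entirely"
            )
        in_labels, n_in = ndimage.label(opened)
        if n_in > 1:
            in_sizes = np.bincount(in_labels.ravel())[1:]
            opened = in_labels == (int(np.argmax(in_sizes)) + 1)
        inner_mask = _fill_voids_array(opened, None)
    a_inner = float(inner_mask.sum())

    pitch2 = pixel_pitch_um**2 if pixel_pitch_um else None
    return ContourMeasurement(
        outer_polygon=_trace_boundary(outer_mask),
        inner_polygon=_trace_boundary(inner_mask),
        a_outer=a_outer,
        a_inner=a_inner,
        a_outer_um2=a_outer * pitch2 if pitch2 else None,
        a_inner_um2=a_inner * pitch2 if pitch2 else None,
        multi_colony_flag=multi_flag,
    )


def f_measure(measurement: ContourMeasurement) -> float:
    """Filamentation index f = (A_outer - A_inner) / A_inner.

    A dimensionless fraction: the relative excess of the
    protrusion-encompassing boundary area over the central-mass area.
    Multiply by 100 for a percent-change reading.
    """
    if measurement.a_inner <= 0:
        raise ValueError("a_inner must be positive (no central mass found)")
    return (measurement.a_outer - measurement.a_inner) / measurement.a_inner


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> RasterImage:
    """Load a JPEG/PNG from disk as an RGB raster."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RasterImage(arr.astype(np.uint8), "RGB", {"path": str(path)})


def process_image(
    image: RasterImage | str | Path,
    config: PipelineConfig | None = None,
    colony_id: str = "",
    strain: str = "",
    compound: str = "",
    concentration_uM: float = float("nan"),
    return_intermediates: bool = False,
):
    """Run the full chain on one image and return its ``FMeasureRecord``.

    Deterministic for a fixed config; any stage failure is re-raised as a
    ``PipelineStageError`` carrying the stage name and colony id. With
    ``return_intermediates=True`` a dict of every intermediate stage output
    is returned alongside the record, for QC.
    """
    cfg = (config or PipelineConfig()).validate()
    stage = "load"
    try:
        if not isinstance(image, RasterImage):
            image = read_image(image)
        stage = "standardize"
        std = standardize(image, cfg.resolution)
        stage = "to_gray"
        gray = to_gray(std)
        stage = "blur"
        smoothed = blur(gray, cfg.gaussian_kernel, cfg.gaussian_sigma)
        stage = "binarize"
        mask = binarize(smoothed, cfg.threshold, cfg.polarity)
        stage = "fill_voids"
        filled = fill_voids(mask, cfg.max_void_px)
        stage = "extract_contours"
        meas = extract_contours(
            filled,
            opening_radius=cfg.opening_radius_px,
            max_void_px=cfg.max_void_px,
            pixel_pitch_um=cfg.pixel_pitch_um,
        )
        stage = "f_measure"
        f = f_measure(meas)
    except Exception as exc:
        raise PipelineStageError(stage, colony_id or None, exc) from exc

    record = FMeasureRecord(
        colony_id=colony_id,
        strain=strain,
        compound=compound,
        concentration_uM=concentration_uM,
        f=f,
        threshold_used=filled.threshold_used,
        a_inner_px2=meas.a_inner,
        a_outer_px2=meas.a_outer,
        a_inner_um2=meas.a_inner_um2,
        a_outer_um2=meas.a_outer_um2,
    )
    if return_intermediates:
        return record, {
            "standardized": std,
            "gray": gray,
            "blurred": smoothed,
            "mask": mask,
            "filled": filled,
            "measurement": meas,
        }
    return record


class FilamentationQuantifier(BaseEstimator, TransformerMixin):
    """Stateless transformer: colony images in, f-measure table out.

    Parameters mirror :class:`PipelineConfig`. ``transform`` accepts an
    iterable of images (``RasterImage``, H x W x 3 arrays, or file paths)
    and returns a DataFrame with one row per colony: the measured areas,
    the threshold actually used, and f. Being stateless, ``fit`` only
    validates the configuration.
    """

    def __init__(
        self,
        resolution: tuple[int, int] = DEFAULT_RESOLUTION,
        gaussian_kernel: int = 5,
        gaussian_sigma: float = 1.1,
        threshold: float | str = "auto",
        polarity: str = "foreground-bright",
        max_void_px: float | None = None,
        opening_radius_px: float = 8.0,
        pixel_pitch_um: float | None = None,
    ):
        self.resolution = resolution
        self.gaussian_kernel = gaussian_kernel
        self.gaussian_sigma = gaussian_sigma
        self.threshold = threshold
        self.polarity = polarity
        self.max_void_px = max_void_px
        self.opening_radius_px = opening_radius_px
        self.pixel_pitch_um = pixel_pitch_um

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            resolution=tuple(self.resolution),
            gaussian_kernel=self.gaussian_kernel,
            gaussian_sigma=self.gaussian_sigma,
            threshold=self.threshold,
            polarity=self.polarity,
            max_void_px=self.max_void_px,
            opening_radius_px=self.opening_radius_px,
            pixel_pitch_um=self.pixel_pitch_um,
        ).validate()

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X: Iterable, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        rows = []
        for i, item in enumerate(X):
            if isinstance(item, np.ndarray) and item.ndim == 3:
                item = RasterImage(item, "RGB")
            meta = {}
            if metadata is not None:
                meta = metadata.iloc[i].to_dict()
            rec = process_image(
                item,
                self.config_,
                colony_id=str(meta.get("colony_id", i)),
                strain=str(meta.get("strain", "")),
                compound=str(meta.get("compound", "")),
                concentration_uM=float(meta.get("concentration_uM", np.nan)),
            )
            rows.append(dataclasses.asdict(rec))
        return pd.DataFrame(rows)
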