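"""Synthetic colony images and simulated f-measure samples.

Two generators make the whole measurement chain testable without real
photographs:

* :func:`render_colony` draws an idealized whole-colony image — a bright
  filled disc (the central colony mass) with thin straight radial
  rectangles (pseudohyphal filaments) on a darker agar background, plus
  optional additive Gaussian pixel noise — and returns the analytically
  known ground truth: the disc area ``a_inner_true``, the area enclosed by
  the external boundary of disc ∪ filaments ``a_outer_true`` (enclosed
  voids between filaments count only when fully surrounded by foreground,
  matching the pipeline's hole-filling step), and the true index
  ``f_true = (a_outer_true - a_inner_true) / a_inner_true``.

* :func:`simulate_fmeasures` draws per-group f-measure samples from a
  positive-support family (lognormal by default — SDs in filamentation
  assays scale with the means and f >= 0 — with gamma and truncated-normal
  alternatives) moment-matched to target (mean, sd), optionally salted
  with multiplicative outliers.

``default_designs`` carries the dose designs of the reference
*Dekkera* filamentation study (strain x compound panels dosed at
0/10/50/100/200 µM of 2-phenylethanol or tryptophol, with the published
post-exclusion group sizes, means and SDs), so simulations reproduce the
statistical structure of that experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .pipeline import RasterImage

__all__ = [
    "Filament",
    "ColonySpec",
    "GroundTruth",
    "DoseGroup",
    "DoseDesign",
    "render_colony",
    "simulate_fmeasures",
    "random_colony_specs",
    "generate_image_dataset",
    "default_designs",
    "parse_design_file",
]


@dataclass(frozen=True)
class Filament:
    """One straight radial filament.

    ``length`` is the protrusion beyond the colony disc; ``start_radius``
    is the radial position of the inner end (defaults to just inside the
    disc boundary so the filament is attached).
    """

    angle: float  # radians
    length: float  # px beyond the disc boundary
    width: float  # px
    start_radius: float | None = None


@dataclass
class ColonySpec:
    """Geometry and photometry of one synthetic colony image."""

    image_width: int = 640
    image_height: int = 480
    center: tuple[float, float] | None = None  # (x, y); default image centre
    inner_radius: float = 100.0
    filaments: Sequence[Filament] = field(default_factory=tuple)
    foreground_level: int = 200
    background_level: int = 60
    noise_sd: float = 0.0
    seed: int = 0
    inverted: bool = False  # render dark colony on bright agar

    def __post_init__(self):
        if self.center is None:
            self.center = (self.image_width / 2.0, self.image_height / 2.0)
        self.validate()

    def validate(self) -> "ColonySpec":
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be positive")
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be positive")
        if not (0 <= self.background_level < self.foreground_level <= 255):
            raise ValueError(
                "need 0 <= background_level < foreground_level <= 255 "
                "(colony brighter than agar; use inverted=True to flip rendering)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for fl in self.filaments:
            if fl.width < 1 or fl.width >= self.inner_radius:
                raise ValueError("filament width must be >= 1 px and < inner_radius")
            if fl.length < 0:
                raise ValueError("filament length must be >= 0")
            start = fl.start_radius
            if start is not None and start > self.inner_radius:
                raise ValueError(
                    "filament detached from disc: its inner end lies outside "
                    "the disc boundary (single-colony ground truth undefined)"
                )
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Exact pixel-count areas of the noiseless rendered mask."""

    a_inner_true: int  # px^2
    a_outer_true: int  # px^2
    f_true: float

    def __post_init__(self):
        if self.a_outer_true < self.a_inner_true:
            raise ValueError("a_outer_true must be >= a_inner_true")


def _disc_mask(spec: ColonySpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    cx, cy = spec.center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.inner_radius**2


def _filament_mask(spec: ColonySpec, fl: Filament) -> np.ndarray:
    """Rasterize one radial rectangle by a point-in-rectangle test.

    A zero-length filament is a no-op by definition (no protrusion), not a
    degenerate sliver on the disc boundary.
    """
    if fl.length <= 0:
        return np.zeros((spec.image_height, spec.image_width), dtype=bool)
    yy, xx = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    cx, cy = spec.center
    dx, dy = xx - cx, yy - cy
    c, s = math.cos(fl.angle), math.sin(fl.angle)
    u = dx * c + dy * s  # radial coordinate
    v = -dx * s + dy * c  # transverse coordinate
    start = fl.start_radius
    if start is None:
        # anchor inside the disc so the spoke is guaranteed attached
        start = max(0.0, spec.inner_radius - max(fl.width, 2.0))
    return (u >= start) & (u <= spec.inner_radius + fl.length) & (np.abs(v) <= fl.width / 2.0)


def _noiseless_masks(spec: ColonySpec) -> tuple[np.ndarray, np.ndarray]:
    """(disc mask, filled union mask) for the spec, both boolean."""
    disc = _disc_mask(spec)
    union = disc.copy()
    for fl in spec.filaments:
        union |= _filament_mask(spec, fl)
    filled = ndimage.binary_fill_holes(union)
    return disc, filled


def render_colony(spec: ColonySpec) -> tuple[RasterImage, GroundTruth]:
    """Render one synthetic colony and its exact ground truth.

    The ground truth is computed by pixel counting on the noiseless mask:
    ``a_inner_true`` counts disc pixels, ``a_outer_true`` counts pixels
    inside the filled external boundary of disc ∪ filaments. With
    ``noise_sd = 0`` the image is a deterministic function of the spec.
    """
    spec.validate()
    disc, filled = _noiseless_masks(spec)
    a_inner = int(disc.sum())
    a_outer = int(filled.sum())
    if a_inner == 0:
        raise ValueError("disc rasterized to zero pixels")
    truth = GroundTruth(a_inner, a_outer, (a_outer - a_inner) / a_inner)

    fg, bg = spec.foreground_level, spec.background_level
    if spec.inverted:
        fg, bg = bg, fg
    img = np.where(filled, float(fg), float(bg))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    raster = RasterImage(
        np.repeat(img[:, :, None], 3, axis=2),
        "RGB",
        {"synthetic": True, "seed": spec.seed},
    )
    return raster, truth


# ---------------------------------------------------------------------------
# simulated f-measure distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseGroup:
    concentration_uM: float
    n: int
    mean_f: float
    sd_f: float


@dataclass
class DoseDesign:
    """Parameterization of one strain x compound dose-response panel."""

    groups: Sequence[DoseGroup]
    family: str = "lognormal"  # lognormal | gamma | truncated-normal
    outlier_rate: float = 0.0
    outlier_scale: float = 1.0
    seed: int = 0
    strain: str = ""
    compound: str = ""

    def validate(self) -> "DoseDesign":
        if self.family not in ("lognormal", "gamma", "truncated-normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.groups:
            raise ValueError("design needs at least one group")
        concs = [g.concentration_uM for g in self.groups]
        if len(set(concs)) != len(concs):
            raise ValueError("concentrations must be unique within a design")
        for g in self.groups:
            if g.concentration_uM < 0:
                raise ValueError("concentrations must be non-negative")
            if g.mean_f <= 0 or g.sd_f < 0:
                raise ValueError("mean_f must be > 0 and sd_f >= 0")
            if g.n < 2:
                raise ValueError("each group needs n >= 2")
        if not (0 <= self.outlier_rate <= 1):
            raise ValueError("outlier_rate must be in [0, 1]")
        return self


def _draw_group(rng: np.random.Generator, family: str, n: int, mean: float, sd: float,
                label: str) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    cv = sd / mean
    if family == "lognormal":
        sigma2 = math.log1p(cv**2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), n)
    if family == "gamma":
        shape = 1.0 / cv**2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, n)
    # truncated normal on [0, inf): moment-match by solving for the
    # standardized truncation point alpha = (0 - mu)/sigma. The coefficient
    # of variation of a left-truncated normal is bounded above by 1, so
    # cv >= 1 is infeasible for this family.
    if cv >= 1.0:
        raise ValueError(
            f"truncated-normal not moment-matchable for group {label}: "
            f"cv = {cv:.3f} >= 1"
        )

    def cv_of(alpha: float) -> float:
        # mu = -alpha * sigma, so the mean is sigma * (m_std - alpha)
        m, v = stats.truncnorm.stats(alpha, np.inf, moments="mv")
        return float(np.sqrt(v) / (m - alpha))

    lo, hi = -30.0, 30.0
    if not (cv_of(lo) <= cv <= cv_of(hi)):
        raise ValueError(
            f"truncated-normal not moment-matchable for group {label}: "
            f"cv = {cv:.3f} out of reach"
        )
    alpha = optimize.brentq(lambda a: cv_of(a) - cv, lo, hi, xtol=1e-10)
    _, v = stats.truncnorm.stats(alpha, np.inf, moments="mv")
    sigma = sd / math.sqrt(float(v))
    mu = -alpha * sigma  # truncated mean mu + sigma*lam then equals sd/cv = mean
    return stats.truncnorm.rvs(
        (0.0 - mu) / sigma, np.inf, loc=mu, scale=sigma, size=n, random_state=rng
    )


def simulate_fmeasures(design: DoseDesign) -> pd.DataFrame:
    """Draw a simulated per-colony f-measure table for one panel.

    Each group's n values come from the design's positive-support family
    moment-matched to (mean_f, sd_f); with probability ``outlier_rate`` a
    draw is multiplied by ``outlier_scale``. Reproducible under the
    design's seed. Columns: colony_id, strain, compound, concentration_uM,
    f, is_outlier.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    for g in design.groups:
        label = f"{design.strain}/{design.compound}/{g.concentration_uM}uM"
        values = _draw_group(rng, design.family, g.n, g.mean_f, g.sd_f, label)
        planted = rng.random(g.n) < design.outlier_rate
        values = np.where(planted, values * design.outlier_scale, values)
        for i, (v, p) in enumerate(zip(values, planted)):
            rows.append(
                {
                    "colony_id": f"sim-{g.concentration_uM:g}uM-{i:04d}",
                    "strain": design.strain,
                    "compound": design.compound,
                    "concentration_uM": g.concentration_uM,
                    "f": float(v),
                    "is_outlier": bool(p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference dose designs
# ---------------------------------------------------------------------------

# Post-exclusion group sizes, composite f-measure means and SDs observed in
# the reference Dekkera filamentation assays, per strain x compound panel
# dosed at 0/10/50/100/200 µM.
_REFERENCE_PANELS = {
    ("D. anomalous", "2-phenylethanol"): [
        (0, 47, 0.467, 0.270),
        (10, 46, 0.489, 0.350),
        (50, 53, 1.109, 0.932),
        (100, 59, 0.969, 0.946),
        (200, 53, 1.570, 1.206),
    ],
    ("D. bruxellensis", "2-phenylethanol"): [
        (0, 99, 0.330, 0.217),
        (10, 62, 0.398, 0.192),
        (50, 106, 0.847, 0.810),
        (100, 91, 1.776, 1.299),
        (200, 77, 1.770, 1.319),
    ],
    ("D. anomalous", "tryptophol"): [
        (0, 85, 0.310, 0.190),
        (10, 44, 0.341, 0.197),
        (50, 76, 0.964, 0.663),
        (100, 77, 1.443, 0.996),
        (200, 80, 0.657, 0.442),
    ],
    ("D. bruxellensis", "tryptophol"): [
        (0, 88, 0.721, 0.459),
        (10, 49, 0.723, 0.498),
        (50, 79, 0.856, 0.435),
        (100, 79, 2.085, 1.547),
        (200, 53, 1.373, 1.222),
    ],
}


def default_designs(
    family: str = "lognormal",
    outlier_rate: float = 0.0,
    outlier_scale: float = 1.0,
    seed: int = 0,
) -> dict[tuple[str, str], DoseDesign]:
    """Dose designs reproducing the reference study's panel structure.

    Keys are (strain, compound); each design carries that panel's
    (concentration, n, mean, sd) quadruples. Seeds are offset per panel so
    panels are independent but jointly reproducible.
    """
    designs = {}
    for offset, ((strain, compound), rows) in enumerate(sorted(_REFERENCE_PANELS.items())):
        groups = [DoseGroup(float(c), int(n), float(m), float(s)) for c, n, m, s in rows]
        designs[(strain, compound)] = DoseDesign(
            groups=groups,
            family=family,
            outlier_rate=outlier_rate,
            outlier_scale=outlier_scale,
            seed=seed + offset,
            strain=strain,
            compound=compound,
        )
    return designs


# ---------------------------------------------------------------------------
# image datasets
# ---------------------------------------------------------------------------


def random_colony_specs(
    n: int,
    seed: int = 0,
    image_size: tuple[int, int] = (640, 480),
    inner_radius_range: tuple[float, float] = (70.0, 110.0),
    n_filaments_range: tuple[int, int] = (0, 24),
    filament_length_range: tuple[float, float] = (10.0, 90.0),
    filament_width_range: tuple[float, float] = (4.0, 10.0),
    noise_sd: float = 4.0,
) -> list[ColonySpec]:
    """Sample n varied colony specs spanning round to strongly filamentous."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        r = rng.uniform(*inner_radius_range)
        k = int(rng.integers(n_filaments_range[0], n_filaments_range[1] + 1))
        # spread spokes with angular jitter so they rarely overlap
        base = rng.uniform(0, 2 * math.pi)
        filaments = []
        for j in range(k):
            angle = base + 2 * math.pi * j / max(k, 1) + rng.normal(0, 0.05)
            filaments.append(
                Filament(
                    angle=angle,
                    length=float(rng.uniform(*filament_length_range)),
                    width=float(rng.uniform(*filament_width_range)),
                )
            )
        specs.append(
            ColonySpec(
                image_width=image_size[0],
                image_height=image_size[1],
                inner_radius=r,
                filaments=tuple(filaments),
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_image_dataset(
    out_dir: str | Path,
    specs: Sequence[ColonySpec],
    strain: str = "synthetic",
    compound: str = "none",
    concentrations: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render specs to PNGs plus manifest and ground-truth CSVs.

    Writes ``colony_####.png`` files, ``manifest.csv`` (file, colony_id,
    strain, compound, concentration_uM) and ``ground_truth.csv``
    (colony_id, a_inner_true, a_outer_true, f_true) under ``out_dir``;
    returns the two tables.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for i, spec in enumerate(specs):
        raster, truth = render_colony(spec)
        cid = f"colony_{i:04d}"
        fname = f"{cid}.png"
        iio.imwrite(out / fname, raster.pixels)
        conc = float(concentrations[i]) if concentrations is not None else 0.0
        manifest_rows.append(
            {
                "file": fname,
                "colony_id": cid,
                "strain": strain,
                "compound": compound,
                "concentration_uM": conc,
            }
        )
        truth_rows.append(
            {
                "colony_id": cid,
                "a_inner_true": truth.a_inner_true,
                "a_outer_true": truth.a_outer_true,
                "f_true": truth.f_true,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    truths = pd.DataFrame(truth_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    truths.to_csv(out / "ground_truth.csv", index=False)
    return manifest, truths


def parse_design_file(path: str | Path) -> DoseDesign:
    """Read a dose design from a plain key = value config file.

    Recognised keys: family, outlier_rate, outlier_scale, seed, strain,
    compound, and one ``group = conc n mean sd`` line per group. Lines
    starting with '#' are comments.
    """
    kw: dict = {"groups": []}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "group":
            parts = value.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: group needs 'conc n mean sd'")
            c, n, m, s = parts
            kw["groups"].append(DoseGroup(float(c), int(n), float(m), float(s)))
        elif key in ("outlier_rate", "outlier_scale"):
            kw[key] = float(value)
        elif key == "seed":
            kw[key] = int(value)
        elif key in ("family", "strain", "compound"):
            kw[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return DoseDesign(**kw).validate()
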