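"""Synthetic charred grape-pip generator.

Grape pips ("pips" is the archaeobotanical term for grape seeds) are modelled
as tapered superellipsoids with a narrowed beak (stalk) end and two
longitudinal grooves — the ventral infolds — carved into the ventral face.
Charring is modelled as anisotropic affine shrinkage (length shrinks faster
than width above 250 °C, so the length/width ratio falls) plus stochastic
crack dropout at high temperature.  The shrinkage factors are calibrated from
the published per-condition mean lengths and widths of the two reference
cultivars (Cabernet Sauvignon and Tzuriman S.), shipped with the package as
``data/charring_reference_means.csv``.

Coordinate convention: mm units, right-handed axes, x = length (beak toward
negative x), y = breadth, z = dorsoventral with the ventral face toward +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRESH",
    "VarietyShape",
    "CharringCondition",
    "DeformationModel",
    "PointCloud",
    "SeedScan",
    "IntrinsicParams",
    "ParameterError",
    "CalibrationError",
    "BoundsError",
    "DEFAULT_VARIETIES",
    "load_reference_means",
    "generate_fresh_cloud",
    "sample_shape",
    "calibrate_deformation",
    "default_deformation_model",
    "apply_charring",
    "simulate_scan",
]

FRESH = "fresh"

#: width (mm) of the Gaussian groove profile carved into the ventral face
GROOVE_SIGMA_MM = 0.15

#: transverse crack bands: count range and half-width (mm)
CRACK_BANDS = (2, 4)
CRACK_HALFWIDTH_MM = 0.05


class ParameterError(ValueError):
    """Invalid shape or generation parameters."""


class CalibrationError(ValueError):
    """Reference table unsuitable for calibrating a deformation model."""


class BoundsError(ValueError):
    """Scan grid too small to contain the cloud footprint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarietyShape:
    """Per-variety pip geometry parameters (all lengths in mm).

    ``infold_separation`` is the fresh distance between the two ventral
    infold grooves (DVI); ``beak_fraction`` controls how strongly the stalk
    end is narrowed; ``asymmetry`` inflates the ventral relative to the
    dorsal half.
    """

    name: str
    base_length: float
    base_width: float
    base_height: float
    infold_separation: float
    infold_depth: float = 0.35
    beak_fraction: float = 0.25
    asymmetry: float = 0.05

    def __post_init__(self) -> None:
        if min(self.base_length, self.base_width, self.base_height) <= 0:
            raise ParameterError("all base dimensions must be positive")
        if self.base_length <= self.base_width:
            raise ParameterError("base_length must exceed base_width")
        if self.infold_separation >= self.base_width:
            raise ParameterError("infold_separation must be below base_width")
        if not 0.0 <= self.beak_fraction < 0.5:
            raise ParameterError("beak_fraction must lie in [0, 0.5)")
        if self.infold_depth < 0 or self.infold_separation <= 0:
            raise ParameterError("infold parameters must be positive")


@dataclass(frozen=True)
class CharringCondition:
    """A charring treatment: temperature (°C) and heating duration (h).

    ``temperature_C is None`` encodes the fresh (uncharred) state.  The
    controlled experiments ran on a {200, 250, 300, 350} °C × {2, 8} h grid;
    intermediate temperatures are admitted so the calibrated model can be
    queried by interpolation.
    """

    temperature_C: float | None
    duration_h: float | None = None

    def __post_init__(self) -> None:
        if self.temperature_C is not None:
            if not 150.0 <= float(self.temperature_C) <= 400.0:
                raise ParameterError("charring temperature outside 150-400 °C")
            if self.duration_h is None or not 0 < float(self.duration_h) <= 24:
                raise ParameterError("charring duration must lie in (0, 24] h")

    @classmethod
    def fresh(cls) -> "CharringCondition":
        return cls(None, None)

    @property
    def is_fresh(self) -> bool:
        return self.temperature_C is None

    def label(self) -> str:
        if self.is_fresh:
            return FRESH
        return f"{self.temperature_C:g}C_{self.duration_h:g}h"


def morphometric_grid() -> list[CharringCondition]:
    """The charring grid with published morphometric means."""
    return [
        CharringCondition(t, d) for t in (200.0, 250.0, 300.0, 350.0) for d in (2.0, 8.0)
    ]


@dataclass(frozen=True)
class PointCloud:
    """A pip surface sampling: an (n, 3) array of xyz coordinates in mm."""

    points: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def with_points(self, pts: np.ndarray, **meta: object) -> "PointCloud":
        return PointCloud(pts, {**self.meta, **meta})


@dataclass(frozen=True)
class SeedScan:
    """A top-view stereoscopic height map: 0 is background, values are mm."""

    height_map: np.ndarray

    def __post_init__(self) -> None:
        hm = np.asarray(self.height_map, dtype=float)
        if hm.ndim != 2:
            raise ParameterError("height_map must be 2-D")
        if np.any(hm < 0) or not np.any(hm > 0):
            raise ParameterError("heights must be >= 0 with at least one foreground pixel")
        object.__setattr__(self, "height_map", hm)

    @property
    def rows(self) -> int:
        return int(self.height_map.shape[0])

    @property
    def cols(self) -> int:
        return int(self.height_map.shape[1])


@dataclass(frozen=True)
class IntrinsicParams:
    """Scanner intrinsics mapping pixel indices to mm.

    ``principal_point`` is (cx, cy) in (column, row) pixel units; a pixel at
    (row, col) maps to x = (col - cx) * mm_per_pixel_x and
    y = (row - cy) * mm_per_pixel_y.
    """

    mm_per_pixel_x: float
    mm_per_pixel_y: float
    principal_point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mm_per_pixel_x <= 0 or self.mm_per_pixel_y <= 0:
            raise ParameterError("pixel scale factors must be positive")


# ---------------------------------------------------------------------------
# reference data and default varieties
# ---------------------------------------------------------------------------


def load_reference_means() -> pd.DataFrame:
    """Published per-condition morphometric means/SDs for the two cultivars.

    Columns: variety, temperature_C (NaN = fresh), duration_h, and mean/sd
    for length, width, DVI and the per-seed length/width ratio.
    """
    with resources.files("carposort.data").joinpath(
        "charring_reference_means.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _fresh_row(table: pd.DataFrame, variety: str) -> pd.Series:
    rows = table[(table["variety"] == variety) & (table["temperature_C"].isna())]
    if rows.empty:
        raise CalibrationError(f"no fresh row for variety {variety!r}")
    return rows.iloc[0]


#: default variety library: the two calibration cultivars with published
#: fresh dimensions, plus three accession-style varieties (9043, 98, 138)
#: with plausible but invented geometry, used to fill out reference libraries.
DEFAULT_VARIETIES: dict[str, VarietyShape] = {
    "cabernet_sauvignon": VarietyShape(
        "cabernet_sauvignon", 5.81, 3.81, 2.60, 0.96, 0.30, 0.30, 0.05
    ),
    "tzuriman": VarietyShape("tzuriman", 5.83, 4.27, 3.20, 1.14, 0.45, 0.15, 0.05),
    "variety_9043": VarietyShape("variety_9043", 5.20, 4.00, 2.70, 1.45, 0.38, 0.22, 0.05),
    "variety_98": VarietyShape("variety_98", 5.90, 4.15, 3.10, 0.85, 0.50, 0.35, 0.05),
    "variety_138": VarietyShape("variety_138", 4.90, 3.90, 2.55, 1.20, 0.25, 0.10, 0.05),
}


# ---------------------------------------------------------------------------
# fresh-pip generation
# ---------------------------------------------------------------------------

_CROSS_EXPONENT = 2.5  # superellipse exponent of the transverse cross-section


def _superellipse(angle: np.ndarray, exponent: float) -> tuple[np.ndarray, np.ndarray]:
    c, s = np.cos(angle), np.sin(angle)
    p = 2.0 / exponent
    return np.sign(c) * np.abs(c) ** p, np.sign(s) * np.abs(s) ** p


def _carve_grooves(pts: np.ndarray, shape: VarietyShape, half_len: float) -> np.ndarray:
    """Subtract two Gaussian-profile grooves from the ventral (+z) face."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    s2 = shape.infold_separation / 2.0
    profile = np.exp(-((y - s2) ** 2) / (2 * GROOVE_SIGMA_MM**2))
    profile += np.exp(-((y + s2) ** 2) / (2 * GROOVE_SIGMA_MM**2))
    envelope = np.exp(-((x / (0.65 * half_len)) ** 4))
    top = (shape.base_height / 2.0) * (1.0 + shape.asymmetry)
    ramp = np.clip(z / (0.6 * top), 0.0, 1.0) ** 2
    carve = shape.infold_depth * profile * envelope * ramp
    out = pts.copy()
    out[:, 2] = np.where(z > 0, z - carve, z)
    return out


def generate_fresh_cloud(
    shape: VarietyShape, n_points: int = 1500, rng_seed: int = 0
) -> PointCloud:
    """Sample the surface of a fresh pip in canonical pose.

    The base surface is an ellipsoid with a superelliptic cross-section,
    tapered toward the beak (negative x) by ``beak_fraction`` and carved with
    two ventral grooves at ±infold_separation/2.  A few exact landmark points
    (the two poles and the two widest equator points) are appended so the
    measured length and width match the nominal dimensions.  Deterministic
    given ``rng_seed``.
    """
    if n_points < 200:
        raise ParameterError("n_points must be at least 200")
    rng = np.random.default_rng(rng_seed)
    a = shape.base_length / 2.0
    b = shape.base_width / 2.0
    c = shape.base_height / 2.0

    n = n_points - 4
    u = np.arcsin(rng.uniform(-1.0, 1.0, n))  # area-uniform in the polar angle
    v = rng.uniform(0.0, 2.0 * np.pi, n)
    cy, sz = _superellipse(v, _CROSS_EXPONENT)
    x = a * np.sin(u)
    r = np.cos(u)
    y = b * r * cy
    z = c * r * sz

    # beak taper: narrow the cross-section toward negative x
    taper = 1.0 - shape.beak_fraction * np.clip(-x / a, 0.0, None) ** 2
    y *= taper
    z *= taper

    # dorsoventral asymmetry: ventral half slightly fuller
    z = np.where(z > 0, z * (1.0 + shape.asymmetry), z * (1.0 - shape.asymmetry))

    pts = np.column_stack([x, y, z])
    landmarks = np.array(
        [
            [-a, 0.0, 0.0],
            [a, 0.0, 0.0],
            [0.0, -b, 0.0],
            [0.0, b, 0.0],
        ]
    )
    pts = np.vstack([pts, landmarks])
    pts = _carve_grooves(pts, shape, a)
    return PointCloud(pts, {"variety": shape.name, "condition": FRESH})


def sample_shape(
    shape: VarietyShape,
    rng: np.random.Generator,
    cv_size: float = 0.022,
    cv_ratio: float = 0.053,
) -> VarietyShape:
    """Draw one seed's geometry around the variety mean.

    Per-seed variability is multiplicative: a common size factor (CV
    ``cv_size``) scaling every dimension, and a ratio factor (CV ``cv_ratio``)
    moving length against width so the spread of per-seed L/W ratios matches
    the published fresh scatter.  Defaults are the CVs implied by the fresh
    Cabernet Sauvignon row of the reference table.
    """
    size = max(0.5, 1.0 + rng.normal(0.0, cv_size))
    ratio = max(0.5, 1.0 + rng.normal(0.0, cv_ratio))
    sqr = np.sqrt(ratio)
    return replace(
        shape,
        base_length=shape.base_length * size * sqr,
        base_width=shape.base_width * size / sqr,
        base_height=shape.base_height * size / sqr,
        infold_separation=shape.infold_separation * size / sqr,
    )


# ---------------------------------------------------------------------------
# charring deformation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformationModel:
    """Charring shrinkage calibrated from per-condition reference means.

    ``shrink_length(variety, T, t)`` is mean_length(variety, T, t) divided by
    the variety's fresh mean length; widths analogously.  Between tabulated
    temperatures (and durations) the factors interpolate linearly; outside
    the tabulated range they clamp.  Unknown varieties fall back to the mean
    factor across the calibrated cultivars.

    ``crack_intensity`` is 0 below 300 °C and ramps linearly to 0.3 at
    350 °C, reflecting the observed onset of surface cracking.

    The model also carries the incremental per-seed noise CVs implied by the
    per-condition SDs (spread beyond the fresh scatter), used to draw
    seed-level variability in :func:`apply_charring`.
    """

    temperatures: tuple[float, ...]
    durations: tuple[float, ...]
    factors: Mapping[str, Mapping[str, np.ndarray]]  # variety -> kind -> (nT, nD)
    fresh_cvs: Mapping[str, tuple[float, float]]  # variety -> (cv_size, cv_ratio)
    crack_onset_C: float = 300.0
    crack_max: float = 0.3

    def _grid(self, variety: str, kind: str) -> np.ndarray:
        if variety in self.factors:
            return self.factors[variety][kind]
        stacked = np.stack([m[kind] for m in self.factors.values()])
        return stacked.mean(axis=0)

    def _interp(self, variety: str, kind: str, T: float, t: float) -> float:
        grid = self._grid(variety, kind)
        temps = np.asarray(self.temperatures)
        durs = np.asarray(self.durations)
        cols = [np.interp(T, temps, grid[:, j]) for j in range(len(durs))]
        return float(np.interp(t, durs, np.asarray(cols)))

    def shrink_length(self, variety: str, T: float, t: float) -> float:
        return self._interp(variety, "length", T, t)

    def shrink_width(self, variety: str, T: float, t: float) -> float:
        return self._interp(variety, "width", T, t)

    def noise_cvs(self, variety: str, T: float, t: float) -> tuple[float, float]:
        return (
            self._interp(variety, "cv_size", T, t),
            self._interp(variety, "cv_ratio", T, t),
        )

    def crack_intensity(self, T: float, t: float) -> float:
        if T < self.crack_onset_C:
            return 0.0
        ramp = (T - 250.0) / 100.0
        return float(np.clip(self.crack_max * ramp, 0.0, self.crack_max))


def calibrate_deformation(reference_means: pd.DataFrame) -> DeformationModel:
    """Calibrate a :class:`DeformationModel` from a reference-means table.

    The table must contain, per variety, one fresh row (NaN temperature) and
    at least one charred row, with columns ``length_mean``/``width_mean`` and
    matching ``*_sd`` plus ``lw_mean``/``lw_sd``.
    """
    t = reference_means
    charred = t[t["temperature_C"].notna()]
    if charred.empty:
        raise CalibrationError("no charred rows in reference table")
    temps = tuple(sorted(charred["temperature_C"].unique()))
    durs = tuple(sorted(charred["duration_h"].unique()))
    factors: dict[str, dict[str, np.ndarray]] = {}
    fresh_cvs: dict[str, tuple[float, float]] = {}
    for variety, sub in t.groupby("variety"):
        fresh = _fresh_row(t, str(variety))
        sub_charred = sub[sub["temperature_C"].notna()]
        if sub_charred.empty:
            raise CalibrationError(f"no charred rows for variety {variety!r}")
        shape = (len(temps), len(durs))
        grids = {k: np.full(shape, np.nan) for k in ("length", "width", "cv_size", "cv_ratio")}
        cv_len_fresh = fresh["length_sd"] / fresh["length_mean"]
        cv_lw_fresh = fresh["lw_sd"] / fresh["lw_mean"]
        cv_size_fresh = float(np.sqrt(max(cv_len_fresh**2 - cv_lw_fresh**2 / 4.0, 0.0)))
        fresh_cvs[str(variety)] = (cv_size_fresh, float(cv_lw_fresh))
        for _, row in sub_charred.iterrows():
            i = temps.index(row["temperature_C"])
            j = durs.index(row["duration_h"])
            grids["length"][i, j] = row["length_mean"] / fresh["length_mean"]
            grids["width"][i, j] = row["width_mean"] / fresh["width_mean"]
            cv_len = row["length_sd"] / row["length_mean"]
            cv_lw = row["lw_sd"] / row["lw_mean"]
            cv_ratio_inc = np.sqrt(max(cv_lw**2 - cv_lw_fresh**2, 0.0))
            cv_size_inc = np.sqrt(
                max(cv_len**2 - cv_len_fresh**2 - cv_ratio_inc**2 / 4.0, 0.0)
            )
            grids["cv_size"][i, j] = cv_size_inc
            grids["cv_ratio"][i, j] = cv_ratio_inc
        if np.any(np.isnan(grids["length"])):
            raise CalibrationError(
                f"variety {variety!r} does not cover the full temperature/duration grid"
            )
        factors[str(variety)] = grids
    return DeformationModel(temps, durs, factors, fresh_cvs)


def default_deformation_model() -> DeformationModel:
    """Deformation model calibrated to the packaged reference means."""
    return calibrate_deformation(load_reference_means())


def apply_charring(
    cloud: PointCloud,
    condition: CharringCondition,
    model: DeformationModel,
    rng_seed: int = 0,
    variety: str | None = None,
    variability: bool = True,
) -> PointCloud:
    """Deform a fresh pip cloud according to a charring condition.

    x coordinates shrink by the calibrated length factor, y and z by the
    width factor.  With ``variability`` the factors are additionally jittered
    per seed using the condition's calibrated incremental CVs.  Above the
    crack onset temperature, 2-4 narrow transverse bands of points are
    dropped and the surviving points jittered, emulating surface cracks.
    """
    if condition.is_fresh:
        return cloud.with_points(cloud.points.copy(), condition=FRESH)
    if variety is None:
        variety = str(cloud.meta.get("variety", ""))
    T, t = float(condition.temperature_C), float(condition.duration_h)
    f_len = model.shrink_length(variety, T, t)
    f_wid = model.shrink_width(variety, T, t)
    rng = np.random.default_rng(rng_seed)
    if variability:
        cv_size, cv_ratio = model.noise_cvs(variety, T, t)
        size = max(0.5, 1.0 + rng.normal(0.0, cv_size))
        ratio = max(0.5, 1.0 + rng.normal(0.0, cv_ratio))
        sqr = np.sqrt(ratio)
        f_len *= size * sqr
        f_wid *= size / sqr
    pts = cloud.points * np.array([f_len, f_wid, f_wid])

    intensity = model.crack_intensity(T, t)
    if intensity > 0:
        x = pts[:, 0]
        half_len = 0.5 * (x.max() - x.min())
        n_bands = int(rng.integers(CRACK_BANDS[0], CRACK_BANDS[1] + 1))
        centers = rng.uniform(-0.8, 0.8, n_bands) * half_len
        drop = np.zeros(len(pts), dtype=bool)
        for center in centers:
            in_band = np.abs(x - center) < CRACK_HALFWIDTH_MM
            drop |= in_band & (rng.random(len(pts)) < min(1.0, 3.0 * intensity))
        pts = pts[~drop]
        pts = pts + rng.normal(0.0, 0.05 * intensity, pts.shape)

    return cloud.with_points(pts, condition=condition.label())


# ---------------------------------------------------------------------------
# scan simulation
# ---------------------------------------------------------------------------


def simulate_scan(
    cloud: PointCloud,
    intrinsics: IntrinsicParams,
    grid: tuple[int, int],
    stage_offset: float = 0.05,
) -> SeedScan:
    """Render a top-view height map of a canonical, ventral-up cloud.

    The cloud is rested on the scanner stage (z shifted so its lowest point
    sits ``stage_offset`` mm above the background plane); each pixel records
    the maximum height among the points falling in its footprint, emulating a
    top-surface stereoscopic scan.  Pixels with no points are background 0.
    """
    rows, cols = grid
    pts = cloud.points
    if pts.shape[0] == 0:
        raise ParameterError("cannot scan an empty cloud")
    if stage_offset <= 0:
        raise ParameterError("stage_offset must be positive")
    cx, cy = intrinsics.principal_point
    col_idx = np.rint(pts[:, 0] / intrinsics.mm_per_pixel_x + cx).astype(int)
    row_idx = np.rint(pts[:, 1] / intrinsics.mm_per_pixel_y + cy).astype(int)
    if (
        col_idx.min() < 0
        or row_idx.min() < 0
        or col_idx.max() >= cols
        or row_idx.max() >= rows
    ):
        raise BoundsError("scan grid too small to contain the cloud footprint")
    heights = pts[:, 2] - pts[:, 2].min() + stage_offset
    hm = np.zeros((rows, cols))
    np.maximum.at(hm, (row_idx, col_idx), heights)
    return SeedScan(hm)


def auto_intrinsics(
    cloud: PointCloud, mm_per_pixel: float = 0.05, margin_px: int = 4
) -> tuple[IntrinsicParams, tuple[int, int]]:
    """Intrinsics and grid size that comfortably contain a cloud's footprint."""
    pts = cloud.points
    half_x = max(abs(pts[:, 0].min()), pts[:, 0].max()) / mm_per_pixel
    half_y = max(abs(pts[:, 1].min()), pts[:, 1].max()) / mm_per_pixel
    cx = int(np.ceil(half_x)) + margin_px
    cy = int(np.ceil(half_y)) + margin_px
    grid = (2 * cy + 1, 2 * cx + 1)
    return IntrinsicParams(mm_per_pixel, mm_per_pixel, (float(cx), float(cy))), grid
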