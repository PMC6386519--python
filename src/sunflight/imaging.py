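"""Brp-density quantification: background-subtracted intensity per unit area.

Quantifies the density of the presynaptic active-zone marker Bruchpilot
(Brp) in the Gall, the lateral neuropil targeted by E-PG axons, from a
grayscale fluorescence image (or a z-stack, max-projected first):

1. background per pixel = unweighted mean intensity over all neighbouring
   background ROIs (rectangles);
2. background is subtracted from every pixel of the rectangular Gall ROI,
   negative values clipped to zero, and the result summed to a total
   intensity;
3. total intensity is divided by the Gall area, outlined manually as a
   polygon (shoelace area, times the physical area per pixel if given).

Coordinates are row-major, 0-based; rectangles are half-open
``(row0, row1, col0, col1)``; the area polygon is a list of (row, col)
vertices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon


@dataclass
class BrpImage:
    """2-D intensity array (or 3-D stack, max-projected on use)."""

    pixels: np.ndarray
    pixel_area: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D image or a 3-D stack")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel intensity")
        if np.any(self.pixels < 0):
            raise ValueError("negative pixel intensity")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def projected(self) -> np.ndarray:
        """Maximum-intensity projection (identity for 2-D input)."""
        if self.pixels.ndim == 3:
            return self.pixels.max(axis=0)
        return self.pixels


@dataclass
class RoiSet:
    """Gall ROI, background ROIs and the manual Gall-area polygon."""

    gall_roi: tuple
    background_rois: list
    area_polygon: np.ndarray

    def __post_init__(self):
        self.gall_roi = tuple(int(v) for v in self.gall_roi)
        self.background_rois = [tuple(int(v) for v in r) for r in self.background_rois]
        self.area_polygon = np.asarray(self.area_polygon, dtype=float)
        if self.area_polygon.ndim != 2 or self.area_polygon.shape[1] != 2:
            raise ValueError("area_polygon must be an (n, 2) array of vertices")
        if self.area_polygon.shape[0] < 3:
            raise ValueError("area_polygon needs at least 3 vertices")
        poly = Polygon(self.area_polygon)
        if not poly.is_valid:
            raise ValueError("area_polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("area_polygon has zero area")

    @property
    def polygon_area_px(self) -> float:
        return float(Polygon(self.area_polygon).area)


@dataclass
class BrpDensityResult:
    total_intensity_bg_subtracted: float
    area: float
    density: float
    background_per_pixel: float


def _check_rect(rect, shape, name):
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"{name} ROI {rect} out of bounds for image {shape}")


def brp_density(image: BrpImage, rois: RoiSet) -> BrpDensityResult:
    """Background-subtracted Brp intensity per unit Gall area."""
    img = image.projected
    _check_rect(rois.gall_roi, img.shape, "gall")
    if not rois.background_rois:
        raise ValueError("empty background ROI set")
    bg_pixels = []
    for rect in rois.background_rois:
        _check_rect(rect, img.shape, "background")
        r0, r1, c0, c1 = rect
        bg_pixels.append(img[r0:r1, c0:c1].ravel())
    background = float(np.concatenate(bg_pixels).mean())

    r0, r1, c0, c1 = rois.gall_roi
    corrected = np.clip(img[r0:r1, c0:c1] - background, 0.0, None)
    total = float(corrected.sum())
    area = rois.polygon_area_px * image.pixel_area
    return BrpDensityResult(
        total_intensity_bg_subtracted=total,
        area=area,
        density=total / area,
        background_per_pixel=background,
    )


@dataclass
class GallGeometry:
    """Layout of the synthetic fixture.

    ``gall`` is the half-open rectangle carrying signal; its corners double
    as the area polygon, so the rasterised pixel count equals the shoelace
    area exactly and noise-free recovery is exact.  A general
    ``polygon`` (list of (row, col) vertices) may be supplied instead, in
    which case the region is rasterised with skimage and the pixel count
    only approximates the polygon area.
    """

    shape: tuple = (64, 64)
    gall: tuple = (24, 40, 24, 40)
    roi_pad: int = 4
    background_rois: list = field(default=None)
    polygon: np.ndarray = None

    def __post_init__(self):
        r0, r1, c0, c1 = self.gall
        if not (r0 < r1 and c0 < c1):
            raise ValueError("degenerate gall rectangle")
        if not (
            0 <= r0 - self.roi_pad
            and r1 + self.roi_pad <= self.shape[0]
            and 0 <= c0 - self.roi_pad
            and c1 + self.roi_pad <= self.shape[1]
        ):
            raise ValueError("gall rectangle plus ROI padding exceeds image bounds")
        if self.background_rois is None:
            # two flanking rectangles left and right of the padded gall ROI
            h0, h1 = r0 - self.roi_pad, r1 + self.roi_pad
            self.background_rois = [
                (h0, h1, 0, max(c0 - self.roi_pad, 1)),
                (h0, h1, min(c1 + self.roi_pad, self.shape[1] - 1), self.shape[1]),
            ]

    def roi_set(self) -> RoiSet:
        r0, r1, c0, c1 = self.gall
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
        else:
            poly = np.array(
                [[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float
            )
        return RoiSet(
            gall_roi=(
                r0 - self.roi_pad,
                r1 + self.roi_pad,
                c0 - self.roi_pad,
                c1 + self.roi_pad,
            ),
            background_rois=self.background_rois,
            area_polygon=poly,
        )


def synth_gall_image(
    signal_level: float,
    background_level: float,
    noise_sd: float = 0.0,
    geometry: GallGeometry | None = None,
    seed=None,
):
    """Render a synthetic Gall image and its matching ROI set.

    The Gall region carries ``background_level + signal_level``, the
    surround ``background_level``; Gaussian noise of SD ``noise_sd`` is
    added everywhere and the image clipped at zero.  Deterministic per
    seed.  Returns ``(BrpImage, RoiSet)``.
    """
    if signal_level < 0 or background_level < 0 or noise_sd < 0:
        raise ValueError("levels and noise_sd must be non-negative")
    geometry = geometry or GallGeometry()
    img = np.full(geometry.shape, float(background_level))
    if geometry.polygon is not None:
        poly = np.asarray(geometry.polygon, dtype=float)
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=geometry.shape)
        img[rr, cc] += signal_level
    else:
        r0, r1, c0, c1 = geometry.gall
        img[r0:r1, c0:c1] += signal_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, geometry.shape)
    img = np.clip(img, 0.0, None)
    return BrpImage(pixels=img), geometry.roi_set()
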