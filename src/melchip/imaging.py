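"""Grid location and spot quantification on chip images.

The acquired image carries four bright Cy5 marker spots at the grid corners.
Gridding detects those markers, fits an affine transform from nominal layout
coordinates to the image, and places a centre on every layout spot.  Each
spot is then quantified GenePix-style: mean interior intensity ``I_m`` over a
disk of 0.6x the nominal radius, local background ``B_m`` as the median over
a 1.2-1.8x annulus (excluding neighbouring spot interiors), plus the camera
dark current ``I_0`` shared per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .panel import ChipLayout
from .synthsim import spot_centers

INTERIOR_FRACTION = 0.6
ANNULUS_INNER = 1.2
ANNULUS_OUTER = 1.8
SATURATION_PIXEL_FRACTION = 0.01
MARKER_RESIDUAL_THRESHOLD = 2.0  # px; above this every spot is flagged weak-marker


class GridError(RuntimeError):
    """Raised when the marker grid cannot be located."""


class BackgroundUndefinedError(RuntimeError):
    """Raised when a spot's background annulus is fully excluded."""


@dataclass(frozen=True)
class SpotQuant:
    spot_index: int
    i_m: float
    b_m: float
    i0: float
    qc_flags: frozenset[str] = frozenset()

    @property
    def usable(self) -> bool:
        return self.b_m > self.i0 and not ({"off-grid"} & self.qc_flags)


@dataclass(frozen=True)
class QuantTable:
    """Per-spot quantifications for one image, one record per occupied spot."""

    image_id: str
    spots: tuple[SpotQuant, ...]
    marker_residual: float = 0.0
    meta: dict = field(default_factory=dict, hash=False)

    def by_index(self) -> dict[int, SpotQuant]:
        return {s.spot_index: s for s in self.spots}

    def to_frame(self, layout: ChipLayout | None = None) -> pd.DataFrame:
        rows = []
        for s in self.spots:
            role = layout.spot_map[s.spot_index] if layout else None
            rows.append({
                "spot_index": s.spot_index,
                "probe_id": role.probe_id if role else None,
                "role": role.kind if role else None,
                "I_m": s.i_m, "B_m": s.b_m, "I0": s.i0,
                "qc_flags": ";".join(sorted(s.qc_flags)),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path, layout: ChipLayout | None = None) -> None:
        self.to_frame(layout).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, image_id: str = "") -> "QuantTable":
        df = pd.read_csv(path, sep="\t")
        spots = tuple(
            SpotQuant(
                int(r.spot_index), float(r.I_m), float(r.B_m), float(r.I0),
                frozenset(str(r.qc_flags).split(";")) if isinstance(r.qc_flags, str) and r.qc_flags else frozenset(),
            )
            for r in df.itertuples()
        )
        return cls(image_id or str(path), spots)


# ---------------------------------------------------------------------------
# Grid location
# ---------------------------------------------------------------------------


def _refine_center(image: np.ndarray, peak: np.ndarray, radius: float) -> np.ndarray:
    """Subpixel refinement: intensity centroid in a window around a peak."""
    r = int(np.ceil(radius)) + 2
    y0, x0 = int(peak[0]), int(peak[1])
    ys = slice(max(0, y0 - r), min(image.shape[0], y0 + r + 1))
    xs = slice(max(0, x0 - r), min(image.shape[1], x0 + r + 1))
    win = image[ys, xs].astype(np.float64)
    win = win - win.min()
    tot = win.sum()
    if tot <= 0:
        return np.array([float(y0), float(x0)])
    yy, xx = np.mgrid[ys, xs]
    return np.array([(win * yy).sum() / tot, (win * xx).sum() / tot])


def locate_grid(image: np.ndarray, layout: ChipLayout
                ) -> tuple[dict[int, tuple[float, float]], float, frozenset[str]]:
    """Locate every layout spot on an image via the four corner markers.

    Returns ``(centers, marker_residual, flags)`` where *centers* maps spot
    index to a continuous (row, col) pixel coordinate.  Raises
    :class:`GridError` when fewer than four markers are found.
    """
    img = np.asarray(image, dtype=np.float64)
    smooth = gaussian(img, sigma=1.0, preserve_range=True)
    g = layout.geometry
    span = smooth.max() - smooth.min()
    if span <= 0:
        raise GridError("uniform image: no markers detectable")
    peaks = peak_local_max(
        smooth,
        min_distance=max(2, int(g.pitch * 0.5)),
        threshold_abs=smooth.min() + 0.5 * span,
    )
    if len(peaks) < 4:
        raise GridError(f"found only {len(peaks)} candidate markers, need 4")

    nominal = spot_centers(layout)
    markers = layout.marker_spots
    if len(markers) != 4:
        raise GridError("layout does not define 4 marker spots")
    # pair each nominal corner with the candidate peak closest to the
    # corresponding image corner direction
    h, w = img.shape
    scale_y, scale_x = h / (2 * g.margin + (g.rows - 1) * g.pitch), \
        w / (2 * g.margin + (g.cols - 1) * g.pitch)
    src, dst = [], []
    used: set[int] = set()
    for m in markers:
        ny, nx = nominal[m]
        target = np.array([ny * scale_y, nx * scale_x])
        dists = np.linalg.norm(peaks - target, axis=1)
        order = np.argsort(dists)
        pick = next((int(j) for j in order if int(j) not in used), None)
        if pick is None:
            raise GridError("could not assign distinct peaks to all markers")
        used.add(pick)
        center = _refine_center(img, peaks[pick], g.radius)
        src.append([ny, nx, 1.0])
        dst.append(center)
    src_a = np.array(src)
    dst_a = np.array(dst)
    coef, res, *_ = np.linalg.lstsq(src_a, dst_a, rcond=None)
    fitted = src_a @ coef
    residual = float(np.sqrt(np.mean(np.sum((fitted - dst_a) ** 2, axis=1))))
    flags = frozenset() if residual <= MARKER_RESIDUAL_THRESHOLD else frozenset({"weak-marker"})
    centers = {}
    for idx in layout.occupied:
        ny, nx = nominal[idx]
        cy, cx = np.array([ny, nx, 1.0]) @ coef
        centers[idx] = (float(cy), float(cx))
    return centers, residual, flags


# ---------------------------------------------------------------------------
# Spot quantification
# ---------------------------------------------------------------------------


def estimate_dark_current(image: np.ndarray) -> float:
    """Fallback dark-current estimate: mean of the darkest 1% of pixels.

    Crude — dark current is a camera property; prefer acquisition metadata
    (the simulator records it in each truth sidecar).
    """
    flat = np.sort(np.asarray(image, dtype=np.float64).ravel())
    k = max(1, int(0.01 * flat.size))
    return float(flat[:k].mean())


def quantify_spot(image: np.ndarray, center: tuple[float, float], radius: float,
                  i0: float, spot_index: int = -1,
                  neighbor_centers: list[tuple[float, float]] | None = None,
                  extra_flags: frozenset[str] = frozenset()) -> SpotQuant:
    """Quantify one spot: interior mean I_m, annulus-median background B_m."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    cy, cx = center
    flags = set(extra_flags)
    if not (0 <= cy < h and 0 <= cx < w):
        return SpotQuant(spot_index, 0.0, 0.0, i0, frozenset(flags | {"off-grid"}))
    r_out = ANNULUS_OUTER * radius
    y0, y1 = max(0, int(cy - r_out) - 1), min(h, int(cy + r_out) + 2)
    x0, x1 = max(0, int(cx - r_out) - 1), min(w, int(cx + r_out) + 2)
    patch = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)

    interior = patch[d <= INTERIOR_FRACTION * radius]
    if interior.size == 0:
        return SpotQuant(spot_index, 0.0, 0.0, i0, frozenset(flags | {"off-grid"}))
    i_m = float(interior.mean())
    if np.issubdtype(image.dtype, np.integer):
        sat = np.iinfo(image.dtype).max
        if np.mean(interior >= sat) > SATURATION_PIXEL_FRACTION:
            flags.add("saturated")

    ann = (d >= ANNULUS_INNER * radius) & (d <= r_out)
    if neighbor_centers:
        for ny, nx in neighbor_centers:
            nd = np.hypot(yy - ny, xx - nx)
            ann &= nd > radius
    bg = patch[ann]
    if bg.size == 0:
        raise BackgroundUndefinedError(
            f"background annulus of spot {spot_index} fully excluded"
        )
    b_m = float(np.median(bg))
    return SpotQuant(spot_index, i_m, b_m, i0, frozenset(flags))


def quantify_image(image: np.ndarray, layout: ChipLayout, i0: float | None = None,
                   image_id: str = "chip") -> QuantTable:
    """Locate the grid and quantify every occupied layout spot."""
    if i0 is None:
        i0 = estimate_dark_current(image)
    centers, residual, grid_flags = locate_grid(image, layout)
    spots = []
    for idx in layout.occupied:
        neighbors = [centers[j] for j in layout.occupied
                     if j != idx and
                     np.hypot(centers[j][0] - centers[idx][0],
                              centers[j][1] - centers[idx][1]) < 2.2 * layout.geometry.radius + layout.geometry.pitch / 2]
        spots.append(
            quantify_spot(image, centers[idx], layout.geometry.radius, i0,
                          spot_index=idx, neighbor_centers=neighbors,
                          extra_flags=grid_flags)
        )
    return QuantTable(image_id, tuple(spots), residual,
                      meta={"i0": i0, "residual": residual})
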