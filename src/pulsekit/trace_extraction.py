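"""ROI definition, rasterization and background-subtracted intensity traces.

A recording is analyzed through user-drawn polygonal regions of interest
(ROIs): one or more *vessel* ROIs sketched over lymphatic segments and one
*background* ROI over dye-free tissue. The per-frame trace is the mean
vessel-ROI intensity minus the mean background-ROI intensity, in arbitrary
units (AU). Negative values are kept — downstream peak/valley detection
must see true excursions, not clamped ones.

Coordinates are 0-based with x increasing rightwards (columns) and y
downwards (rows); the center of pixel ``(row i, col j)`` is the point
``(x=j, y=i)``. A pixel belongs to a polygon iff its center lies inside
under the even-odd (ray crossing) rule, which makes rasterization exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROI_ROLES = ("vessel", "background")


def _polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (n, 2) x/y rows."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Roi:
    """A named polygonal region of interest.

    Parameters
    ----------
    name : str
        Label carried through to output tables.
    vertices : sequence of (x, y)
        Polygon vertices in pixel coordinates, implicitly closed.
    role : {"vessel", "background"}
    """

    name: str
    vertices: tuple
    role: str = "vessel"

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError(f"ROI {self.name!r}: a polygon needs >= 3 vertices")
        if self.role not in ROI_ROLES:
            raise ValueError(f"ROI {self.name!r}: role must be one of {ROI_ROLES}")
        if abs(_polygon_area(np.asarray(verts))) <= 0.0:
            raise ValueError(f"ROI {self.name!r}: degenerate polygon (zero area)")

    @property
    def area(self) -> float:
        return abs(_polygon_area(np.asarray(self.vertices)))


def rasterize_roi(roi: Roi, shape: tuple[int, int]) -> np.ndarray:
    """Boolean membership mask for *roi* on an image of the given shape.

    A pixel is included iff its center lies strictly inside the polygon
    under the even-odd rule. Deterministic; raises on degenerate polygons
    (enforced by :class:`Roi`) and on vertices outside the frame.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    verts = np.asarray(roi.vertices, dtype=float)
    if (verts[:, 0] < -0.5).any() or (verts[:, 0] > w - 0.5).any() \
            or (verts[:, 1] < -0.5).any() or (verts[:, 1] > h - 0.5).any():
        raise ValueError(f"ROI {roi.name!r}: vertices outside frame bounds {shape}")

    jj, ii = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = np.zeros((h, w), dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # edge crosses the horizontal line through the pixel center
        crosses = (y1 > ii) != (y2 > ii)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (ii - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (jj < x_int)
    return inside


@dataclass
class IntensityTrace:
    """Background-subtracted mean ROI intensity per frame (AU)."""

    values: np.ndarray
    frame_interval_s: float
    roi_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval_s

    @property
    def duration_min(self) -> float:
        return self.values.size * self.frame_interval_s / 60.0


def extract_trace(
    stack: np.ndarray,
    vessel_roi: Roi,
    background_roi: Roi,
    frame_interval_s: float,
    valid_mask: np.ndarray | None = None,
) -> IntensityTrace:
    """Mean vessel-ROI intensity minus mean background-ROI intensity per frame.

    ``valid_mask`` (same shape as the stack, boolean) marks pixels that carry
    real data; zero-filled borders produced by stabilization are excluded
    through it. If an ROI has no valid pixel at some frame the function
    raises, naming the frame.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, rows, cols)")
    vmask = rasterize_roi(vessel_roi, stack.shape[1:])
    bmask = rasterize_roi(background_roi, stack.shape[1:])
    n = stack.shape[0]
    values = np.empty(n, dtype=float)
    for t in range(n):
        vm, bm = vmask, bmask
        if valid_mask is not None:
            vm = vmask & valid_mask[t]
            bm = bmask & valid_mask[t]
        if not vm.any():
            raise ValueError(
                f"ROI {vessel_roi.name!r} has no valid pixel at frame {t}")
        if not bm.any():
            raise ValueError(
                f"ROI {background_roi.name!r} has no valid pixel at frame {t}")
        frame = stack[t].astype(float)
        values[t] = frame[vm].mean() - frame[bm].mean()
    return IntensityTrace(values=values, frame_interval_s=float(frame_interval_s),
                          roi_name=vessel_roi.name)
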