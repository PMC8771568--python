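"""Translational stack stabilization by normalized template matching.

Intravital recordings drift with respiration and muscle motion; before any
ROI intensity is read, every frame is aligned to a reference frame by
maximizing the zero-normalized cross-correlation (ZNCC) between a template
cut from the reference and a search window in the frame. ZNCC is invariant
to intensity offset and gain, which matters under fluorescence drift.

Only integer-pixel translations are considered; the stabilized frame is the
input frame translated by the negative of the found displacement, with
exposed borders zero-filled and flagged in a validity mask so downstream
ROI statistics can exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

logger = logging.getLogger(__name__)

LOW_SCORE_WARNING = 0.5


def shift_image(img: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    """Translate a 2-D image by integer (dy, dx), filling exposed pixels."""
    dy, dx = int(dy), int(dx)
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def default_template_region(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Central 50% crop as (x, y, w, h)."""
    h, w = shape
    th, tw = max(h // 2, 1), max(w // 2, 1)
    return (w - tw) // 2, (h - th) // 2, tw, th


@dataclass
class RegistrationResult:
    """Per-frame displacements, match scores and the stabilized stack.

    ``shifts[t] = (dy, dx)`` is the displacement of frame *t*'s content
    relative to the reference frame; the stabilized frame is translated by
    its negative. ``valid_mask`` is False on zero-filled border pixels.
    """

    shifts: np.ndarray
    scores: np.ndarray
    stabilized: np.ndarray
    valid_mask: np.ndarray
    template_region: tuple[int, int, int, int]
    reference_frame: int = 0


def _best_shift(scores: np.ndarray, dys: np.ndarray, dxs: np.ndarray):
    """Argmax with deterministic tie-breaking: highest score, then smallest
    displacement magnitude, then row-major (dy, dx) order."""
    finite = np.isfinite(scores)
    if not finite.any():
        return 0, 0, 0.0
    s, dy, dx = scores[finite], dys[finite], dxs[finite]
    order = np.lexsort((dx, dy, dy * dy + dx * dx, -s))
    k = order[0]
    return int(dy[k]), int(dx[k]), float(np.clip(s[k], -1.0, 1.0))


def register_stack(
    stack: np.ndarray,
    template_region: tuple[int, int, int, int] | None = None,
    search_radius: int = 20,
    reference_frame: int = 0,
) -> RegistrationResult:
    """Stabilize a stack against its reference frame by ZNCC template matching.

    Parameters
    ----------
    stack : (T, H, W) array
    template_region : (x, y, w, h), optional
        Rectangle in the reference frame; defaults to the central 50% crop.
    search_radius : int
        Maximum displacement examined in each direction (pixels).
    reference_frame : int
        Index of the frame the others are aligned to; its shift is (0, 0).

    Candidate displacements whose template window would leave the frame are
    skipped. A constant (zero-variance) template makes the correlation
    undefined and raises. Frames whose best score falls below 0.5 are logged
    as potentially out-of-range matches.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, rows, cols)")
    n, h, w = stack.shape
    if not 0 <= reference_frame < n:
        raise ValueError("reference_frame out of range")
    if search_radius < 0:
        raise ValueError("search_radius must be >= 0")
    if template_region is None:
        template_region = default_template_region((h, w))
    x, y, tw, th = (int(v) for v in template_region)
    if tw < 1 or th < 1 or x < 0 or y < 0 or x + tw > w or y + th > h:
        raise ValueError(f"template_region {template_region} does not fit a "
                         f"{h}x{w} frame")
    template = stack[reference_frame, y:y + th, x:x + tw].astype(float)
    if template.std() == 0:
        raise ValueError("constant template: normalized correlation undefined")

    r = int(search_radius)
    y0, y1 = max(0, y - r), min(h, y + th + r)
    x0, x1 = max(0, x - r), min(w, x + tw + r)

    shifts = np.zeros((n, 2), dtype=int)
    scores = np.ones(n, dtype=float)
    stabilized = np.empty_like(stack)
    valid_mask = np.ones((n, h, w), dtype=bool)
    ones = np.ones((h, w), dtype=np.uint8)

    for t in range(n):
        if t == reference_frame:
            stabilized[t] = stack[t]
            continue
        window = stack[t, y0:y1, x0:x1].astype(float)
        res = match_template(window, template)  # ZNCC at every placement
        res = np.where(np.isfinite(res), res, -np.inf)
        ii, jj = np.meshgrid(np.arange(res.shape[0]), np.arange(res.shape[1]),
                             indexing="ij")
        dys = (y0 + ii) - y
        dxs = (x0 + jj) - x
        dy, dx, score = _best_shift(res.ravel(), dys.ravel(), dxs.ravel())
        if score < LOW_SCORE_WARNING:
            logger.warning("frame %d: best match score %.3f (< %.1f); the true "
                           "displacement may exceed the search radius",
                           t, score, LOW_SCORE_WARNING)
        shifts[t] = (dy, dx)
        scores[t] = score
        stabilized[t] = shift_image(stack[t], -dy, -dx)
        valid_mask[t] = shift_image(ones, -dy, -dx).astype(bool)

    return RegistrationResult(shifts=shifts, scores=scores, stabilized=stabilized,
                              valid_mask=valid_mask, template_region=(x, y, tw, th),
                              reference_frame=reference_frame)
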