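"""Morphological segmentation pipeline for pearl-chain micrographs.

The pipeline reduces a raw micrograph to a binary chain mask replicated into a
3-channel image:

    grayscale -> histogram threshold -> binarize -> dilate(S1)
    -> erode-then-dilate(S2) -> fill holes + clear border
    -> dilate-then-erode(S2) -> stack to RGB

S1 defaults to a 3x3 cross (union of a horizontal and a vertical 3-pixel line);
S2 to a horizontal 1x3 line.  Dilation and erosion follow the set definitions
(dilation hits with the reflected structuring element), with pixels outside the
image treated as background.  All intermediates are strictly {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_LUMA = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class StructuringElement:
    """Small binary mask with an origin pixel.

    The origin is the pixel of the mask that is aligned with the output pixel
    being computed; it must lie inside the mask, which must contain at least
    one on-pixel.
    """

    mask: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2 or not m.any():
            raise ValueError("mask must be 2-D with at least one on-pixel")
        r, c = self.origin
        if not (0 <= r < m.shape[0] and 0 <= c < m.shape[1]):
            raise ValueError("origin must lie inside the mask")

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of on-pixel displacements relative to the origin."""
        rows, cols = np.nonzero(self.mask)
        return np.stack([rows - self.origin[0], cols - self.origin[1]], axis=1)


def cross3() -> StructuringElement:
    """3x3 cross: union of horizontal and vertical 3-pixel lines (default S1)."""
    mask = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    return StructuringElement(mask, (1, 1))


def hline3() -> StructuringElement:
    """Horizontal 1x3 line (default S2)."""
    return StructuringElement(np.ones((1, 3), dtype=bool), (0, 1))


_NAMED_SE = {"cross3": cross3, "hline3": hline3}


def named_se(name: str) -> StructuringElement:
    try:
        return _NAMED_SE[name]()
    except KeyError:
        raise ValueError(f"unknown structuring element {name!r}") from None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale conversion (0.299 R + 0.587 G + 0.114 B).

    Single-channel input passes through unchanged.  Integer inputs are rounded
    back to their dtype; float inputs stay float.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0]
    if img.ndim == 3 and img.shape[2] == 3:
        gray = (
            _LUMA[0] * img[:, :, 0].astype(float)
            + _LUMA[1] * img[:, :, 1].astype(float)
            + _LUMA[2] * img[:, :, 2].astype(float)
        )
        if np.issubdtype(img.dtype, np.integer):
            return np.rint(gray).astype(img.dtype)
        return gray
    raise ValueError(f"expected 1 or 3 channels, got shape {img.shape}")


def select_threshold(image: np.ndarray) -> int:
    """Global histogram threshold maximizing between-class variance (Otsu).

    The returned alpha is meant for the `I >= alpha` foreground convention of
    :func:`binarize`: candidate splits alpha in 1..255 are scored by the
    between-class variance of {I < alpha} vs {I >= alpha}, and the smallest
    maximizing alpha is returned.  Constant images are rejected (no separating
    threshold exists).
    """
    img = np.asarray(image)
    vals = img.astype(np.int64).ravel()
    if vals.min() == vals.max():
        raise ValueError("constant image has no separating threshold")
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("select_threshold expects intensities in 0..255")
    hist = np.bincount(vals, minlength=256).astype(float)
    n = hist.sum()
    p = hist / n
    idx = np.arange(256, dtype=float)
    # cumulative weight / mean of the background class {I < alpha}
    w0 = np.cumsum(p)[:-1]  # w0[a-1] = P(I < a) for a = 1..255
    mu0 = np.cumsum(p * idx)[:-1]
    mu_total = float((p * idx).sum())
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(w0 > 0, mu0 / w0, 0.0)
        m1 = np.where(w1 > 0, (mu_total - mu0) / w1, 0.0)
    sigma_b = w0 * w1 * (m0 - m1) ** 2
    alpha = int(np.argmax(sigma_b)) + 1  # smallest maximizer wins ties
    return alpha


def binarize(image: np.ndarray, alpha: float) -> np.ndarray:
    """Binary image: 1 where I >= alpha, else 0."""
    return (np.asarray(image) >= alpha).astype(np.uint8)


def _check_binary(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if not np.isin(img, (0, 1)).all():
        raise ValueError("expected a strictly binary {0,1} image")
    return img.astype(bool)


def _shift(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean image by (dr, dc), filling with background."""
    out = np.zeros_like(image)
    h, w = image.shape
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = image[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def dilate(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Set dilation: z is on iff the reflected SE translated to z hits the image.

    Equivalently the union of image translates by every SE offset.  Extensive
    whenever the SE origin is an on-pixel.
    """
    img = _check_binary(image)
    out = np.zeros_like(img)
    for dr, dc in se.offsets:
        out |= _shift(img, dr, dc)
    return out.astype(np.uint8)


def erode(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Set erosion: z is on iff every SE on-pixel translated to z is on.

    Pixels outside the image count as background, so the result shrinks at the
    border.
    """
    img = _check_binary(image)
    out = np.ones_like(img)
    for dr, dc in se.offsets:
        out &= _shift(img, -dr, -dc)
    return out.astype(np.uint8)


def erode_then_dilate(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation with the same SE (a morphological opening:
    anti-extensive and idempotent; removes features thinner than the SE)."""
    return dilate(erode(image, se), se)


def dilate_then_erode(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion with the same SE (a morphological closing:
    extensive and idempotent; bridges gaps narrower than the SE).

    The composition runs on a frame padded by the SE extent and is cropped
    back afterwards, so the intermediate dilation is not clipped at the
    border and extensivity holds on the full raster (the infinite-domain set
    semantics restricted to the image).
    """
    img = _check_binary(image).astype(np.uint8)
    offs = se.offsets
    pr = int(np.abs(offs[:, 0]).max())
    pc = int(np.abs(offs[:, 1]).max())
    padded = np.pad(img, ((pr, pr), (pc, pc)))
    out = erode(dilate(padded, se), se)
    h, w = img.shape
    return out[pr : pr + h, pc : pc + w]


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def fill_holes_and_clear_border(image: np.ndarray) -> np.ndarray:
    """Fill enclosed background holes, then drop components touching the border.

    Both steps use 4-connectivity.  A hole is a background component with no
    4-connected path to the image border.
    """
    img = _check_binary(image)
    filled = ndimage.binary_fill_holes(img, structure=_CROSS)
    labels, n = ndimage.label(filled, structure=_CROSS)
    if n:
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        border = border[border != 0]
        if border.size:
            filled &= ~np.isin(labels, border)
    return filled.astype(np.uint8)


def stack_to_rgb(image: np.ndarray) -> np.ndarray:
    """Replicate a binary image into three identical channels."""
    img = _check_binary(image).astype(np.uint8)
    return np.stack([img, img, img], axis=-1)


def segment(
    image: np.ndarray,
    s1: StructuringElement | None = None,
    s2: StructuringElement | None = None,
) -> np.ndarray:
    """Full segmentation pipeline; returns an H x W x 3 {0,1} image.

    Stage order: grayscale, per-image histogram threshold, binarize,
    dilate(S1), erode-then-dilate(S2), fill holes + clear border,
    dilate-then-erode(S2), 3-channel stack.
    """
    s1 = s1 or cross3()
    s2 = s2 or hline3()
    gray = to_grayscale(image)
    alpha = select_threshold(gray)
    binary = binarize(gray, alpha)
    binary = dilate(binary, s1)
    binary = erode_then_dilate(binary, s2)
    binary = fill_holes_and_clear_border(binary)
    binary = dilate_then_erode(binary, s2)
    return stack_to_rgb(binary)
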