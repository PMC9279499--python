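"""Particle detection by normalized cross-correlation template matching.

A small template patch of a single particle is slid across the micrograph and
each offset (x, y) is scored with the normalized cross-correlation metric

    R(x, y) = sum T(x',y') I(x+x', y+y')
              / sqrt( sum T(x',y')^2 * sum I(x+x', y+y')^2 )

(the sums run over the template window; for multi-channel input the numerator
and each denominator sum additionally run over channels, yielding a
single-channel map).  On non-negative images R lies in [0, 1] by
Cauchy-Schwarz.  Particle centers are the thresholded local maxima of R after
greedy non-maximum suppression.

Template geometry follows the pearl-radius convention: for a template of width
l and height b pixels the particle radius is r = (l + b) / 4 and the chain
search tolerance is c = r / 4 unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve


def template_geometry(
    l: float, b: float, c_override: float | None = None
) -> tuple[float, float]:
    """Radius r = (l + b) / 4 and tolerance c (= r / 4 by default) in pixels."""
    if l < 1 or b < 1:
        raise ValueError(f"template dimensions must be >= 1, got l={l}, b={b}")
    r = (l + b) / 4.0
    c = r / 4.0 if c_override is None else float(c_override)
    return r, c


@dataclass(frozen=True)
class Template:
    """A particle reference patch with derived search geometry.

    `l` is the patch width, `b` its height (pixels); `r` and `c` are the
    derived pearl radius and adjacency tolerance.
    """

    patch: np.ndarray
    l: int
    b: int
    r: float
    c: float

    @classmethod
    def from_patch(
        cls, patch: np.ndarray, c_override: float | None = None
    ) -> "Template":
        arr = np.asarray(patch, dtype=float)
        if arr.ndim not in (2, 3):
            raise ValueError("template patch must be 2-D or 3-D (H x W [x C])")
        if not np.any(arr):
            raise ValueError("template patch is identically zero")
        b, l = arr.shape[:2]
        r, c = template_geometry(l, b, c_override)
        return cls(patch=arr, l=l, b=b, r=r, c=c)


@dataclass(frozen=True)
class Detection:
    """One detected particle: integer (row, col) center and its match score."""

    row: int
    col: int
    score: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.row, self.col)


def _as_channels(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2:
        return a[:, :, None]
    if a.ndim == 3:
        return a
    raise ValueError(f"expected 2-D or 3-D array, got shape {a.shape}")


def normalized_cross_correlation(
    image: np.ndarray, template: Template
) -> np.ndarray:
    """Score map of the NCC metric at every valid top-left offset.

    The output has shape (H - b + 1, W - l + 1).  Windows with zero energy
    score 0 (they cannot contain a particle and a 0 never crosses a positive
    threshold).  Channel counts of image and template must match.
    """
    img = _as_channels(image)
    tpl = _as_channels(template.patch)
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise ValueError("template does not fit inside the image")
    if tpl.shape[2] != img.shape[2]:
        raise ValueError("image and template channel counts differ")

    num = np.zeros(
        (img.shape[0] - tpl.shape[0] + 1, img.shape[1] - tpl.shape[1] + 1)
    )
    win_energy = np.zeros_like(num)
    ones = np.ones(tpl.shape[:2])
    for ch in range(img.shape[2]):
        flipped = tpl[::-1, ::-1, ch]
        num += fftconvolve(img[:, :, ch], flipped, mode="valid")
        win_energy += fftconvolve(img[:, :, ch] ** 2, ones, mode="valid")
    t_energy = float((tpl**2).sum())
    # FFT round-off can leave tiny residues where the true window energy is 0;
    # anything below this floor is treated as an empty window.
    total = float((img**2).sum())
    floor = 1e-9 * total
    win_energy = np.where(win_energy <= floor, 0.0, win_energy)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / np.sqrt(t_energy * win_energy)
    scores = np.where(win_energy > 0, scores, 0.0)
    return np.clip(scores, 0.0, 1.0)


def detect_particles(
    score_map: np.ndarray, template: Template, threshold: float = 0.9
) -> list[Detection]:
    """Thresholded local maxima of the score map with non-maximum suppression.

    Candidates (3x3 local maxima with score >= threshold) are accepted greedily
    in descending score order; a candidate within Euclidean distance r of an
    already accepted center is suppressed, so touching chain members (2r apart)
    are never merged.  Centers are the template's central pixel: offset +
    ((b-1)/2, (l-1)/2), rounded half up.  Odd-sized templates therefore give
    exact integer centers.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    scores = np.asarray(score_map, dtype=float)
    if scores.size == 0:
        return []
    local_max = scores >= ndimage.maximum_filter(scores, size=3, mode="constant")
    rows, cols = np.nonzero(local_max & (scores >= threshold))
    if rows.size == 0:
        return []
    vals = scores[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    rows, cols, vals = rows[order], cols[order], vals[order]

    dr = (template.b - 1) / 2.0
    dc = (template.l - 1) / 2.0
    accepted_rc: list[tuple[float, float]] = []
    detections: list[Detection] = []
    r2 = template.r**2
    for y, x, s in zip(rows, cols, vals):
        if any((y - ar) ** 2 + (x - ac) ** 2 <= r2 for ar, ac in accepted_rc):
            continue
        accepted_rc.append((float(y), float(x)))
        detections.append(
            Detection(
                row=int(np.floor(y + dr + 0.5)),
                col=int(np.floor(x + dc + 0.5)),
                score=float(s),
            )
        )
    return detections


def match_and_detect(
    image: np.ndarray, template: Template, threshold: float = 0.9
) -> list[Detection]:
    """Convenience composition: score map then particle detection."""
    return detect_particles(
        normalized_cross_correlation(image, template), template, threshold
    )
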