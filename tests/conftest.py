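"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use naive nested loops and the
textbook set definitions, independent of the vectorized/FFT code paths they
are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from depchain.detect import Template
from depchain.synthetic import render_template


# --- oracles ----------------------------------------------------------------

def ncc_bruteforce(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct nested-loop evaluation of the normalized cross-correlation map.

    Supports single- and multi-channel input; channel sums are folded into the
    numerator and each denominator sum.
    """
    img = np.asarray(image, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
        tpl = tpl[:, :, None]
    th, tw = tpl.shape[:2]
    oh = img.shape[0] - th + 1
    ow = img.shape[1] - tw + 1
    out = np.zeros((oh, ow))
    t_sq = 0.0
    for a in range(th):
        for b in range(tw):
            for ch in range(tpl.shape[2]):
                t_sq += tpl[a, b, ch] ** 2
    for y in range(oh):
        for x in range(ow):
            num = 0.0
            i_sq = 0.0
            for a in range(th):
                for b in range(tw):
                    for ch in range(tpl.shape[2]):
                        v = img[y + a, x + b, ch]
                        num += tpl[a, b, ch] * v
                        i_sq += v * v
            den = np.sqrt(t_sq * i_sq)
            out[y, x] = num / den if den > 0 else 0.0
    return out


def dilate_bruteforce(image, offsets) -> np.ndarray:
    """Set-definition dilation: z on iff some (dr, dc) offset maps an on-pixel
    of the input onto z."""
    img = np.asarray(image).astype(bool)
    h, w = img.shape
    out = np.zeros_like(img)
    for z_r in range(h):
        for z_c in range(w):
            hit = False
            for dr, dc in offsets:
                sr, sc = z_r - dr, z_c - dc
                if 0 <= sr < h and 0 <= sc < w and img[sr, sc]:
                    hit = True
                    break
            out[z_r, z_c] = hit
    return out.astype(np.uint8)


def erode_bruteforce(image, offsets) -> np.ndarray:
    """Set-definition erosion: z on iff every offset lands on an on-pixel
    (outside the image counts as background)."""
    img = np.asarray(image).astype(bool)
    h, w = img.shape
    out = np.zeros_like(img)
    for z_r in range(h):
        for z_c in range(w):
            ok = True
            for dr, dc in offsets:
                sr, sc = z_r + dr, z_c + dc
                if not (0 <= sr < h and 0 <= sc < w and img[sr, sc]):
                    ok = False
                    break
            out[z_r, z_c] = ok
    return out.astype(np.uint8)


def otsu_bruteforce(image) -> int:
    """Exhaustive between-class-variance search over all 256 thresholds,
    computed from raw pixels (no histogram); smallest maximizer wins."""
    vals = np.asarray(image).astype(float).ravel()
    best_alpha, best_var = None, -1.0
    for alpha in range(1, 256):
        fg = vals[vals >= alpha]
        bg = vals[vals < alpha]
        if len(fg) == 0 or len(bg) == 0:
            var = 0.0
        else:
            w0 = len(bg) / len(vals)
            w1 = len(fg) / len(vals)
            var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_alpha = alpha
    return best_alpha


def components_bruteforce(n: int, edges) -> list[list[int]]:
    """Transitive-closure grouping by repeated sweeps (no union-find)."""
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            lo = min(labels[i], labels[j])
            if labels[i] != lo or labels[j] != lo:
                labels[i] = labels[j] = lo
                changed = True
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        root = lab
        while root != labels[root]:
            root = labels[root]
        groups.setdefault(root, []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def disk_template() -> Template:
    """The default particle template: radius-10 disk, matching the generator."""
    return Template.from_patch(render_template(10))
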