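"""Synthetic pearl-chain micrographs with known ground truth.

Real micrographs of dielectrophoretic pearl chains (spherical particles
assembled into linear aggregates aligned with the field) are emulated as
filled disks on a uniform background with additive Gaussian noise.  The
distribution of chain lengths is conditioned on the applied voltage (1-10 V at
a fixed 200 kHz drive) through a piecewise-categorical model anchored at the
experimentally reported shares:

* at 3 V, 84% of chains are pairs (C2) and 15% triples (C3);
* beyond 5 V about 40% of chains exceed 4 particles;
* above 7 V the majority of chains have 8+ particles, with the 8-10 band
  holding a significant (>= 6.7%) share and very few short chains.

Between anchors the categorical probabilities are interpolated linearly, so
the expected chain length is non-decreasing in voltage by construction.
Chains are rendered as straight lines of touching disks (center spacing
exactly 2r); member centers are rounded to integer pixels and recorded as
ground truth together with the chain partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chains import FeatureVector, bin_chain_sizes

#: Voltage-anchored chain-length distributions {length: probability}.
#: Overridable via the `anchors` argument of :func:`sample_chain_lengths`.
#: The 3 V anchor pins the reported 84% / 15% C2 / C3 shares; the 5 V anchor
#: puts 40% of the mass above 4 particles; from 7 V upward the majority of
#: chains have 8+ particles and the mean length keeps growing by roughly one
#: particle per volt, consistent with the 10-12 bead chains reported for
#: comparable bead systems at higher drive amplitudes.
DEFAULT_LENGTH_ANCHORS: dict[float, dict[int, float]] = {
    1: {2: 0.97, 3: 0.03},
    3: {2: 0.84, 3: 0.15, 4: 0.01},
    5: {2: 0.18, 3: 0.22, 4: 0.20, 5: 0.18, 6: 0.12, 7: 0.10},
    7: {5: 0.03, 6: 0.08, 7: 0.14, 8: 0.30, 9: 0.25, 10: 0.12,
        11: 0.05, 12: 0.03},
    10: {7: 0.02, 8: 0.05, 9: 0.08, 10: 0.12, 11: 0.18, 12: 0.20,
         13: 0.15, 14: 0.10, 15: 0.06, 16: 0.04},
}

#: Fraction of the particle budget assembled into chains at each voltage
#: (linearly interpolated).  Pearl chains appear only from about 2 V; at 1 V
#: almost all particles stay dispersed as singletons.
DEFAULT_CHAINING_FRACTION: dict[float, float] = {
    1: 0.10, 2: 0.60, 3: 0.85, 5: 0.95, 10: 0.98,
}

VOLTAGE_MIN = 1.0
VOLTAGE_MAX = 10.0


def length_distribution(
    voltage: float,
    anchors: dict[float, dict[int, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, probabilities) of the chain-length distribution at `voltage`.

    Probabilities are linearly interpolated between the two bracketing anchor
    voltages; a convex combination of normalized distributions, so the result
    is itself normalized and its mean interpolates the anchor means.
    """
    if not VOLTAGE_MIN <= voltage <= VOLTAGE_MAX:
        raise ValueError(
            f"voltage must be in [{VOLTAGE_MIN}, {VOLTAGE_MAX}] V, got {voltage}"
        )
    anchors = anchors if anchors is not None else DEFAULT_LENGTH_ANCHORS
    knots = sorted(anchors)
    for v, dist in anchors.items():
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"anchor at {v} V sums to {total}, expected 1")
    v = float(np.clip(voltage, knots[0], knots[-1]))
    hi_idx = int(np.searchsorted(knots, v, side="left"))
    if knots[min(hi_idx, len(knots) - 1)] == v:
        lo, hi, w = v, v, 0.0
    else:
        lo, hi = knots[hi_idx - 1], knots[hi_idx]
        w = (v - lo) / (hi - lo)
    support = sorted(set(anchors[lo]) | set(anchors[hi]))
    p = np.array(
        [
            (1 - w) * anchors[lo].get(L, 0.0) + w * anchors[hi].get(L, 0.0)
            for L in support
        ]
    )
    return np.asarray(support, dtype=int), p / p.sum()


def expected_chain_length(
    voltage: float, anchors: dict[float, dict[int, float]] | None = None
) -> float:
    lengths, p = length_distribution(voltage, anchors)
    return float((lengths * p).sum())


def sample_chain_lengths(
    voltage: float,
    n_chains: int,
    seed: int | np.random.Generator,
    anchors: dict[float, dict[int, float]] | None = None,
) -> list[int]:
    """Draw `n_chains` chain lengths from the voltage-conditioned distribution."""
    if n_chains < 0:
        raise ValueError(f"n_chains must be >= 0, got {n_chains}")
    lengths, p = length_distribution(voltage, anchors)
    if n_chains == 0:
        return []
    rng = np.random.default_rng(seed)
    return [int(v) for v in rng.choice(lengths, size=n_chains, p=p)]


@dataclass(frozen=True)
class Chain:
    """A straight pearl chain: start center (row, col), orientation, length."""

    start: tuple[float, float]
    angle: float  # radians, measured from the +col axis
    length: int


@dataclass
class SceneSpec:
    """Full description of one synthetic micrograph.

    Chain member centers are spaced exactly 2 * particle_radius along the
    chain axis and rounded to integer pixels for rendering and ground truth.
    Distinct chains must keep a center-to-center clearance strictly greater
    than 2r + c (c = r/4) so that the adjacency rule can never merge them.
    """

    image_height: int = 512
    image_width: int = 512
    particle_radius: int = 10
    voltage: float = 5.0
    chains: list[Chain] = field(default_factory=list)
    background_level: float = 10.0
    particle_level: float = 200.0
    noise_sd: float = 8.0
    seed: int = 0

    @property
    def tolerance(self) -> float:
        return self.particle_radius / 4.0


def chain_centers(chain: Chain, radius: float) -> np.ndarray:
    """Integer (row, col) member centers of a chain (spacing 2r along axis)."""
    step = 2.0 * radius
    i = np.arange(chain.length)
    rows = chain.start[0] + i * step * np.sin(chain.angle)
    cols = chain.start[1] + i * step * np.cos(chain.angle)
    return np.rint(np.stack([rows, cols], axis=1)).astype(int)


def _all_centers(spec: SceneSpec) -> tuple[np.ndarray, list[list[int]]]:
    centers: list[np.ndarray] = []
    membership: list[list[int]] = []
    idx = 0
    for chain in spec.chains:
        cc = chain_centers(chain, spec.particle_radius)
        centers.append(cc)
        membership.append(list(range(idx, idx + len(cc))))
        idx += len(cc)
    if centers:
        return np.concatenate(centers, axis=0), membership
    return np.zeros((0, 2), dtype=int), membership


def validate_scene(spec: SceneSpec) -> None:
    """Reject scenes violating the placement invariants before rendering."""
    r = spec.particle_radius
    centers, membership = _all_centers(spec)
    if centers.size == 0:
        return
    if (
        centers[:, 0].min() < r
        or centers[:, 1].min() < r
        or centers[:, 0].max() > spec.image_height - 1 - r
        or centers[:, 1].max() > spec.image_width - 1 - r
    ):
        raise ValueError("chain member disks extend outside the image")
    sep = 2 * r + spec.tolerance
    for a in range(len(membership)):
        pa = centers[membership[a]]
        for b in range(a + 1, len(membership)):
            pb = centers[membership[b]]
            d2 = (
                (pa[:, None, 0] - pb[None, :, 0]) ** 2
                + (pa[:, None, 1] - pb[None, :, 1]) ** 2
            )
            if d2.min() <= sep**2:
                raise ValueError(
                    f"chains {a} and {b} closer than the 2r+c separation"
                )


@dataclass
class GroundTruth:
    """Exact particle centers, chain partition and true chain-length counts."""

    particle_centers: np.ndarray  # (n, 2) int, (row, col)
    chain_membership: list[list[int]]
    true_counts: FeatureVector


def _render_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radius: float,
    background: float,
    level: float,
) -> np.ndarray:
    img = np.full(shape, background, dtype=float)
    r_int = int(math.ceil(radius))
    offs = np.arange(-r_int, r_int + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    disk = (dr**2 + dc**2) <= radius**2
    drs, dcs = dr[disk], dc[disk]
    h, w = shape
    for cr, cc in centers:
        rr = cr + drs
        cc_ = cc + dcs
        keep = (rr >= 0) & (rr < h) & (cc_ >= 0) & (cc_ < w)
        img[rr[keep], cc_[keep]] = level
    return img


def generate_micrograph(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a SceneSpec to a uint8 image plus its ground truth.

    Each particle is a filled disk of `particle_level` on `background_level`;
    Gaussian noise of sd `noise_sd` is added and the result clipped to
    [0, 255].  The same spec (including seed) always yields a bit-identical
    image.
    """
    validate_scene(spec)
    centers, membership = _all_centers(spec)
    img = _render_disks(
        (spec.image_height, spec.image_width),
        centers,
        spec.particle_radius,
        spec.background_level,
        spec.particle_level,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        particle_centers=centers,
        chain_membership=membership,
        true_counts=bin_chain_sizes([len(m) for m in membership]),
    )
    return img, truth


def render_template(
    radius: int, particle_level: float = 200.0, background_level: float = 10.0
) -> np.ndarray:
    """A (2r+1) x (2r+1) patch of one particle, matching the scene renderer."""
    size = 2 * radius + 1
    return _render_disks(
        (size, size),
        np.array([[radius, radius]]),
        radius,
        background_level,
        particle_level,
    ).astype(np.uint8)


# --- scene construction -----------------------------------------------------

#: Target number of particles per micrograph.  The particle density is the
#: same at every voltage (it is one suspension observed at different drive
#: amplitudes); what changes with voltage is how the budget is partitioned
#: into chains versus dispersed singletons, and how long the chains are.
DEFAULT_PARTICLE_BUDGET = 150

#: Extra clearance (pixels) added to the 2r + c separation when placing
#: chains, so +-1 px detection error can never bridge two distinct chains.
SEPARATION_SLACK = 4.0


def chaining_fraction(voltage: float) -> float:
    knots = sorted(DEFAULT_CHAINING_FRACTION)
    return float(
        np.interp(voltage, knots, [DEFAULT_CHAINING_FRACTION[k] for k in knots])
    )


def scene_composition(
    voltage: float, particle_budget: int = DEFAULT_PARTICLE_BUDGET
) -> tuple[int, int]:
    """(n_chains, n_singletons) for a scene at `voltage`.

    The chained share of the particle budget is divided by the expected chain
    length; the remainder stays dispersed.
    """
    fc = chaining_fraction(voltage)
    n_chains = max(0, round(particle_budget * fc / expected_chain_length(voltage)))
    n_singletons = max(0, round(particle_budget * (1 - fc)))
    return n_chains, n_singletons


def make_scene(
    voltage: float,
    seed: int,
    image_height: int = 512,
    image_width: int = 512,
    particle_radius: int = 10,
    n_chains: int | None = None,
    n_singletons: int | None = None,
    noise_sd: float = 8.0,
    background_level: float = 10.0,
    particle_level: float = 200.0,
    anchors: dict[float, dict[int, float]] | None = None,
    max_tries: int = 300,
) -> SceneSpec:
    """Sample a valid SceneSpec: voltage-conditioned lengths plus dispersed
    singleton particles, random straight placements, rejection sampling to
    honor the separation invariant.

    Chains that cannot be placed within `max_tries` attempts are dropped
    (occasional in crowded low-voltage scenes).
    """
    rng = np.random.default_rng(seed)
    if n_chains is None or n_singletons is None:
        auto_chains, auto_singles = scene_composition(voltage)
        n_chains = auto_chains if n_chains is None else n_chains
        n_singletons = auto_singles if n_singletons is None else n_singletons
    lengths = sample_chain_lengths(voltage, n_chains, rng, anchors)
    lengths = lengths + [1] * int(n_singletons)
    r = particle_radius
    margin = r + 2
    min_sep = 2 * r + r / 4.0 + SEPARATION_SLACK
    placed: list[Chain] = []
    placed_centers: list[np.ndarray] = []
    for length in lengths:
        span = (length - 1) * 2.0 * r
        for _ in range(max_tries):
            angle = rng.uniform(0.0, 2.0 * np.pi)
            d_row = span * np.sin(angle)
            d_col = span * np.cos(angle)
            lo_r = margin + max(0.0, -d_row)
            hi_r = image_height - 1 - margin - max(0.0, d_row)
            lo_c = margin + max(0.0, -d_col)
            hi_c = image_width - 1 - margin - max(0.0, d_col)
            if hi_r <= lo_r or hi_c <= lo_c:
                continue
            start = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            cand = Chain(start=start, angle=float(angle), length=int(length))
            cc = chain_centers(cand, r).astype(float)
            ok = True
            for other in placed_centers:
                d2 = (
                    (cc[:, None, 0] - other[None, :, 0]) ** 2
                    + (cc[:, None, 1] - other[None, :, 1]) ** 2
                )
                if d2.min() <= min_sep**2:
                    ok = False
                    break
            if ok:
                placed.append(cand)
                placed_centers.append(cc)
                break
    return SceneSpec(
        image_height=image_height,
        image_width=image_width,
        particle_radius=particle_radius,
        voltage=float(voltage),
        chains=placed,
        background_level=background_level,
        particle_level=particle_level,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# --- augmentation -----------------------------------------------------------

MAX_TRANSLATION = 30


def flip_vertical_axis(image: np.ndarray) -> np.ndarray:
    """Mirror the image across its vertical axis (left-right flip)."""
    return np.asarray(image)[:, ::-1].copy()


def translate(
    image: np.ndarray, shift: tuple[int, int], fill: float = 0.0
) -> np.ndarray:
    """Integer (row, col) translation, padding exposed pixels with `fill`."""
    img = np.asarray(image)
    out = np.full_like(img, fill)
    dr, dc = int(shift[0]), int(shift[1])
    h, w = img.shape[:2]
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = img[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def augment(
    image: np.ndarray,
    seed: int | np.random.Generator,
    max_shift: int = MAX_TRANSLATION,
    background_level: float = 0.0,
) -> np.ndarray:
    """Random vertical-axis flip plus uniform integer translation of up to
    `max_shift` pixels per axis, padding with the background level."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot augment an empty image")
    rng = np.random.default_rng(seed)
    out = img
    if rng.integers(0, 2):
        out = flip_vertical_axis(out)
    dr = int(rng.integers(-max_shift, max_shift + 1))
    dc = int(rng.integers(-max_shift, max_shift + 1))
    return translate(out, (dr, dc), fill=background_level)
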