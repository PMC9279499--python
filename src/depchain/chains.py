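"""Pearl-chain assembly and chain-length-count features.

Detected particle centers are linked whenever their Euclidean distance is at
most 2r + c (two touching pearls of radius r, plus a tolerance c absorbing
rasterization and detection error).  Chains are the connected components of
this adjacency graph, and the feature vector counts chains by length:
C_L for L = 2..18, with size-1 groups reported as singletons and groups longer
than 18 as overflow.  The conservation identity

    sum_L L * C_L + singletons + overflow_particles == number of detections

holds for every input and is the bookkeeping check used throughout the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import Detection, Template, match_and_detect

L_MIN = 2
L_MAX = 18
FEATURE_NAMES = tuple(f"C{L}" for L in range(L_MIN, L_MAX + 1))
#: The regression/ranking predictor set: 18 values C1..C18, where C1 is the
#: singleton count and C2..C18 the chain-length counts.
PREDICTOR_NAMES = ("C1",) + FEATURE_NAMES


def build_adjacency(
    centers: list[tuple[float, float]] | np.ndarray, r: float, c: float
) -> list[tuple[int, int]]:
    """Symmetric, irreflexive edge list: (i, j), i < j, iff dist <= 2r + c."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if c < 0:
        raise ValueError(f"c must be >= 0, got {c}")
    pts = np.asarray(centers, dtype=float)
    if pts.size == 0:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(2 * r + c, output_type="ndarray")
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return [tuple(p) for p in pairs[order]]


@dataclass
class ChainSet:
    """A partition of detection indices into maximal adjacency groups."""

    groups: list[list[int]]

    @property
    def lengths(self) -> list[int]:
        return [len(g) for g in self.groups]


def group_chains(n_points: int, edges: list[tuple[int, int]]) -> ChainSet:
    """Connected components of the adjacency graph (union-find).

    Groups are sorted internally and ordered by their smallest member index,
    so the output is deterministic for a given edge set.
    """
    parent = list(range(n_points))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    members: dict[int, list[int]] = {}
    for i in range(n_points):
        members.setdefault(find(i), []).append(i)
    groups = sorted((sorted(g) for g in members.values()), key=lambda g: g[0])
    return ChainSet(groups=groups)


@dataclass
class FeatureVector:
    """Chain-length counts C_2..C_18 plus singleton and overflow bookkeeping."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(L_MAX - L_MIN + 1, dtype=int)
    )
    singletons: int = 0
    overflow: int = 0  # number of groups with more than L_MAX members
    overflow_particles: int = 0  # total particles inside overflow groups
    voltage: float | None = None

    def __getitem__(self, length: int) -> int:
        if not L_MIN <= length <= L_MAX:
            raise KeyError(f"chain length {length} outside [{L_MIN}, {L_MAX}]")
        return int(self.counts[length - L_MIN])

    @property
    def total_particles(self) -> int:
        lengths = np.arange(L_MIN, L_MAX + 1)
        return int((lengths * self.counts).sum()) + self.singletons + self.overflow_particles

    def as_series(self) -> pd.Series:
        data = {name: int(v) for name, v in zip(FEATURE_NAMES, self.counts)}
        data["singletons"] = self.singletons
        data["overflow"] = self.overflow
        return pd.Series(data)

    def as_predictors(self) -> np.ndarray:
        """The 18-value predictor vector C1..C18 (C1 = singleton count)."""
        return np.concatenate([[self.singletons], self.counts]).astype(float)


def bin_chain_sizes(sizes: list[int] | np.ndarray) -> FeatureVector:
    """Bucket group sizes into a FeatureVector (shared with the generator's
    ground-truth bookkeeping)."""
    fv = FeatureVector()
    for s in sizes:
        s = int(s)
        if s <= 0:
            raise ValueError("group sizes must be positive")
        if s == 1:
            fv.singletons += 1
        elif s <= L_MAX:
            fv.counts[s - L_MIN] += 1
        else:
            fv.overflow += 1
            fv.overflow_particles += s
    return fv


def chain_counts(chain_set: ChainSet) -> FeatureVector:
    """Count groups by size: C_L for L = 2..18, singletons, overflow."""
    return bin_chain_sizes(chain_set.lengths)


def assemble_chains(
    detections: list[Detection], r: float, c: float
) -> ChainSet:
    centers = [(d.row, d.col) for d in detections]
    return group_chains(len(centers), build_adjacency(centers, r, c))


def extract_features(
    image: np.ndarray,
    template: Template,
    threshold: float = 0.9,
    voltage: float | None = None,
) -> FeatureVector:
    """End-to-end feature extraction: detect -> adjacency -> group -> counts."""
    detections = match_and_detect(image, template, threshold)
    fv = chain_counts(assemble_chains(detections, template.r, template.c))
    fv.voltage = voltage
    return fv


def features_to_frame(
    features: list[FeatureVector], image_ids: list | None = None
) -> pd.DataFrame:
    """Tabulate feature vectors as a DataFrame (image_id, voltage, C2..C18,
    singletons, overflow)."""
    rows = []
    for i, fv in enumerate(features):
        row = {"image_id": image_ids[i] if image_ids is not None else i}
        row["voltage"] = fv.voltage
        row.update(fv.as_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def predictor_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for learning from a feature table: X holds the 18 predictors
    C1..C18 (C1 = singletons column), y the voltage labels."""
    X = np.column_stack(
        [frame["singletons"].to_numpy(float)]
        + [frame[name].to_numpy(float) for name in FEATURE_NAMES]
    )
    return X, frame["voltage"].to_numpy(float)
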