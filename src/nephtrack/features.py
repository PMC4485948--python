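"""Feature extraction: cross sections, nodes, shape factors and profiles.

Each binary slice is segmented into 4-connected lumen cross sections.
A cross section is abstracted into one or more *nodes* (3D points placed
by K-means over its pixels — one for a round lumen, several along an
elongated one), six shape factors, and a 24-sample centroidal shape
profile per node (boundary radius every 15 degrees).

Coordinate convention: 0-based pixel indices, x = column, y = row,
z = slice index; profile angles are measured from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from sklearn.cluster import KMeans

__all__ = [
    "PROFILE_ANGLES_DEG",
    "N_PROFILE_ANGLES",
    "ShapeFactors",
    "Node",
    "CrossSection",
    "SliceFeatures",
    "StackFeatures",
    "segment_components",
    "allocate_nodes",
    "compute_shape_factors",
    "compute_shape_profile",
    "extract_slice_features",
    "extract_features",
    "features_to_dataframe",
]

N_PROFILE_ANGLES = 24
PROFILE_ANGLES_DEG = np.arange(N_PROFILE_ANGLES) * 15.0


@dataclass(frozen=True)
class ShapeFactors:
    """Six per-cross-section shape descriptors.

    Circularity, eccentricity, solidity and aspect ratio are
    dimensionless (size-invariant); area and minor axis length are
    absolute-valued and carried alongside.
    """

    circularity: float
    eccentricity: float
    solidity: float
    aspect_ratio: float
    area: float
    minor_axis_length: float

    NAMES = ("circularity", "eccentricity", "solidity", "aspect_ratio", "area", "minor_axis_length")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.circularity,
                self.eccentricity,
                self.solidity,
                self.aspect_ratio,
                self.area,
                self.minor_axis_length,
            ]
        )


@dataclass
class Node:
    """A 3D point abstracting (part of) a cross section."""

    x: int
    y: int
    z: int
    cs_id: tuple[int, int]
    k: int = 0
    profile: np.ndarray | None = field(default=None, repr=False)
    cross_section: "CrossSection | None" = field(default=None, repr=False, compare=False)

    @property
    def node_id(self) -> tuple[int, int, int]:
        """(slice, component label, node index) — unique within a stack."""
        return (self.cs_id[0], self.cs_id[1], self.k)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @property
    def radius(self) -> float:
        """Half the minor axis length of the owning cross section."""
        if self.cross_section is None or self.cross_section.shape is None:
            raise ValueError("node has no shape factors attached")
        return self.cross_section.shape.minor_axis_length / 2.0


@dataclass
class CrossSection:
    """One 4-connected lumen component on one slice.

    The pixel mask is stored locally (``mask`` within the bounding box
    anchored at ``bbox_origin``) to keep memory proportional to component
    size rather than image size.
    """

    slice_index: int
    label: int
    mask: np.ndarray = field(repr=False)
    bbox_origin: tuple[int, int]  # (min_row, min_col)
    shape: ShapeFactors | None = None
    nodes: list[Node] = field(default_factory=list)

    @property
    def cs_id(self) -> tuple[int, int]:
        return (self.slice_index, self.label)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of (row, col) pixel coordinates in image frame."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.bbox_origin[0], cc + self.bbox_origin[1]])

    @property
    def centroid_xy(self) -> np.ndarray:
        rr, cc = np.nonzero(self.mask)
        return np.array(
            [cc.mean() + self.bbox_origin[1], rr.mean() + self.bbox_origin[0]]
        )

    def contains_point(self, x: float, y: float, tol: int = 1) -> bool:
        """True if image point (x, y) is on the component or within ``tol`` px."""
        r = int(round(y)) - self.bbox_origin[0]
        c = int(round(x)) - self.bbox_origin[1]
        h, w = self.mask.shape
        r0, r1 = max(0, r - tol), min(h, r + tol + 1)
        c0, c1 = max(0, c - tol), min(w, c + tol + 1)
        if r0 >= r1 or c0 >= c1:
            return False
        return bool(self.mask[r0:r1, c0:c1].any())


def segment_components(binary: np.ndarray, slice_index: int) -> list[CrossSection]:
    """Split a binary slice into 4-connected cross sections.

    Labels follow raster-scan order, so numbering is deterministic for a
    given mask.  Shape factors and nodes are left unfilled.
    """
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndi.label(binary, structure=ndi.generate_binary_structure(2, 1))
    out: list[CrossSection] = []
    slices = ndi.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        out.append(
            CrossSection(
                slice_index=slice_index,
                label=lab,
                mask=labels[sl] == lab,
                bbox_origin=(sl[0].start, sl[1].start),
            )
        )
    return out


def _chain_order(points: np.ndarray) -> np.ndarray:
    """Order points by nearest-neighbour chaining from the most extreme one.

    The chain starts at the point farthest from the centroid (ties broken
    lexicographically) and repeatedly moves to the nearest unvisited point.
    Returns the index permutation.
    """
    n = len(points)
    if n <= 1:
        return np.arange(n)
    d_from_centroid = np.linalg.norm(points - points.mean(axis=0), axis=1)
    start = int(np.lexsort((points[:, 1], points[:, 0], -d_from_centroid))[0])
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(n - 1):
        cur = points[order[-1]]
        dists = np.linalg.norm(points - cur, axis=1)
        dists[visited] = np.inf
        nxt = int(np.argmin(dists))
        order.append(nxt)
        visited[nxt] = True
    return np.array(order)


def _mean_chain_spacing(centroids: np.ndarray, pixels_xy: np.ndarray) -> float:
    """Spacing statistic driving the K-increment loop.

    For two or more nodes: mean distance between consecutive nodes in
    nearest-neighbour chain order.  For a single node there is no pair, so
    the node's reach (the maximum distance from it to any component pixel)
    stands in — a round lumen keeps its single centroid while a long thin
    component seen from its lone centroid still triggers splitting.
    """
    if len(centroids) >= 2:
        order = _chain_order(centroids)
        diffs = np.diff(centroids[order], axis=0)
        return float(np.linalg.norm(diffs, axis=1).mean())
    return float(np.linalg.norm(pixels_xy - centroids[0], axis=1).max())


def allocate_nodes(
    cs: CrossSection, max_mean_spacing: float = 20.0, random_state: int = 0
) -> list[Node]:
    """Place nodes on a cross section by K-means over its pixels.

    K starts at 1 and increments, reclustering each time, until the mean
    spacing between adjacent nodes (nearest-neighbour chain order) drops
    below ``max_mean_spacing``.  Centroids are rounded to the nearest
    pixel.  K is capped at the pixel count.
    """
    if max_mean_spacing <= 0:
        raise ValueError("max_mean_spacing must be > 0")
    pix = cs.pixels  # (N, 2) row, col
    if len(pix) == 0:
        raise ValueError("empty cross section")
    pts = np.column_stack([pix[:, 1], pix[:, 0]]).astype(float)  # x, y
    k = 1
    while True:
        if k == 1:
            centroids = pts.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=3, random_state=random_state)
            km.fit(pts)
            centroids = km.cluster_centers_
        if _mean_chain_spacing(centroids, pts) < max_mean_spacing or k >= len(pts):
            break
        k += 1
    order = _chain_order(centroids)
    nodes = []
    for i, ci in enumerate(order):
        cx, cy = centroids[ci]
        if not cs.contains_point(cx, cy, tol=1):
            # concave components can place a centroid off the mask; snap
            # it to the nearest component pixel so every node lies on it
            j = int(np.argmin(np.linalg.norm(pts - centroids[ci], axis=1)))
            cx, cy = pts[j]
        node = Node(
            x=int(round(cx)), y=int(round(cy)), z=cs.slice_index, cs_id=cs.cs_id, k=i
        )
        node.cross_section = cs
        nodes.append(node)
    return nodes


def compute_shape_factors(cs: CrossSection) -> ShapeFactors:
    """Shape factors from the component mask.

    circularity = 4*pi*area / perimeter^2 with the boundary-chain perimeter
    (diagonal steps weighted sqrt(2)); eccentricity and axis lengths from
    the moment-equivalent ellipse; solidity = area / convex hull area;
    aspect ratio = major / minor axis length.  One-pixel (and other
    degenerate) components fall back to eccentricity 0, aspect ratio 1,
    minor axis 1.
    """
    padded = np.pad(cs.mask, 1)  # regionprops perimeter needs a clear border
    rp = measure.regionprops(padded.astype(np.uint8))[0]
    area = float(rp.area)
    perim = float(rp.perimeter)
    circularity = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
    minor = float(rp.axis_minor_length)
    major = float(rp.axis_major_length)
    if minor < 1.0:
        # degenerate: single pixels and 1-px-wide lines
        if major < 1.0:
            return ShapeFactors(circularity, 0.0, float(rp.solidity), 1.0, area, 1.0)
        minor = 1.0
    return ShapeFactors(
        circularity=circularity,
        eccentricity=float(rp.eccentricity),
        solidity=float(rp.solidity),
        aspect_ratio=major / minor,
        area=area,
        minor_axis_length=minor,
    )


def compute_shape_profile(cs: CrossSection, node: Node) -> np.ndarray:
    """Centroidal shape profile: boundary radius at 24 angles from the node.

    The component boundary is extracted as an ordered closed sub-pixel
    contour; each boundary segment contributes the angle/radius pairs it
    crosses, and multivalued angles are resolved by keeping the *first*
    crossing along increasing radius (the local lumen outline).  Radii are
    linearly interpolated at the 15-degree grid angles.
    """
    if not cs.contains_point(node.x, node.y, tol=1):
        raise ValueError(f"node at ({node.x}, {node.y}) lies outside cross section {cs.cs_id}")
    padded = np.pad(cs.mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no closed boundary found for cross section")
    # reference point in padded-local coordinates
    ref_x = node.x - cs.bbox_origin[1] + 1
    ref_y = node.y - cs.bbox_origin[0] + 1
    grid = np.deg2rad(PROFILE_ANGLES_DEG)
    radii = np.full(N_PROFILE_ANGLES, np.inf)
    nearest_fallback = np.full(N_PROFILE_ANGLES, np.inf)
    for contour in contours:
        if not np.allclose(contour[0], contour[-1]):
            raise ValueError("open boundary encountered on a filled component")
        x = contour[:, 1] - ref_x
        y = contour[:, 0] - ref_y
        theta = np.arctan2(y, x)
        r = np.hypot(x, y)
        # fallback: nearest vertex per angle bin (used if no segment crossing)
        bins = np.round(theta / (np.pi / 12)).astype(int) % N_PROFILE_ANGLES
        for b, rv in zip(bins, r):
            nearest_fallback[b] = min(nearest_fallback[b], rv)
        for i in range(len(contour) - 1):
            t0, t1 = theta[i], theta[i + 1]
            r0, r1 = r[i], r[i + 1]
            span = np.angle(np.exp(1j * (t1 - t0)))  # signed short-arc difference
            if span == 0.0:
                continue
            for a_idx, a in enumerate(grid):
                off = np.angle(np.exp(1j * (a - t0)))
                t = off / span
                if 0.0 <= t <= 1.0:
                    rc = r0 + t * (r1 - r0)
                    if rc < radii[a_idx]:
                        radii[a_idx] = rc
    missing = ~np.isfinite(radii)
    radii[missing] = nearest_fallback[missing]
    radii[~np.isfinite(radii)] = 0.0  # node on the boundary itself
    return radii


@dataclass
class SliceFeatures:
    """All cross sections and nodes of one slice, plus a flat node index."""

    slice_index: int
    cross_sections: list[CrossSection]

    @property
    def nodes(self) -> list[Node]:
        return [n for cs in self.cross_sections for n in cs.nodes]


@dataclass
class StackFeatures:
    """Per-slice features for a whole binary stack."""

    slices: list[SliceFeatures]

    def __getitem__(self, slice_index: int) -> SliceFeatures:
        return self.slices[slice_index]

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[SliceFeatures]:
        return iter(self.slices)

    def node_positions(self, slice_index: int) -> np.ndarray:
        """(N, 2) x/y positions of every node on a slice."""
        nodes = self.slices[slice_index].nodes
        if not nodes:
            return np.empty((0, 2))
        return np.array([[n.x, n.y] for n in nodes], dtype=float)

    def find_node_near(self, x: float, y: float, z: int, max_dist: float = 15.0) -> Node | None:
        """Closest node to (x, y) on slice z within ``max_dist``, if any."""
        nodes = self.slices[z].nodes
        if not nodes:
            return None
        pos = self.node_positions(z)
        d = np.linalg.norm(pos - [x, y], axis=1)
        i = int(np.argmin(d))
        return nodes[i] if d[i] <= max_dist else None


def extract_slice_features(
    binary: np.ndarray,
    slice_index: int,
    max_mean_spacing: float = 20.0,
    random_state: int = 0,
) -> SliceFeatures:
    """Segment one binary slice and fill shape factors, nodes and profiles."""
    sections = segment_components(binary, slice_index)
    for cs in sections:
        cs.shape = compute_shape_factors(cs)
        cs.nodes = allocate_nodes(cs, max_mean_spacing, random_state)
        for node in cs.nodes:
            node.profile = compute_shape_profile(cs, node)
    return SliceFeatures(slice_index=slice_index, cross_sections=sections)


def extract_features(
    binary_stack: np.ndarray, max_mean_spacing: float = 20.0, random_state: int = 0
) -> StackFeatures:
    """Feature-extract every slice of a binary stack."""
    return StackFeatures(
        [
            extract_slice_features(binary_stack[i], i, max_mean_spacing, random_state)
            for i in range(len(binary_stack))
        ]
    )


def features_to_dataframe(feats: StackFeatures) -> pd.DataFrame:
    """One row per node: ids, position, shape factors, 24 profile radii."""
    rows = []
    for sf in feats:
        for cs in sf.cross_sections:
            factors = cs.shape.as_array() if cs.shape else np.full(6, np.nan)
            for node in cs.nodes:
                row: dict[str, float] = {
                    "slice": sf.slice_index,
                    "label": cs.label,
                    "k": node.k,
                    "x": node.x,
                    "y": node.y,
                }
                row.update(dict(zip(ShapeFactors.NAMES, factors)))
                prof = node.profile if node.profile is not None else np.full(24, np.nan)
                for a, r in zip(PROFILE_ANGLES_DEG.astype(int), prof):
                    row[f"r{a:03d}"] = r
                rows.append(row)
    return pd.DataFrame(rows)
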