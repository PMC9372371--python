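"""GFAP skeleton morphometry: preprocessing, thinning, and topology metrics.

The preprocessing cascade mirrors a classical astrocyte-process workflow on
bright-field micrographs with dark staining:

1. bandpass (difference of Gaussians passing structures between 3 and 40 px)
2. rolling-ball background subtraction (radius 200 px)
3. linear brightness/contrast rescale mapping [10, 254] -> [0, 255]
4. unsharp mask (sigma 1.5 px, weight 0.6)
5. despeckle (3x3 median)
6. binarisation by an inclusive intensity window [0, threshold_upper]
   (region-specific upper levels; stained structures are dark)
7. binary clean-up: despeckle, 3x3 closing, remove-outliers

The binary image is thinned to a unit-width 8-connected skeleton; skeleton
voxels are classified by their 8-neighbour count (endpoint < 2, slab = 2,
junction > 2), adjacent junction voxels are merged into single junctions,
and branches are traced as slab paths between endpoint/junction nodes with
Euclidean step lengths (1 or sqrt(2) pixels).  Connected skeleton pieces
consisting of a bare segment (exactly two endpoint voxels, no junctions)
shorter than the fragment cut-off (0.7 um) are discarded before the metric
totals, emulating the removal of thresholding debris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize
from skimage.transform import rescale as _rescale_image

from .images import Micrograph

__all__ = [
    "SkeletonConfig", "SkeletonGraph", "SkeletonMetrics", "Branch",
    "REGION_THRESHOLDS", "preprocess", "skeletonize_and_analyze",
]

#: region-specific upper binarisation levels (inclusive window [0, level])
REGION_THRESHOLDS = {"cc": 218, "layerV": 223, "layerVI": 219, "CA3b": 223}


@dataclass(frozen=True)
class SkeletonConfig:
    bandpass_large: float = 40.0     # px, largest structure passed
    bandpass_small: float = 3.0      # px, smallest structure passed
    rolling_ball_radius: int = 200   # px
    rescale_min: int = 10
    rescale_max: int = 254
    unsharp_sigma: float = 1.5       # px
    unsharp_weight: float = 0.6
    threshold_upper: int = 223       # default window; see REGION_THRESHOLDS
    outlier_radius: int = 2          # px, remove-outliers neighbourhood
    outlier_threshold: int = 50      # 8-bit levels
    fragment_cutoff: float = 0.7     # um

    def __post_init__(self) -> None:
        if not (0 <= self.threshold_upper <= 255):
            raise ValueError("threshold_upper must be an 8-bit level")
        if not (0 <= self.rescale_min < self.rescale_max <= 255):
            raise ValueError("rescale window must satisfy 0 <= min < max <= 255")
        if self.fragment_cutoff <= 0:
            raise ValueError("fragment_cutoff must be positive")
        if not (0 < self.unsharp_weight < 1):
            raise ValueError("unsharp_weight must be in (0, 1)")
        if self.bandpass_small >= self.bandpass_large:
            raise ValueError("bandpass_small must be below bandpass_large")

    @classmethod
    def for_region(cls, region: str, **overrides) -> "SkeletonConfig":
        if region not in REGION_THRESHOLDS:
            raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGION_THRESHOLDS)}")
        return cls(threshold_upper=REGION_THRESHOLDS[region], **overrides)


@dataclass
class Branch:
    path: np.ndarray        # (n, 2) voxel coordinates from node to node
    length_um: float
    component: int
    end_nodes: tuple[int, int]  # node ids (junction cluster or endpoint ids)


@dataclass
class SkeletonGraph:
    skeleton: np.ndarray          # bool, the surviving (filtered) skeleton
    endpoint_voxels: np.ndarray   # (n, 2)
    junction_voxels: np.ndarray   # (n, 2)
    junction_labels: np.ndarray   # int image; 0 outside junction voxels
    branches: list[Branch]
    n_components: int
    removed_fragments: int        # sub-cut-off pieces deleted before totals


@dataclass
class SkeletonMetrics:
    branches: int
    branch_length: float      # um, total
    slab_voxels: int
    junction_voxels: int
    junctions: int
    endpoint_voxels: int
    triple_points: int
    quadruple_points: int
    average_length: float     # um; NaN when there are no branches

    def as_dict(self) -> dict[str, float]:
        return {
            "branches": self.branches, "branch_length": self.branch_length,
            "slab_voxels": self.slab_voxels, "junction_voxels": self.junction_voxels,
            "junctions": self.junctions, "endpoint_voxels": self.endpoint_voxels,
            "triple_points": self.triple_points, "quadruple_points": self.quadruple_points,
            "average_length": self.average_length,
        }


# ---------------------------------------------------------------------------
# preprocessing cascade
# ---------------------------------------------------------------------------

def _rolling_ball_background(inverted: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background of a dark-background image.

    Large radii are evaluated on a downsampled copy (the background is
    smooth by construction) and resampled back, keeping the 200 px default
    tractable on megapixel tiles.
    """
    from skimage.restoration import rolling_ball

    shrink = max(1, int(radius // 25))
    if shrink > 1:
        small = _rescale_image(inverted, 1.0 / shrink, anti_aliasing=True,
                               preserve_range=True)
        bg_small = rolling_ball(small, radius=max(1, radius // shrink))
        bg = _rescale_image(bg_small, np.array(inverted.shape) / np.array(bg_small.shape),
                            preserve_range=True)
        # guard against interpolation shape drift
        bg = bg[: inverted.shape[0], : inverted.shape[1]]
        if bg.shape != inverted.shape:
            pad = [(0, inverted.shape[i] - bg.shape[i]) for i in range(2)]
            bg = np.pad(bg, pad, mode="edge")
    else:
        bg = rolling_ball(inverted, radius=radius)
    return np.minimum(bg, inverted)


def _remove_outliers(img: np.ndarray, radius: int, threshold: float,
                     direction: str = "bright") -> np.ndarray:
    """Replace a pixel by the local median when it deviates beyond threshold."""
    size = 2 * radius + 1
    med = ndi.median_filter(img, size=size, mode="reflect")
    if direction == "bright":
        outlier = img - med > threshold
    elif direction == "dark":
        outlier = med - img > threshold
    else:
        outlier = np.abs(img - med) > threshold
    out = img.copy()
    out[outlier] = med[outlier]
    return out


def preprocess(img: Micrograph, cfg: SkeletonConfig = SkeletonConfig()) -> np.ndarray:
    """Run the full grayscale-to-binary cascade; returns a boolean image."""
    f = img.pixels.astype(float)

    # 1. bandpass: suppress structures larger than bandpass_large and
    # smaller than bandpass_small; DC restored so the background stays bright
    sigma_large = cfg.bandpass_large / 2.0
    sigma_small = cfg.bandpass_small / 2.0
    low = ndi.gaussian_filter(f, sigma_large, mode="reflect")
    f = ndi.gaussian_filter(f - low, sigma_small, mode="reflect") + f.mean()
    f = np.clip(f, 0, 255)

    # 2. rolling-ball background subtraction (light background, dark stain)
    inverted = 255.0 - f
    bg = _rolling_ball_background(inverted, cfg.rolling_ball_radius)
    f = 255.0 - (inverted - bg)

    # 3. brightness/contrast rescale
    f = np.clip((f - cfg.rescale_min) * 255.0 / (cfg.rescale_max - cfg.rescale_min), 0, 255)

    # 4. unsharp mask
    blurred = ndi.gaussian_filter(f, cfg.unsharp_sigma, mode="reflect")
    f = np.clip((f - cfg.unsharp_weight * blurred) / (1.0 - cfg.unsharp_weight), 0, 255)

    # 5. despeckle
    f = ndi.median_filter(f, size=3, mode="reflect")

    # 6. threshold: inclusive window [0, upper]; stain is dark
    binary = f <= cfg.threshold_upper

    # 7. binary clean-up: despeckle, closing, remove outliers
    binary = ndi.median_filter(binary.astype(np.uint8), size=3, mode="reflect").astype(bool)
    binary = ndi.binary_closing(binary, structure=np.ones((3, 3)), border_value=0)
    as_gray = binary.astype(np.uint8) * 255
    as_gray = _remove_outliers(as_gray, cfg.outlier_radius, cfg.outlier_threshold,
                               direction="bright")
    return as_gray > 127


# ---------------------------------------------------------------------------
# skeleton analysis
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_STRUCT8 = np.ones((3, 3), dtype=int)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def _neighbors_of(r: int, c: int, skel: np.ndarray):
    h, w = skel.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                yield rr, cc


def _analyze_skeleton(skel: np.ndarray, pixel_size: float):
    """Classify voxels, merge junction clusters, trace branches.

    Returns (endpoint coords, junction coords, junction label image,
    branches, component label image, n_components).
    """
    ncount = _neighbor_counts(skel).astype(np.int16)
    ncount[~skel] = -1
    endpoint_mask = skel & (ncount < 2)
    junction_mask = skel & (ncount > 2)
    slab_mask = skel & (ncount == 2)

    junction_labels, _ = ndi.label(junction_mask, structure=_STRUCT8)
    comp_labels, n_comp = ndi.label(skel, structure=_STRUCT8)

    # node id space: junction cluster j -> ("J", j); endpoint voxel -> ("E", idx)
    endpoint_coords = np.argwhere(endpoint_mask)
    endpoint_id = {tuple(p): i for i, p in enumerate(endpoint_coords)}

    def node_of(r, c):
        if junction_labels[r, c]:
            return ("J", int(junction_labels[r, c]))
        if endpoint_mask[r, c]:
            return ("E", endpoint_id[(r, c)])
        return None

    visited_slab = np.zeros_like(skel, dtype=bool)
    branches: list[Branch] = []
    seen_direct = set()  # node-node steps with no slab in between

    node_voxels = np.argwhere(endpoint_mask | junction_mask)
    for r, c in node_voxels:
        start_node = node_of(r, c)
        for nr, nc in _neighbors_of(r, c, skel):
            nb_node = node_of(nr, nc)
            if nb_node is not None:
                # direct node-to-node contact; adjacent voxels of one
                # junction cluster are not a branch
                if nb_node == start_node:
                    continue
                key = frozenset((start_node, nb_node))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                length = float(np.hypot(nr - r, nc - c)) * pixel_size
                branches.append(Branch(
                    path=np.array([[r, c], [nr, nc]]), length_um=length,
                    component=int(comp_labels[r, c]), end_nodes=(start_node, nb_node)))
                continue
            if visited_slab[nr, nc]:
                continue
            # walk the slab path until the next node voxel
            path = [(r, c), (nr, nc)]
            visited_slab[nr, nc] = True
            prev, cur = (r, c), (nr, nc)
            while True:
                nxt = None
                for xr, xc in _neighbors_of(cur[0], cur[1], skel):
                    if (xr, xc) == prev:
                        continue
                    # avoid stepping back into the start node cluster corner
                    if (xr, xc) == (r, c):
                        continue
                    nxt = (xr, xc)
                    # prefer a node voxel when both a node and slab touch
                    if node_of(xr, xc) is not None:
                        break
                if nxt is None:
                    break  # dead end inside slab (should not occur)
                path.append(nxt)
                end_node = node_of(*nxt)
                if end_node is not None:
                    break
                visited_slab[nxt[0], nxt[1]] = True
                prev, cur = cur, nxt
            arr = np.array(path, dtype=float)
            length = float(np.hypot(*np.diff(arr, axis=0).T).sum()) * pixel_size
            end_node = node_of(*path[-1])
            if end_node is None:
                end_node = ("E", -1)  # open slab end; degenerate, keep traceable
            branches.append(Branch(
                path=np.array(path), length_um=length,
                component=int(comp_labels[r, c]),
                end_nodes=(start_node, end_node)))

    # pure cycles: slab voxels never visited and not adjacent to any node
    remaining = slab_mask & ~visited_slab
    # slab voxels adjacent to nodes were traversed as path interiors already
    # unless they form node-free loops
    cyc_labels, n_cyc = ndi.label(remaining, structure=_STRUCT8)
    for ci in range(1, n_cyc + 1):
        coords = np.argwhere(cyc_labels == ci)
        # skip voxels that belong to branches already traced (visited check
        # above) -- any remaining cluster with all neighbor counts == 2 and
        # no adjacent node voxel is a closed loop
        touches_node = False
        for r, c in coords:
            for nr, nc in _neighbors_of(r, c, skel):
                if endpoint_mask[nr, nc] or junction_mask[nr, nc]:
                    touches_node = True
                    break
            if touches_node:
                break
        if touches_node:
            continue
        # trace the loop once
        start = tuple(coords[0])
        path = [start]
        prev, cur = None, start
        while True:
            nxt = None
            for xr, xc in _neighbors_of(cur[0], cur[1], skel):
                if (xr, xc) != prev and cyc_labels[xr, xc] == ci:
                    nxt = (xr, xc)
                    break
            if nxt is None or nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
            if len(path) > coords.shape[0]:
                break
        path.append(start)
        arr = np.array(path, dtype=float)
        length = float(np.hypot(*np.diff(arr, axis=0).T).sum()) * pixel_size
        branches.append(Branch(path=np.array(path), length_um=length,
                               component=int(comp_labels[start]),
                               end_nodes=(("L", ci), ("L", ci))))

    return (endpoint_coords, np.argwhere(junction_mask), junction_labels,
            branches, comp_labels, n_comp)


def _fuse_junctions(branches: list[Branch], junction_labels: np.ndarray,
                    pixel_size: float, fusion_px: float):
    """Merge junction clusters joined by a slab connector shorter than
    ``fusion_px`` pixels.

    Thinning splits a 4-way crossing into two triple-point clusters one or
    two voxels apart; contracting such sub-resolution connectors restores
    the single quadruple junction.  Returns the filtered branch list and a
    relabelled junction image.
    """
    n = int(junction_labels.max())
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    drop_idx = set()
    order = sorted(range(len(branches)), key=lambda i: branches[i].length_um)
    for idx in order:
        b = branches[idx]
        (k1, id1), (k2, id2) = b.end_nodes
        if k1 == "J" and k2 == "J" and b.length_um <= fusion_px * pixel_size:
            r1, r2 = find(id1), find(id2)
            if r1 != r2:
                parent[max(r1, r2)] = min(r1, r2)
            # drop either way: a short path re-entering an already-fused
            # cluster is a thinning loop at the crossing, not a branch
            drop_idx.add(idx)

    if not drop_idx:
        return branches, junction_labels

    # compact relabelling of the fused clusters
    roots = sorted({find(i) for i in range(1, n + 1)})
    new_id = {r: i + 1 for i, r in enumerate(roots)}
    mapping = np.zeros(n + 1, dtype=junction_labels.dtype)
    for i in range(1, n + 1):
        mapping[i] = new_id[find(i)]
    fused_labels = mapping[junction_labels]

    fused_branches = []
    for idx, b in enumerate(branches):
        if idx in drop_idx:
            continue
        nodes = tuple((k, int(mapping[i]) if k == "J" else i) for k, i in b.end_nodes)
        fused_branches.append(Branch(path=b.path, length_um=b.length_um,
                                     component=b.component, end_nodes=nodes))
    return fused_branches, fused_labels


def _metrics_from(skel: np.ndarray, endpoint_coords, junction_coords,
                  junction_labels, branches, pixel_size: float) -> SkeletonMetrics:
    n_branches = len(branches)
    total_len = float(sum(b.length_um for b in branches))
    # branches emanating per junction cluster (a loop anchored at a junction
    # contributes both of its ends)
    from collections import Counter

    incident = Counter()
    for b in branches:
        for node in b.end_nodes:
            if node[0] == "J":
                incident[node[1]] += 1
    triple = sum(1 for v in incident.values() if v == 3)
    quad = sum(1 for v in incident.values() if v == 4)
    n_junctions = int(junction_labels.max())
    ncount = _neighbor_counts(skel)
    slab_voxels = int(np.sum(skel & (ncount == 2) & (junction_labels == 0)))
    return SkeletonMetrics(
        branches=n_branches,
        branch_length=total_len,
        slab_voxels=slab_voxels,
        junction_voxels=int(len(junction_coords)),
        junctions=n_junctions,
        endpoint_voxels=int(len(endpoint_coords)),
        triple_points=triple,
        quadruple_points=quad,
        average_length=total_len / n_branches if n_branches else float("nan"),
    )


def skeletonize_and_analyze(
    binary: np.ndarray,
    pixel_size: float,
    cutoff: float = 0.7,
    junction_fusion_px: float = 10.0,
) -> tuple[SkeletonGraph, SkeletonMetrics]:
    """Thin a binary image and extract skeleton topology metrics.

    ``cutoff`` (um) is the fragment filter: connected skeleton pieces with
    exactly two endpoint voxels, no junctions, and total length below the
    cut-off are deleted before totals; isolated single-voxel components
    (zero length) fall under the same rule.  Pass ``cutoff=0`` to disable.

    ``junction_fusion_px`` merges junction clusters whose connecting slab
    path is at most that many pixels long (thinning artefact at 4-way
    crossings); set to 0 to keep raw clusters.
    """
    binary = np.asarray(binary)
    if binary.dtype != bool:
        vals = np.unique(binary)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("skeletonize_and_analyze expects a binary image")
        binary = binary.astype(bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    skel = _skimage_skeletonize(binary)
    (endpoint_coords, junction_coords, junction_labels,
     branches, comp_labels, n_comp) = _analyze_skeleton(skel, pixel_size)
    if junction_fusion_px > 0:
        branches, junction_labels = _fuse_junctions(
            branches, junction_labels, pixel_size, junction_fusion_px)

    removed = 0
    if cutoff > 0 and n_comp:
        # per-component tallies for the fragment rule
        ep_per_comp = np.bincount(
            comp_labels[tuple(endpoint_coords.T)] if len(endpoint_coords) else np.array([], int),
            minlength=n_comp + 1)
        jn_per_comp = np.zeros(n_comp + 1, dtype=int)
        if len(junction_coords):
            jc = comp_labels[tuple(junction_coords.T)]
            np.add.at(jn_per_comp, jc, 1)
        len_per_comp = np.zeros(n_comp + 1)
        for b in branches:
            len_per_comp[b.component] += b.length_um
        size_per_comp = np.bincount(comp_labels.ravel(), minlength=n_comp + 1)
        drop = {ci for ci in range(1, n_comp + 1)
                if (ep_per_comp[ci] == 2 and jn_per_comp[ci] == 0
                    and len_per_comp[ci] < cutoff)
                or size_per_comp[ci] == 1}
        if drop:
            removed = len(drop)
            keep_mask = ~np.isin(comp_labels, list(drop)) & skel
            skel = keep_mask
            (endpoint_coords, junction_coords, junction_labels,
             branches, comp_labels, n_comp) = _analyze_skeleton(skel, pixel_size)
            if junction_fusion_px > 0:
                branches, junction_labels = _fuse_junctions(
                    branches, junction_labels, pixel_size, junction_fusion_px)

    metrics = _metrics_from(skel, endpoint_coords, junction_coords,
                            junction_labels, branches, pixel_size)
    graph = SkeletonGraph(
        skeleton=skel,
        endpoint_voxels=endpoint_coords,
        junction_voxels=junction_coords,
        junction_labels=junction_labels,
        branches=branches,
        n_components=n_comp,
        removed_fragments=removed,
    )
    return graph, metrics


def analyze_micrograph(img: Micrograph, cfg: SkeletonConfig = SkeletonConfig()
                       ) -> tuple[SkeletonGraph, SkeletonMetrics]:
    """Full cascade: preprocess then skeletonise and analyse one micrograph."""
    binary = preprocess(img, cfg)
    return skeletonize_and_analyze(binary, img.pixel_size, cutoff=cfg.fragment_cutoff)
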