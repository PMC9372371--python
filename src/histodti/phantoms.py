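"""Synthetic micrographs and cohort tables with known ground truth.

Four generators emulate the inputs of the DTI-histology pipeline:

* :func:`generate_nissl` — dark cell somata on a bright background at a
  known density (fixture for automated cell counting),
* :func:`generate_fibers` — oriented dark fiber textures with a
  controllable von-Mises orientation dispersion (fixture for
  structure-tensor anisotropy),
* :func:`generate_astrocytes` — branching tree structures with an exactly
  recorded skeleton topology (fixture for skeleton morphometry),
* :func:`generate_cohort` — an animals x regions table in which each
  histological parameter is an exact linear function of the five DTI
  predictors (FA, RD, MD, CP, CS) plus Gaussian noise.

Every generator is driven by a single integer seed; internally each
operation uses its own spawned random stream so that, e.g., adding cells
to a scene never perturbs the fiber draws of another generator run with
the same global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation as _gray_dilation, disk as disk_footprint


def binary_dilation(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return _gray_dilation(mask.astype(np.uint8), footprint).astype(bool)

from .dti import compute_scalar_metrics, EigenvalueTriple
from .images import Micrograph

__all__ = [
    "NisslPhantomSpec", "GroundTruthCells", "generate_nissl",
    "FiberPhantomSpec", "GroundTruthOrientation", "generate_fibers",
    "AstroPhantomSpec", "GroundTruthSkeleton", "generate_astrocytes",
    "CohortSpec", "ResponseSpec", "generate_cohort", "calibrate_noise_sd",
    "DEFAULT_EIGENVALUE_DISTRIBUTIONS", "REGIONS",
]

# stream-split tags: one global seed, one independent stream per generator
_STREAMS = {"nissl": 0, "fibers": 1, "astro": 2, "cohort": 3}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[op],)))


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Nissl-like cell phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NisslPhantomSpec:
    """Dark, roughly circular somata on a bright background.

    Defaults follow high-magnification Nissl photomicrographs digitised at
    0.114 um/pixel: somata of 2.5-5 um radius, stained dark (~60) on a
    bright (~200) background.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.114  # um / pixel
    n_cells: int = 50
    cell_radius_range: tuple[float, float] = (2.5, 5.0)  # um
    cell_intensity: int = 60
    background_intensity: int = 200
    noise_sd: float = 0.0
    min_center_distance: float | None = None  # um; default 2*max radius + 1
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 <= self.cell_intensity < self.background_intensity <= 255):
            raise ValueError("need 0 <= cell_intensity < background_intensity <= 255")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell radii must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def resolved_min_distance(self) -> float:
        if self.allow_touching:
            return 0.0
        if self.min_center_distance is not None:
            return self.min_center_distance
        return 2.0 * self.cell_radius_range[1] + 1.0


@dataclass
class GroundTruthCells:
    centers: np.ndarray        # (n, 2) row/col pixel coordinates
    radii_um: np.ndarray       # (n,)
    count: int
    ideal_mask: np.ndarray     # boolean union of the stamped disks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": self.centers[:, 0], "col": self.centers[:, 1], "radius_um": self.radii_um}
        )


def generate_nissl(spec: NisslPhantomSpec) -> tuple[Micrograph, GroundTruthCells]:
    """Render a cell phantom; placement respects ``min_center_distance``.

    Raises ``RuntimeError`` when the spec is too crowded to place all cells
    within a bounded number of rejection-sampling retries.
    """
    rng = _rng(spec.seed, "nissl")
    h, w = spec.image_size
    rmin_px, rmax_px = (r / spec.pixel_size for r in spec.cell_radius_range)
    min_dist_px = spec.resolved_min_distance / spec.pixel_size

    centers: list[tuple[float, float]] = []
    radii_px: list[float] = []
    max_tries = max(1000, 300 * spec.n_cells)
    tries = 0
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with min distance "
                f"{spec.resolved_min_distance} um after {max_tries} tries: spec is overcrowded"
            )
        r = rng.uniform(rmin_px, rmax_px)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if min_dist_px > 0 and centers:
            d = np.hypot(np.array([c[0] for c in centers]) - cy,
                         np.array([c[1] for c in centers]) - cx)
            if np.any(d < min_dist_px):
                continue
        centers.append((cy, cx))
        radii_px.append(r)

    img = np.full((h, w), float(spec.background_intensity))
    mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), r in zip(centers, radii_px):
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        img[rr, cc] = spec.cell_intensity
        mask[rr, cc] = True

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    truth = GroundTruthCells(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        radii_um=np.array(radii_px, dtype=float) * spec.pixel_size,
        count=len(centers),
        ideal_mask=mask,
    )
    return Micrograph(_quantize(img), spec.pixel_size), truth


# ---------------------------------------------------------------------------
# Oriented fiber phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberPhantomSpec:
    """Dark line-segment fibers with von-Mises-distributed orientations.

    ``dispersion_kappa`` is the concentration of the axial orientation
    distribution (applied on the doubled angle, so kappa = 0 yields
    uniformly distributed orientations on [0, pi)).
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.114
    mean_orientation: float = 0.0  # radians, 0 = along image rows' axis (x)
    dispersion_kappa: float = 8.0
    n_fibers: int = 60
    fiber_width: float = 1.0  # um
    fiber_intensity: int = 70
    background_intensity: int = 210
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_kappa < 0:
            raise ValueError("dispersion_kappa must be >= 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if not (0 <= self.fiber_intensity < self.background_intensity <= 255):
            raise ValueError("need fiber_intensity < background_intensity in 8-bit range")
        if self.fiber_width <= 0 or self.pixel_size <= 0:
            raise ValueError("fiber_width and pixel_size must be positive")


@dataclass
class GroundTruthOrientation:
    orientations: np.ndarray  # drawn fiber orientations, radians in [0, pi)
    mean_orientation: float
    circular_variance: float  # 1 - |mean(exp(2i theta))|, axial statistics


#: cap applied to very large concentrations so sampling stays stable
_KAPPA_CAP = 1e6


def generate_fibers(spec: FiberPhantomSpec) -> tuple[Micrograph, GroundTruthOrientation]:
    """Render anti-aliased fiber segments and record the drawn orientations."""
    rng = _rng(spec.seed, "fibers")
    h, w = spec.image_size

    kappa = min(spec.dispersion_kappa, _KAPPA_CAP)
    if kappa == 0:
        theta = rng.uniform(0.0, np.pi, size=spec.n_fibers)
    elif kappa >= _KAPPA_CAP:
        theta = np.full(spec.n_fibers, spec.mean_orientation % np.pi)
    else:
        # axial von Mises: draw the doubled angle, halve it
        phi = rng.vonmises(0.0, kappa, size=spec.n_fibers)
        theta = (spec.mean_orientation + phi / 2.0) % np.pi

    if spec.n_fibers:
        z = np.exp(2j * theta)
        circ_var = 1.0 - float(np.abs(z.mean()))
    else:
        circ_var = float("nan")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coverage = np.zeros((h, w))
    half_width_px = 0.5 * spec.fiber_width / spec.pixel_size
    half_len = 0.75 * float(np.hypot(h, w))

    for t in theta:
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        # direction of the fiber axis; x = columns, y = rows (y axis points down)
        dx, dy = np.cos(t), -np.sin(t)
        rel_x = xx - cx
        rel_y = yy - cy
        longitudinal = rel_x * dx + rel_y * dy
        transverse = np.abs(rel_x * (-dy) + rel_y * dx)
        # anti-aliased coverage: 1 inside the band, linear rolloff over 1 px
        cov = np.clip(half_width_px + 0.5 - transverse, 0.0, 1.0)
        cov[np.abs(longitudinal) > half_len] = 0.0
        np.maximum(coverage, cov, out=coverage)

    img = spec.background_intensity - (spec.background_intensity - spec.fiber_intensity) * coverage
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    truth = GroundTruthOrientation(
        orientations=theta,
        mean_orientation=spec.mean_orientation % np.pi,
        circular_variance=circ_var,
    )
    return Micrograph(_quantize(img), spec.pixel_size), truth


# ---------------------------------------------------------------------------
# Astrocyte-like branching phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AstroPhantomSpec:
    """Branching tree structures with exactly known skeleton topology.

    Each tree has ``branches_per_soma`` primary processes radiating from a
    single root; at every level below ``branching_depth`` a process tip
    splits into two children.  Centerlines are stamped as 8-connected
    Bresenham segments, then dilated to ``process_width``, so the
    ground-truth topology (branch / junction / endpoint / triple /
    quadruple counts and centerline length) is unambiguous.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.114
    n_somata: int = 3
    branches_per_soma: tuple[int, int] = (3, 4)   # inclusive count range
    branch_length: tuple[float, float] = (5.0, 9.0)  # um, per segment
    branching_depth: int = 2                      # 1 = primary branches only
    process_width: float = 1.0                    # um
    tree_intensity: int = 60
    background_intensity: int = 240
    noise_sd: float = 0.0
    n_fragments: int = 0                          # planted sub-cutoff debris segments
    fragment_length: tuple[float, float] = (0.3, 0.45)  # um, below the 0.7 um cut-off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_somata < 0 or self.n_fragments < 0:
            raise ValueError("counts must be >= 0")
        if self.branching_depth < 1:
            raise ValueError("branching_depth must be >= 1")
        if not (2 <= self.branches_per_soma[0] <= self.branches_per_soma[1] <= 6):
            raise ValueError("branches_per_soma range must lie within [2, 6]")
        if self.branch_length[0] <= 0 or self.process_width <= 0:
            raise ValueError("lengths and widths must be positive")


@dataclass
class GroundTruthSkeleton:
    branches: int
    junctions: int
    endpoints: int
    triple_points: int
    quadruple_points: int
    total_length_um: float
    per_tree: list[dict] = field(default_factory=list)
    n_fragments: int = 0
    fragment_lengths_um: np.ndarray | None = None
    centerline_mask: np.ndarray | None = None
    ideal_mask: np.ndarray | None = None


def _bresenham_path_length(r0: int, c0: int, r1: int, c1: int, pixel_size: float):
    """8-connected raster segment plus its geometric step length in um."""
    rr, cc = draw_line(r0, c0, r1, c1)
    steps = np.hypot(np.diff(rr.astype(float)), np.diff(cc.astype(float)))
    return rr, cc, float(steps.sum() * pixel_size)


def _tree_reach_px(spec: AstroPhantomSpec) -> float:
    return spec.branching_depth * (spec.branch_length[1] / spec.pixel_size) + \
        spec.process_width / spec.pixel_size + 4


def generate_astrocytes(spec: AstroPhantomSpec) -> tuple[Micrograph, GroundTruthSkeleton]:
    """Render non-touching branching trees with recorded topology.

    Raises ``RuntimeError`` if the somata cannot be placed with
    non-overlapping reach discs after bounded retries.
    """
    rng = _rng(spec.seed, "astro")
    h, w = spec.image_size
    reach = _tree_reach_px(spec)
    if 2 * reach + 2 >= min(h, w) and spec.n_somata > 0:
        raise RuntimeError("image too small for even one tree at this spec")

    # place somata so trees (reach discs) cannot touch; greedy sampling with
    # full restarts when a partial placement blocks the rest
    somata: list[tuple[int, int]] = []
    for _restart in range(80):
        somata = []
        tries = 0
        while len(somata) < spec.n_somata and tries < 400 * max(spec.n_somata, 1):
            tries += 1
            cy = int(rng.uniform(reach + 1, h - reach - 1))
            cx = int(rng.uniform(reach + 1, w - reach - 1))
            if any(np.hypot(cy - sy, cx - sx) < 2 * reach + 3 for sy, sx in somata):
                continue
            somata.append((cy, cx))
        if len(somata) == spec.n_somata:
            break
    else:
        raise RuntimeError(
            f"could not place {spec.n_somata} non-touching trees "
            f"(reach {reach:.0f} px) in a {h}x{w} image"
        )

    centerline = np.zeros((h, w), dtype=bool)
    per_tree: list[dict] = []
    seg_len_range_px = (spec.branch_length[0] / spec.pixel_size,
                        spec.branch_length[1] / spec.pixel_size)
    radius_px = max(1, int(round(0.5 * spec.process_width / spec.pixel_size)))
    # unrelated branches must stay this far apart so dilation and thinning
    # cannot merge them; segments sharing a node are exempt near that node
    min_sep_px = 2 * radius_px + 4.0
    node_excl_px = 2.0 * min_sep_px

    def _collides(p0, p1, segments, shared_nodes) -> bool:
        n_pts = max(2, int(np.hypot(p1[0] - p0[0], p1[1] - p0[1])))
        ts = np.linspace(0.0, 1.0, n_pts + 1)
        pts = np.stack([p0[0] + ts * (p1[0] - p0[0]), p0[1] + ts * (p1[1] - p0[1])], axis=1)
        for (q0, q1) in segments:
            mask = np.ones(len(pts), dtype=bool)
            for node in shared_nodes:
                if (abs(q0[0] - node[0]) < 1 and abs(q0[1] - node[1]) < 1) or \
                   (abs(q1[0] - node[0]) < 1 and abs(q1[1] - node[1]) < 1):
                    d_node = np.hypot(pts[:, 0] - node[0], pts[:, 1] - node[1])
                    mask &= d_node > node_excl_px
            if not mask.any():
                continue
            d = np.asarray(q1, float) - np.asarray(q0, float)
            L2 = float(d @ d)
            rel = pts[mask] - np.asarray(q0, float)
            t = np.clip(rel @ d / L2, 0.0, 1.0) if L2 > 0 else np.zeros(mask.sum())
            proj = np.asarray(q0, float) + t[:, None] * d
            if np.min(np.hypot(*(pts[mask] - proj).T)) < min_sep_px:
                return True
        return False

    all_segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for cy, cx in somata:
        committed = None
        for _tree_try in range(40):
            n_primary = int(rng.integers(spec.branches_per_soma[0],
                                         spec.branches_per_soma[1] + 1))
            base = rng.uniform(0, 2 * np.pi)
            jitter_span = 0.25 * (2 * np.pi / n_primary)
            segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
            stats = dict(branches=0, length_um=0.0, endpoints=0, d3=0, d4=0)
            if n_primary == 3:
                stats["d3"] += 1
            elif n_primary == 4:
                stats["d4"] += 1
            frontier: list[tuple[int, int, float, int]] = [
                (cy, cx, base + 2 * np.pi * i / n_primary
                 + rng.uniform(-jitter_span, jitter_span), 1)
                for i in range(n_primary)
            ]
            failed = False
            while frontier and not failed:
                r0, c0, ang0, depth = frontier.pop()
                placed = False
                for _seg_try in range(40):
                    ang = ang0 if _seg_try == 0 else ang0 + rng.uniform(-0.35, 0.35)
                    seg_len = rng.uniform(*seg_len_range_px)
                    r1 = int(round(r0 - seg_len * np.sin(ang)))
                    c1 = int(round(c0 + seg_len * np.cos(ang)))
                    if not (2 <= r1 < h - 2 and 2 <= c1 < w - 2):
                        continue
                    if _collides((r0, c0), (r1, c1),
                                 segments + all_segments, [(r0, c0)]):
                        continue
                    placed = True
                    break
                if not placed:
                    failed = True
                    break
                segments.append(((r0, c0), (r1, c1)))
                _, _, lum = _bresenham_path_length(r0, c0, r1, c1, spec.pixel_size)
                stats["branches"] += 1
                stats["length_um"] += lum
                if depth < spec.branching_depth:
                    # binary split: children fan out from the parent direction
                    stats["d3"] += 1
                    spread = rng.uniform(np.pi / 5, np.pi / 3.2)
                    for sign in (-1.0, 1.0):
                        frontier.append((r1, c1, ang + sign * spread, depth + 1))
                else:
                    stats["endpoints"] += 1
            if not failed:
                committed = (segments, stats)
                break
        if committed is None:
            raise RuntimeError("could not grow a collision-free tree; spec too dense")
        segments, stats = committed
        for (p0, p1) in segments:
            rr, cc, _ = _bresenham_path_length(p0[0], p0[1], p1[0], p1[1], spec.pixel_size)
            centerline[rr, cc] = True
        all_segments.extend(segments)
        per_tree.append(dict(
            branches=stats["branches"], junctions=stats["d3"] + stats["d4"],
            endpoints=stats["endpoints"], triple_points=stats["d3"],
            quadruple_points=stats["d4"], total_length_um=stats["length_um"],
            soma=(cy, cx),
        ))

    # planted sub-cut-off fragments: short isolated thin segments
    frag_lengths: list[float] = []
    fragment_centerlines: list[tuple[np.ndarray, np.ndarray]] = []
    guard = binary_dilation(centerline, disk_footprint(
        int(np.ceil(spec.process_width / spec.pixel_size)) + 6))
    tries = 0
    while len(frag_lengths) < spec.n_fragments:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place isolated debris fragments")
        flen_px = rng.uniform(spec.fragment_length[0] / spec.pixel_size,
                              spec.fragment_length[1] / spec.pixel_size)
        flen_px = max(flen_px, 1.0)
        ang = rng.uniform(0, 2 * np.pi)
        r0 = int(rng.uniform(10, h - 10))
        c0 = int(rng.uniform(10, w - 10))
        r1 = int(round(r0 - flen_px * np.sin(ang)))
        c1 = int(round(c0 + flen_px * np.cos(ang)))
        rr, cc, lum = _bresenham_path_length(r0, c0, r1, c1, spec.pixel_size)
        box = guard[max(rr.min() - 8, 0):rr.max() + 9, max(cc.min() - 8, 0):cc.max() + 9]
        if box.any():
            continue
        fragment_centerlines.append((rr, cc))
        guard[max(rr.min() - 8, 0):rr.max() + 9, max(cc.min() - 8, 0):cc.max() + 9] = True
        frag_lengths.append(lum)

    ideal = binary_dilation(centerline, disk_footprint(radius_px))
    for rr, cc in fragment_centerlines:
        frag = np.zeros((h, w), dtype=bool)
        frag[rr, cc] = True
        ideal |= binary_dilation(frag, disk_footprint(1))
        centerline[rr, cc] = True

    img = np.full((h, w), float(spec.background_intensity))
    img[ideal] = spec.tree_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    truth = GroundTruthSkeleton(
        branches=sum(t["branches"] for t in per_tree),
        junctions=sum(t["triple_points"] + t["quadruple_points"] for t in per_tree),
        endpoints=sum(t["endpoints"] for t in per_tree),
        triple_points=sum(t["triple_points"] for t in per_tree),
        quadruple_points=sum(t["quadruple_points"] for t in per_tree),
        total_length_um=sum(t["total_length_um"] for t in per_tree),
        per_tree=per_tree,
        n_fragments=len(frag_lengths),
        fragment_lengths_um=np.array(frag_lengths, dtype=float),
        centerline_mask=centerline,
        ideal_mask=ideal,
    )
    return Micrograph(_quantize(img), spec.pixel_size), truth


# ---------------------------------------------------------------------------
# Cohort tables with a known linear DTI -> histology relation
# ---------------------------------------------------------------------------

REGIONS = ("cc", "layerV", "layerVI", "CA3b")
PREDICTORS = ("FA", "RD", "MD", "CP", "CS")

#: per (group, region) eigenvalue means and SDs in mm^2/s, emulating rat
#: brain at 7 T: anisotropic corpus callosum, near-isotropic cortex, and a
#: CA3b whose diffusion geometry shifts after status epilepticus (higher
#: FA, lower CS), as the in vivo effect-size tables indicate.
DEFAULT_EIGENVALUE_DISTRIBUTIONS: dict[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...]]] = {
    ("C", "cc"): ((1.65e-3, 0.40e-3, 0.25e-3), (0.10e-3, 0.06e-3, 0.05e-3)),
    ("SE", "cc"): ((1.55e-3, 0.52e-3, 0.38e-3), (0.10e-3, 0.06e-3, 0.05e-3)),
    ("C", "layerV"): ((1.10e-3, 0.85e-3, 0.75e-3), (0.08e-3, 0.06e-3, 0.06e-3)),
    ("SE", "layerV"): ((1.05e-3, 0.82e-3, 0.70e-3), (0.08e-3, 0.06e-3, 0.06e-3)),
    ("C", "layerVI"): ((0.95e-3, 0.68e-3, 0.55e-3), (0.08e-3, 0.06e-3, 0.05e-3)),
    ("SE", "layerVI"): ((1.08e-3, 0.70e-3, 0.50e-3), (0.08e-3, 0.06e-3, 0.05e-3)),
    ("C", "CA3b"): ((0.90e-3, 0.72e-3, 0.62e-3), (0.07e-3, 0.05e-3, 0.05e-3)),
    ("SE", "CA3b"): ((1.25e-3, 0.75e-3, 0.52e-3), (0.08e-3, 0.06e-3, 0.05e-3)),
}


@dataclass(frozen=True)
class ResponseSpec:
    """True linear relation of one histological parameter to (FA, RD, MD, CP, CS)."""

    b: tuple[float, float, float, float, float]
    c: float
    noise_sd: float


def _default_responses() -> dict[str, ResponseSpec]:
    # anisotropy-index-like response; noise_sd calibrated once via
    # calibrate_noise_sd (fixed internal draw) so the population R^2 is 0.8
    # under the default eigenvalue distributions.
    return {"AI_myelin": ResponseSpec(b=(0.8, -300.0, 150.0, 0.5, -0.4), c=0.30,
                                      noise_sd=0.12905)}


@dataclass(frozen=True)
class CohortSpec:
    """K animals x J regions with a known linear DTI -> histology relation.

    The default cohort matches the study design the pipeline targets:
    17 animals (4 controls, 13 status-epilepticus survivors pooled across
    induction models) by 4 brain regions, i.e. 68 rows.
    """

    K: int = 17
    J: int = 4
    group_labels: tuple[str, ...] = ("C",) * 4 + ("SE",) * 13
    region_names: tuple[str, ...] = REGIONS
    eigenvalue_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_EIGENVALUE_DISTRIBUTIONS))
    responses: dict = field(default_factory=_default_responses)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_labels) != self.K:
            raise ValueError(f"need {self.K} group labels, got {len(self.group_labels)}")
        if len(self.region_names) != self.J:
            raise ValueError(f"need {self.J} region names, got {len(self.region_names)}")
        for g in set(self.group_labels):
            for r in self.region_names:
                if (g, r) not in self.eigenvalue_distributions:
                    raise ValueError(f"no eigenvalue distribution for group {g!r}, region {r!r}")


def _draw_triple(rng: np.random.Generator, means, sds) -> EigenvalueTriple:
    for _ in range(1000):
        lam = rng.normal(means, sds)
        if lam[0] >= lam[1] >= lam[2] > 0:
            return EigenvalueTriple(*lam)
    raise RuntimeError("eigenvalue distribution yields almost no ordered positive triples")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort table; true coefficients land in ``df.attrs``.

    One row per (animal, region) with columns ``animal_id, group, region,
    lambda1..3, FA, AD, RD, MD, CL, CP, CS`` followed by one column per
    response, each equal to ``b . x + c + N(0, noise_sd)`` with
    ``x = (FA, RD, MD, CP, CS)``.
    """
    rng = _rng(spec.seed, "cohort")
    rows = []
    for k in range(spec.K):
        group = spec.group_labels[k]
        for region in spec.region_names:
            means, sds = spec.eigenvalue_distributions[(group, region)]
            ev = _draw_triple(rng, np.asarray(means, float), np.asarray(sds, float))
            m = compute_scalar_metrics(ev)
            row = {
                "animal_id": f"A{k:02d}", "group": group, "region": region,
                "lambda1": ev.lambda1, "lambda2": ev.lambda2, "lambda3": ev.lambda3,
                **m.as_dict(),
            }
            x = np.array([m.FA, m.RD, m.MD, m.CP, m.CS])
            for name, rs in spec.responses.items():
                noise = rng.normal(0.0, rs.noise_sd) if rs.noise_sd > 0 else 0.0
                row[name] = float(np.dot(rs.b, x) + rs.c + noise)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["true_coefficients"] = {
        name: {"b": dict(zip(PREDICTORS, rs.b)), "c": rs.c, "noise_sd": rs.noise_sd}
        for name, rs in spec.responses.items()
    }
    df.attrs["seed"] = spec.seed
    return df


def calibrate_noise_sd(spec: CohortSpec, response: str, target_r2: float,
                       n_rows: int = 4000, seed: int = 12345) -> float:
    """Noise SD giving population R^2 = ``target_r2`` for one response.

    Estimates Var(b.x) over the cohort's mixture of (group, region)
    eigenvalue distributions with a large fixed-seed Monte-Carlo draw and
    solves ``noise_sd = sqrt(Var(b.x) * (1 - R^2) / R^2)``.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    rs = spec.responses[response]
    rng = np.random.default_rng(seed)
    cells = [(g, r) for g in spec.group_labels for r in spec.region_names]
    signals = np.empty(n_rows)
    for i in range(n_rows):
        g, r = cells[i % len(cells)]
        means, sds = spec.eigenvalue_distributions[(g, r)]
        ev = _draw_triple(rng, np.asarray(means, float), np.asarray(sds, float))
        m = compute_scalar_metrics(ev)
        x = np.array([m.FA, m.RD, m.MD, m.CP, m.CS])
        signals[i] = np.dot(rs.b, x)
    var_signal = float(np.var(signals, ddof=1))
    return float(np.sqrt(var_signal * (1.0 - target_r2) / target_r2))
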