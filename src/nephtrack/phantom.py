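"""Synthetic serial-section phantoms with known ground truth.

The generator renders densely packable, tortuous tubes slice by slice as
a dark wall annulus around a bright lumen on a brighter slide
background, mirroring the appearance of toluidine-blue kidney sections
after grayscale conversion.  Tube radius follows a sigmoid schedule that
narrows sharply at a transition slice (the cortico-medullary transition
zone).  Optional ingredients: thin interstitial-like clutter, blanked /
smeared artefact slices, small per-slice translational misalignment, a
glomerulus-like lobulated blob at a tube origin, and a hairpin
(loop-of-Henle-like) turn.  Everything is deterministic given the seed,
and every rendered structure is recorded in a per-pixel label volume and
per-tube ground-truth centerline paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology

from .stack import SliceStack
from .tracker import PathPoint, TrackedPath

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_stack",
    "generate_move_dataset",
    "make_truth_labeller",
    "LABEL_CLUTTER",
    "LABEL_GLOMERULUS",
]

LABEL_CLUTTER = -1
LABEL_GLOMERULUS = -2


@dataclass(frozen=True)
class TubeSpec:
    """Geometry and intensity of one synthetic tube.

    The centerline is a Gaussian-smoothed random walk (``tortuosity`` is
    the per-slice step standard deviation in pixels, ``drift`` a constant
    per-slice velocity producing oblique, elongated cross sections).  The
    lumen radius narrows from ``cortex_radius`` to ``medulla_radius``
    through a sigmoid at ``transition_slice``.
    """

    start: tuple[float, float]
    cortex_radius: float = 12.0
    medulla_radius: float = 4.0
    transition_slice: float = 1e9  # effectively "all cortex" unless set
    transition_steepness: float = 0.08
    wall_thickness: float = 3.0
    tortuosity: float = 1.0
    drift: tuple[float, float] = (0.0, 0.0)
    smooth_sigma: float = 5.0
    lumen_intensity: float = 0.70
    wall_intensity: float = 0.15
    glomerulus: bool = False
    glomerulus_depth: int = 3  # slices occupied by the glomerulus blob
    hairpin_slice: int | None = None

    def radius_at(self, z: float) -> float:
        t = -self.transition_steepness * (z - self.transition_slice)
        sig = 1.0 / (1.0 + np.exp(-t))
        return self.medulla_radius + (self.cortex_radius - self.medulla_radius) * sig


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; reproducible given ``seed``."""

    image_size: tuple[int, int] = (160, 160)
    n_slices: int = 200
    tubes: tuple[TubeSpec, ...] = ()
    clutter_density: float = 0.0  # components per slice
    artefact_rate: float = 0.0  # probability per slice
    blank_slices: tuple[int, ...] = ()  # forced fully-blanked slices
    misalignment_sd: float = 0.0  # pixels
    noise_sd: float = 0.015  # intensity units
    background_intensity: float = 0.92
    tissue_intensity: float = 0.40  # interstitial matrix between tubules
    tissue_border: int = 3  # bare-slide frame width around the tissue block
    clutter_intensity: float = 0.70
    min_separation: float | None = None  # demand pairwise tube separation
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth for one generated phantom.

    ``paths`` are per-tube centerlines in the rendered image frame (the
    per-slice misalignment shift already applied); ``centerlines`` hold
    the unshifted coordinates; ``labels`` is a per-pixel volume with tube
    index + 1 on lumen pixels, -1 on clutter and -2 on glomerulus blobs.
    """

    paths: list[TrackedPath]
    centerlines: list[np.ndarray]  # per tube: (m, 4) of x, y, z, radius
    shifts: np.ndarray  # (n_slices, 2) integer (dx, dy) applied per slice
    labels: np.ndarray  # (n_slices, H, W) int16
    artefact_slices: list[int]
    spec: PhantomSpec


def _tube_centerline(
    tube: TubeSpec, n_slices: int, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """(m, 4) samples of x, y, z, radius in tracking order (down, then up
    again after a hairpin turn if one is requested)."""
    h, w = shape
    z0 = tube.glomerulus_depth if tube.glomerulus else 0
    z_end = min(n_slices, int(tube.hairpin_slice) + 1) if tube.hairpin_slice else n_slices
    zs = np.arange(z0, z_end)
    steps = rng.normal(0.0, tube.tortuosity, size=(len(zs), 2)) + np.asarray(tube.drift)
    steps = ndi.gaussian_filter1d(steps, tube.smooth_sigma, axis=0, mode="nearest")
    xy = np.asarray(tube.start, dtype=float) + np.cumsum(steps, axis=0)
    margin = tube.cortex_radius + tube.wall_thickness + 2
    xy[:, 0] = np.clip(xy[:, 0], margin, w - 1 - margin)
    xy[:, 1] = np.clip(xy[:, 1], margin, h - 1 - margin)
    radii = np.array([tube.radius_at(z) for z in zs])
    down = np.column_stack([xy, zs, radii])
    if tube.hairpin_slice is None:
        return down
    # ascending limb: fold back up at a lateral offset so the two limbs
    # stay side by side, sharing the turn slice
    offset = 2.5 * (tube.radius_at(tube.hairpin_slice) + tube.wall_thickness)
    up = down[-2::-1].copy()
    up[:, 0] = np.clip(up[:, 0] + offset, margin, w - 1 - margin)
    return np.vstack([down, up])


def _draw_disk(canvas: np.ndarray, cx: float, cy: float, r: float) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw.disk((cy, cx), max(r, 0.5), shape=canvas.shape)
    return rr, cc


def _draw_section(
    canvas: np.ndarray, cx: float, cy: float, r: float, vx: float, vy: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cross section of a tube at xy velocity (vx, vy) px/slice.

    An oblique cylinder cuts a slice in an ellipse elongated along the
    direction of travel by sec(tilt) = sqrt(1 + |v|^2); a vertical tube
    (v = 0) degenerates to a disk.
    """
    speed2 = vx * vx + vy * vy
    if speed2 < 0.25:
        return _draw_disk(canvas, cx, cy, r)
    major = max(r, 0.5) * float(np.sqrt(1.0 + speed2))
    rot = float(np.arctan2(vy, vx))
    rr, cc = draw.ellipse(cy, cx, max(r, 0.5), major, shape=canvas.shape, rotation=-rot)
    return rr, cc


def _render_clutter(
    canvas: np.ndarray,
    labels: np.ndarray,
    forbidden: np.ndarray,
    n_components: int,
    intensity: float,
    rng: np.random.Generator,
) -> None:
    """Scatter thin, irregular interstitial-tissue-like components."""
    h, w = canvas.shape
    placed = 0
    attempts = 0
    while placed < n_components and attempts < n_components * 10:
        attempts += 1
        cy, cx = rng.uniform(2, h - 3), rng.uniform(2, w - 3)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(5, 16)
        y2 = np.clip(cy + length * np.sin(angle), 1, h - 2)
        x2 = np.clip(cx + length * np.cos(angle), 1, w - 2)
        rr, cc = draw.line(int(cy), int(cx), int(y2), int(x2))
        mask = np.zeros_like(canvas, dtype=bool)
        mask[rr, cc] = True
        # a few pixels wide, like real interstitial slivers; 1-px-thin
        # threads would be erased by the erode/dilate cleaning anyway
        mask = morphology.dilation(mask, morphology.disk(1))
        if (forbidden & mask).any():
            continue
        canvas[mask] = intensity
        labels[mask] = LABEL_CLUTTER
        # keep components separate: placed clutter joins the exclusion zone
        forbidden |= morphology.dilation(mask, morphology.disk(1))
        placed += 1


def generate_stack(spec: PhantomSpec) -> tuple[SliceStack, PhantomTruth]:
    """Render a phantom stack and its ground truth.

    Raises if ``min_separation`` is requested but the generated
    centerlines violate it on some slice (the spec then makes
    non-intersection geometrically impossible).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n = spec.n_slices

    centerlines = [_tube_centerline(t, n, (h, w), rng) for t in spec.tubes]
    if spec.min_separation is not None:
        for z in range(n):
            pts = [c[c[:, 2] == z][:, :2] for c in centerlines]
            pts = [p for p in pts if len(p)]
            flat = np.vstack(pts) if pts else np.empty((0, 2))
            if len(flat) > 1:
                d = np.linalg.norm(flat[:, None] - flat[None, :], axis=2)
                np.fill_diagonal(d, np.inf)
                if d.min() < spec.min_separation:
                    raise ValueError(
                        f"tubes closer than min_separation={spec.min_separation} on slice {z}"
                    )

    volume = np.full((n, h, w), spec.background_intensity, dtype=float)
    labels = np.zeros((n, h, w), dtype=np.int16)

    # per-sample centerline velocity (px/slice) sets cross-section elongation
    velocities = [
        np.gradient(c[:, :2], axis=0) if len(c) > 1 else np.zeros((len(c), 2))
        for c in centerlines
    ]

    for z in range(n):
        canvas = volume[z]
        lab = labels[z]
        # interstitial tissue matrix fills the section; bare slide remains
        # only as a border frame (and is what background removal strips)
        b = spec.tissue_border
        canvas[b : h - b, b : w - b] = spec.tissue_intensity
        structures = np.zeros((h, w), dtype=bool)
        # walls first so adjacent lumens stay separated
        for tube, c, v in zip(spec.tubes, centerlines, velocities):
            for (x, y, zz, r), (vx, vy) in zip(c[c[:, 2] == z], v[c[:, 2] == z]):
                rr, cc = _draw_section(canvas, x, y, r + tube.wall_thickness, vx, vy)
                canvas[rr, cc] = tube.wall_intensity
                structures[rr, cc] = True
        for ti, (tube, c, v) in enumerate(zip(spec.tubes, centerlines, velocities)):
            for (x, y, zz, r), (vx, vy) in zip(c[c[:, 2] == z], v[c[:, 2] == z]):
                rr, cc = _draw_section(canvas, x, y, r, vx, vy)
                canvas[rr, cc] = tube.lumen_intensity
                lab[rr, cc] = ti + 1
        for tube, c in zip(spec.tubes, centerlines):
            if tube.glomerulus and z < tube.glomerulus_depth:
                gx, gy = c[0, 0], c[0, 1]
                rg = 2.0 * tube.cortex_radius
                for k in range(5):
                    ox, oy = rng.uniform(-rg / 2, rg / 2, size=2)
                    rr, cc = _draw_disk(canvas, gx + ox, gy + oy, rg * 0.55)
                    canvas[rr, cc] = tube.lumen_intensity
                    lab[rr, cc] = LABEL_GLOMERULUS
                    structures[rr, cc] = True
        if spec.clutter_density > 0:
            forbidden = morphology.dilation(structures, morphology.disk(2))
            _render_clutter(
                canvas, lab, forbidden, int(round(spec.clutter_density)),
                spec.clutter_intensity, rng,
            )

    # artefacts: whole-slice blanking or a smeared rectangular region
    artefact_slices = sorted(set(int(b) for b in spec.blank_slices))
    for z in range(n):
        if spec.artefact_rate > 0 and rng.random() < spec.artefact_rate:
            artefact_slices.append(z)
    artefact_slices = sorted(set(artefact_slices))
    for z in artefact_slices:
        if z in spec.blank_slices or rng.random() < 0.5:
            volume[z] = spec.background_intensity
            labels[z] = 0
        else:
            y0 = rng.integers(0, h // 2)
            x0 = rng.integers(0, w // 2)
            volume[z, y0 : y0 + h // 2, x0 : x0 + w // 2] = spec.background_intensity
            labels[z, y0 : y0 + h // 2, x0 : x0 + w // 2] = 0

    # per-slice translational misalignment, integer pixels, recorded
    shifts = np.zeros((n, 2), dtype=int)
    if spec.misalignment_sd > 0:
        shifts = np.round(rng.normal(0.0, spec.misalignment_sd, size=(n, 2))).astype(int)
        for z in range(n):
            dx, dy = shifts[z]
            if dx or dy:
                volume[z] = ndi.shift(
                    volume[z], (dy, dx), order=0, cval=spec.background_intensity
                )
                labels[z] = ndi.shift(labels[z], (dy, dx), order=0, cval=0)

    if spec.noise_sd > 0:
        volume = np.clip(volume + rng.normal(0.0, spec.noise_sd, volume.shape), 0.0, 1.0)

    paths = []
    for c in centerlines:
        pts = [
            PathPoint(
                x=float(x + shifts[int(z), 0]),
                y=float(y + shifts[int(z), 1]),
                z=int(z),
                radius=float(r),
            )
            for x, y, z, r in c
        ]
        paths.append(TrackedPath(pts))

    stack = SliceStack(volume, pixel_size=1.16, slice_thickness=2.5)
    truth = PhantomTruth(
        paths=paths,
        centerlines=centerlines,
        shifts=shifts,
        labels=labels,
        artefact_slices=artefact_slices,
        spec=spec,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# ground-truth move labelling and balanced dataset generation


def _majority_structure(cs, labels: np.ndarray) -> int:
    """Dominant ground-truth label under a cross section's pixels."""
    pix = cs.pixels
    vals = labels[cs.slice_index][pix[:, 0], pix[:, 1]]
    vals = vals[vals != 0]
    if len(vals) == 0:
        return 0
    uniq, counts = np.unique(vals, return_counts=True)
    return int(uniq[np.argmax(counts)])


def make_truth_labeller(
    truth: PhantomTruth,
    transition_slice: float | None = None,
    elongated_aspect: float = 2.0,
):
    """Build a labeller assigning the 5 move classes from ground truth.

    Moves touching a glomerulus blob are class 4; moves onto clutter, an
    unidentifiable component, or a *different* tube are class 3; moves
    with both ends below the transition slice are class 5 (inner
    medulla); remaining valid moves are class 2 when either cross section
    is elongated, else class 1.
    """

    def labeller(parent, child, ctx) -> int | None:
        sp = _majority_structure(parent.cross_section, truth.labels)
        sc = _majority_structure(child.cross_section, truth.labels)
        if LABEL_GLOMERULUS in (sp, sc):
            return 4
        if sp == 0 or sc == 0 or LABEL_CLUTTER in (sp, sc) or sp != sc:
            return 3
        if transition_slice is not None and min(parent.z, child.z) >= transition_slice:
            return 5
        a1 = parent.cross_section.shape.aspect_ratio
        a2 = child.cross_section.shape.aspect_ratio
        return 2 if max(a1, a2) >= elongated_aspect else 1

    return labeller


def _capture_scenario(
    spec: PhantomSpec,
    transition_slice: float | None,
    want: set[int],
    track_config=None,
    seed_all_tubes: bool = True,
) -> list[tuple[np.ndarray, int]]:
    """Preprocess, feature-extract and capture labelled moves on one phantom."""
    from .ml import capture_training_examples
    from .preprocess import PreprocessParams, preprocess_stack
    from .features import extract_features
    from .tracker import TrackConfig

    stack, truth = generate_stack(spec)
    binary = preprocess_stack(stack, PreprocessParams())
    feats = extract_features(binary, random_state=spec.seed)
    labeller = make_truth_labeller(truth, transition_slice)
    cfg = track_config or TrackConfig(tracking_radius=28.0, use_registration=False)
    seeds = []
    for path in truth.paths:
        for p in path.points[:1] if not seed_all_tubes else path.points[:: max(1, len(path) // 3)]:
            node = feats.find_node_near(p.x, p.y, p.z, max_dist=12)
            if node is not None:
                seeds.append(node)
    captured = capture_training_examples(
        stack, feats, seeds, labeller, config=cfg, capture_all=True
    )
    return [(f, c) for f, c in captured if c in want]


def generate_move_dataset(
    n_per_class: int,
    seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
    max_rounds: int = 60,
) -> list[tuple[np.ndarray, int]]:
    """Generate a class-balanced labelled move dataset.

    Purpose-built phantom scenarios are tracked unregulated and their
    attempted moves labelled from ground truth: wide circular tubes yield
    class 1, oblique drifting tubes class 2, tubes amid dense clutter
    class 3, glomerulus-capped tubes class 4, and narrow deep tubes below
    the transition slice class 5.  Scenarios re-run with fresh sub-seeds
    until each class reaches ``n_per_class`` (balance by generation, not
    duplication); a class that cannot be produced raises.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    h, w = image_size
    per_class: dict[int, list] = {c: [] for c in (1, 2, 3, 4, 5)}

    def scenario(kind: str, sub: int) -> list[tuple[np.ndarray, int]]:
        s = (seed * 1000 + sub) % (2**31 - 1)
        if kind == "circular":
            tubes = tuple(
                TubeSpec(start=(x0, y0), cortex_radius=9, tortuosity=0.6)
                for x0, y0 in ((w * 0.3, h * 0.3), (w * 0.7, h * 0.65))
            )
            spec = PhantomSpec(image_size=image_size, n_slices=22, tubes=tubes, seed=s)
            return _capture_scenario(spec, None, {1})
        if kind == "elongated":
            tubes = tuple(
                TubeSpec(start=(x0, y0), cortex_radius=6, tortuosity=0.4, drift=drift)
                for (x0, y0), drift in (
                    ((w * 0.25, h * 0.3), (3.0, 0.5)),
                    ((w * 0.3, h * 0.7), (2.5, -0.8)),
                )
            )
            spec = PhantomSpec(image_size=image_size, n_slices=22, tubes=tubes, seed=s)
            return _capture_scenario(spec, None, {2})
        if kind == "clutter":
            tubes = (
                TubeSpec(start=(w * 0.35, h * 0.4), cortex_radius=8, tortuosity=0.8),
                TubeSpec(start=(w * 0.65, h * 0.6), cortex_radius=8, tortuosity=0.8),
            )
            spec = PhantomSpec(
                image_size=image_size, n_slices=20, tubes=tubes,
                clutter_density=35, seed=s,
            )
            return _capture_scenario(spec, None, {3})
        if kind == "glomerulus":
            tubes = (
                TubeSpec(
                    start=(w * 0.5, h * 0.5), cortex_radius=8, tortuosity=0.5,
                    glomerulus=True, glomerulus_depth=6,
                ),
            )
            spec = PhantomSpec(image_size=image_size, n_slices=16, tubes=tubes, seed=s)
            return _capture_scenario(spec, None, {4})
        if kind == "medulla":
            tubes = tuple(
                TubeSpec(
                    start=(x0, y0), cortex_radius=10, medulla_radius=4,
                    transition_slice=8, transition_steepness=0.6, tortuosity=0.5,
                )
                for x0, y0 in ((w * 0.3, h * 0.35), (w * 0.7, h * 0.6))
            )
            spec = PhantomSpec(image_size=image_size, n_slices=30, tubes=tubes, seed=s)
            return _capture_scenario(spec, 12, {5})
        raise ValueError(kind)

    kinds = {1: "circular", 2: "elongated", 3: "clutter", 4: "glomerulus", 5: "medulla"}
    for cls, kind in kinds.items():
        rounds = 0
        while len(per_class[cls]) < n_per_class:
            if rounds >= max_rounds:
                raise RuntimeError(
                    f"could not generate enough class-{cls} ({kind}) examples"
                )
            per_class[cls].extend(scenario(kind, cls * 100 + rounds))
            rounds += 1
        per_class[cls] = per_class[cls][:n_per_class]

    out: list[tuple[np.ndarray, int]] = []
    for cls in (1, 2, 3, 4, 5):
        out.extend(per_class[cls])
    return out
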