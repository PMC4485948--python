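"""Graph-based 3D tracking of a tubule from a seed node.

From a seed, the tracker grows a tree of nodes through the stack using
open/closed lists, in the spirit of A*-style search.  Each expansion
proposes at most one *vertical* link per direction (nearest node on the
slice above/below within the tracking radius, after local translational
registration of the two slices) and *horizontal* links chaining every
node of the entered cross section.  Proposed vertical moves must pass,
in order of increasing cost: the distance rule, the skip rule (when
slices are skipped), the bidirectionality rule, and optionally a trained
move classifier.  The longest root-to-leaf path of the resulting tree is
the reconstructed tubule centerline.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.feature import match_template

from .features import Node, CrossSection, StackFeatures
from .preprocess import SigmoidSchedule
from .stack import SliceStack
from . import ml

logger = logging.getLogger(__name__)

__all__ = [
    "TrackConfig",
    "TrackGraph",
    "TrackedPath",
    "PathPoint",
    "local_register",
    "vertical_candidate",
    "horizontal_links",
    "validate_distance",
    "validate_bidirectional",
    "validate_skip",
    "track",
    "reconstruct_path",
    "evaluate_against_truth",
]

RULE_NAMES = ("distance", "skip", "bidirectional", "ml")


@dataclass
class TrackConfig:
    """Tracking parameters.

    ``tracking_radius`` may be a number, a depth schedule, or ``"auto"``
    (1.5x the mean nearest-neighbour spacing of cross-section centroids on
    the target slice).  ``max_skip`` is the hard ceiling on skipped images
    per move (morphology changes too fast beyond two sections).  Skip
    attempts are gated by a direction buffer (the last few accepted move
    directions must agree) and a refractory period (minimum number of
    accepted moves between attempts).
    """

    tracking_radius: float | str | SigmoidSchedule = 25.0
    registration_window: int = 48
    max_shift: int = 10
    max_skip: int = 2
    distance_coefficient: float = 1.0
    shape_change_limit: float = 30.0  # percent, per shape factor
    refractory_period: int = 10
    direction_buffer_len: int = 5
    direction_consensus: float = 0.8
    unidirectional_mode: bool = False
    ml_threshold: float = 0.3
    use_registration: bool = True
    record_overlap: bool = False

    def __post_init__(self) -> None:
        if self.max_skip > 2:
            raise ValueError("max_skip must be <= 2")
        if self.refractory_period < 0:
            raise ValueError("refractory_period must be >= 0")


@dataclass
class TrackGraph:
    """Parent/child links among nodes discovered from one seed."""

    root: Node
    nodes: dict[tuple, Node] = field(default_factory=dict)
    parent: dict[tuple, tuple | None] = field(default_factory=dict)
    children: dict[tuple, list[tuple]] = field(default_factory=dict)
    edge_kind: dict[tuple, str] = field(default_factory=dict)  # kind of edge from parent
    corrections: list[tuple] = field(default_factory=list)
    rejections: Counter = field(default_factory=Counter)  # first-firing rule
    overlap: Counter = field(default_factory=Counter)  # all rules that would fire
    n_skip_moves: int = 0
    correction_requested: bool = False
    region_signal_fired: bool = False

    def add_root(self, node: Node) -> None:
        self.nodes[node.node_id] = node
        self.parent[node.node_id] = None
        self.children[node.node_id] = []
        self.edge_kind[node.node_id] = "root"

    def add_edge(self, parent: Node, child: Node, kind: str) -> None:
        cid = child.node_id
        if cid in self.nodes:
            return
        self.nodes[cid] = child
        self.parent[cid] = parent.node_id
        self.children.setdefault(parent.node_id, []).append(cid)
        self.children[cid] = []
        self.edge_kind[cid] = kind

    def __contains__(self, node_id: tuple) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class PathPoint:
    x: float
    y: float
    z: int
    radius: float
    source: str = "auto"  # auto | manual


@dataclass
class TrackedPath:
    """Reconstructed ordered centerline with per-point lumen radius."""

    points: list[PathPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def corrections(self) -> list[PathPoint]:
        return [p for p in self.points if p.source == "manual"]

    def as_array(self) -> np.ndarray:
        """(N, 4) array of x, y, z, radius."""
        if not self.points:
            return np.empty((0, 4))
        return np.array([[p.x, p.y, p.z, p.radius] for p in self.points])


# ---------------------------------------------------------------------------
# local registration


def local_register(
    stack: SliceStack,
    slice_a: int,
    slice_b: int,
    center: tuple[float, float],
    window: int = 48,
    max_shift: int = 10,
) -> tuple[int, int, bool]:
    """Integer translational offset between two slices around a point.

    A ``window``-sized patch of slice ``a`` centred on ``center`` (x, y) is
    matched by normalised cross-correlation inside a ``2*max_shift``-padded
    search region of slice ``b``.  Returns ``(dx, dy, ok)`` such that
    content at (x, y) on slice ``a`` appears at (x + dx, y + dy) on slice
    ``b``; ``ok`` is False when either patch is flat (zero variance), in
    which case (0, 0) is returned.
    """
    a = np.asarray(stack.slices[slice_a], dtype=float)
    b = np.asarray(stack.slices[slice_b], dtype=float)
    h, w = a.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = window // 2
    ty0, ty1 = max(0, cy - half), min(h, cy + half)
    tx0, tx1 = max(0, cx - half), min(w, cx + half)
    template = a[ty0:ty1, tx0:tx1]
    sy0, sy1 = max(0, ty0 - max_shift), min(h, ty1 + max_shift)
    sx0, sx1 = max(0, tx0 - max_shift), min(w, tx1 + max_shift)
    search = b[sy0:sy1, sx0:sx1]
    if (
        template.size == 0
        or search.shape[0] < template.shape[0]
        or search.shape[1] < template.shape[1]
        or float(template.std()) < 1e-12
        or float(search.std()) < 1e-12
    ):
        logger.debug("local_register: flat or degenerate patch at %s", center)
        return 0, 0, False
    resp = match_template(search, template)
    pr, pc = np.unravel_index(int(np.argmax(resp)), resp.shape)
    dy = (sy0 + pr) - ty0
    dx = (sx0 + pc) - tx0
    return int(dx), int(dy), True


# ---------------------------------------------------------------------------
# edge proposal


def vertical_candidate(
    position: tuple[float, float] | np.ndarray,
    candidates: Sequence[Node],
    r_track: float,
    positions: np.ndarray | None = None,
) -> Node | None:
    """Nearest candidate node strictly within the tracking radius.

    ``positions`` overrides the candidates' stored coordinates (used to
    pass offset-corrected positions); only one node may be linked per
    direction, so only the distance minimiser is returned.
    """
    if len(candidates) == 0:
        return None
    if positions is None:
        positions = np.array([[n.x, n.y] for n in candidates], dtype=float)
    d = np.linalg.norm(positions - np.asarray(position, dtype=float), axis=1)
    i = int(np.argmin(d))
    return candidates[i] if d[i] < r_track else None


def horizontal_links(entering_node: Node, cs: CrossSection) -> list[tuple[Node, Node]]:
    """Chain all nodes of a cross section from the entering node.

    Edges follow nearest-neighbour chaining by pairwise Euclidean
    distance, so every node of the cross section is reachable from the
    entering node.
    """
    others = [n for n in cs.nodes if n.node_id != entering_node.node_id]
    edges: list[tuple[Node, Node]] = []
    current = entering_node
    remaining = list(others)
    while remaining:
        dists = [np.linalg.norm(current.xy - n.xy) for n in remaining]
        i = int(np.argmin(dists))
        nxt = remaining.pop(i)
        edges.append((current, nxt))
        current = nxt
    return edges


# ---------------------------------------------------------------------------
# the rule base


def validate_distance(
    parent: Node,
    child: Node,
    coefficient: float = 1.0,
    xy_distance: float | None = None,
) -> bool:
    """Distance rule: xy distance must be strictly less than the sum of the
    two nodes' radii (half minor axis length), scaled by ``coefficient``."""
    if xy_distance is None:
        xy_distance = float(np.linalg.norm(parent.xy - child.xy))
    return xy_distance < coefficient * (parent.radius + child.radius)


def validate_bidirectional(
    node_a: Node,
    node_b: Node,
    nodes_on_a_slice: Sequence[Node],
    r_track: float,
    positions: np.ndarray | None = None,
) -> bool:
    """Bidirectionality rule: the reverse search from B toward A's slice
    must return A itself."""
    back = vertical_candidate(node_b.xy, nodes_on_a_slice, r_track, positions)
    return back is not None and back.node_id == node_a.node_id


def validate_skip(
    node_before: Node,
    node_after: Node,
    skip_count: int,
    shape_change_limit: float = 30.0,
    max_skip: int = 2,
) -> bool:
    """Skip rule: at most ``max_skip`` images skipped, and the cross-section
    shape must stay nearly constant across the skip (each of the six shape
    factors changes by at most ``shape_change_limit`` percent).

    The percentage change of each factor is taken relative to its
    pre-skip value, floored at the factor's characteristic scale (half a
    unit for the bounded dimensionless factors, one pixel for the minor
    axis): a change from eccentricity 0.05 to 0.10 is noise on a round
    lumen, not a 100% shape change, and an exactly zero pre-skip factor
    degenerates to an absolute comparison against the floor.
    """
    if skip_count < 1:
        raise ValueError("skip_count must be >= 1")
    if skip_count > max_skip:
        return False
    before = node_before.cross_section.shape.as_array()
    after = node_after.cross_section.shape.as_array()
    # circularity, eccentricity, solidity, aspect_ratio, area, minor_axis
    floors = (0.5, 0.5, 0.5, 1.0, 10.0, 1.0)
    for pre, post, floor in zip(before, after, floors):
        if abs(post - pre) / max(abs(pre), floor) * 100.0 > shape_change_limit:
            return False
    return True


# ---------------------------------------------------------------------------
# tracking


def _resolve_r_track(
    cfg: TrackConfig, feats: StackFeatures, slice_index: int
) -> float:
    rt = cfg.tracking_radius
    if isinstance(rt, SigmoidSchedule):
        return float(rt.value_at(slice_index))
    if isinstance(rt, str):
        if rt != "auto":
            raise ValueError(f"unknown tracking_radius mode {rt!r}")
        sections = feats[slice_index].cross_sections
        if len(sections) < 2:
            return 25.0
        cents = np.array([cs.centroid_xy for cs in sections])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        return 1.5 * float(d.min(axis=1).mean())
    return float(rt)


def _resolve_seed(seed, feats: StackFeatures) -> Node:
    if isinstance(seed, Node):
        return seed
    x, y, z = seed
    node = feats.find_node_near(float(x), float(y), int(z))
    if node is None:
        raise ValueError(f"seed {seed} does not fall on any cross section")
    return node


def track(
    stack: SliceStack,
    feats: StackFeatures,
    seed,
    config: TrackConfig | None = None,
    classifier: "ml.MoveClassifier | None" = None,
    correction_provider: Callable[[Node, TrackGraph], Node | None] | None = None,
    move_recorder: Callable[[Node, Node, "ml.MoveContext"], None] | None = None,
    capture_all: bool = False,
) -> TrackGraph:
    """Grow the tracking tree from a seed node.

    ``seed`` is a :class:`~nephtrack.features.Node` or an (x, y, z) triple
    resolved to the nearest node.  ``classifier`` adds machine-learned move
    validation after the rule base; ``correction_provider`` is consulted at
    dead ends once the open list empties and may supply a bridge node
    (recorded as a manual correction); ``move_recorder`` observes every
    proposed vertical move (with ``capture_all``, every in-radius candidate)
    for training-example capture.
    """
    cfg = config or TrackConfig()
    n_slices = stack.n_slices
    seed_node = _resolve_seed(seed, feats)

    graph = TrackGraph(root=seed_node)
    graph.add_root(seed_node)
    open_list: deque[Node] = deque([seed_node])
    closed: set[tuple] = set()
    direction_buffer: deque[int] = deque(maxlen=cfg.direction_buffer_len)
    moves_since_skip_attempt = cfg.refractory_period  # first attempt allowed
    unidirectional = cfg.unidirectional_mode
    dominant_dir: int | None = None
    dead_ends: list[tuple[Node, int]] = []  # (node, blocked direction)
    asked_corrections: set[tuple] = set()
    terminated: set[tuple] = set()  # glomerulus terminations

    def make_context(node: Node, dz_signed: int, offset: tuple[int, int]) -> "ml.MoveContext":
        rel_z = node.z / max(1, n_slices - 1)
        return ml.MoveContext(
            relative_z=rel_z, image_difference=abs(dz_signed), offset=offset
        )

    def skip_allowed(d: int) -> bool:
        if moves_since_skip_attempt < cfg.refractory_period:
            return False
        if len(direction_buffer) == 0:
            return True
        frac = sum(1 for b in direction_buffer if b == d) / len(direction_buffer)
        return frac >= cfg.direction_consensus

    def try_move(node: Node, d: int, dz: int) -> tuple[Node | None, str]:
        """Propose and validate one vertical move of signed extent d*dz.

        Returns (child, reason); reason is one of "accepted", "oob"
        (target slice outside the stack), "none" (no candidate in the
        tracking radius), "already" (the nearest candidate is linked
        already — that direction is satisfied, not a dead end),
        "rejected" (a validator fired) or "terminated" (glomerulus).
        """
        nonlocal unidirectional, dominant_dir
        zt = node.z + d * dz
        if not 0 <= zt < n_slices:
            return None, "oob"
        if cfg.use_registration:
            dx, dy, _ = local_register(
                stack, node.z, zt, (node.x, node.y), cfg.registration_window, cfg.max_shift
            )
        else:
            dx = dy = 0
        candidates = feats[zt].nodes
        if not candidates:
            return None, "none"
        raw = np.array([[n.x, n.y] for n in candidates], dtype=float)
        corrected = raw - [dx, dy]  # child positions mapped into the parent frame
        r_track = _resolve_r_track(cfg, feats, zt)
        ctx = make_context(node, d * dz, (dx, dy))

        if move_recorder is not None and capture_all:
            dists = np.linalg.norm(corrected - node.xy, axis=1)
            for i in np.nonzero(dists < r_track)[0]:
                move_recorder(node, candidates[int(i)], ctx)

        cand = vertical_candidate(node.xy, candidates, r_track, corrected)
        if cand is None:
            return None, "none"
        if cand.node_id in graph or cand.node_id in terminated:
            return None, "already"
        if move_recorder is not None and not capture_all:
            move_recorder(node, cand, ctx)

        ci = candidates.index(cand)
        dist = float(np.linalg.norm(corrected[ci] - node.xy))
        skip_count = dz - 1

        fired: list[str] = []
        if not validate_distance(node, cand, cfg.distance_coefficient, dist):
            fired.append("distance")
        if skip_count >= 1 and not validate_skip(
            node, cand, skip_count, cfg.shape_change_limit, cfg.max_skip
        ):
            fired.append("skip")
        if not fired or cfg.record_overlap:
            parents = feats[node.z].nodes
            parent_pos = np.array([[n.x, n.y] for n in parents], dtype=float) + [dx, dy]
            if not validate_bidirectional(node, cand, parents, r_track, parent_pos):
                fired.append("bidirectional")
        decision = None
        if classifier is not None and (not fired or cfg.record_overlap):
            f = ml.extract_move_features(node, cand, ctx)
            decision = classifier.decide(f)
            if decision.final == "invalid":
                fired.append("ml")
        if fired:
            graph.rejections[fired[0]] += 1
            for rule in fired:
                graph.overlap[rule] += 1
            logger.debug("move %s -> %s rejected by %s", node.node_id, cand.node_id, fired)
            return None, "rejected"
        if decision is not None:
            if decision.final == "terminate":
                terminated.add(cand.node_id)
                logger.info("glomerulus termination at %s", cand.node_id)
                return None, "terminated"
            if decision.final == "region_signal":
                graph.region_signal_fired = True
                unidirectional = True
                dominant_dir = d
        graph.add_edge(node, cand, "skip" if skip_count >= 1 else "vertical")
        if skip_count >= 1:
            graph.n_skip_moves += 1
        return cand, "accepted"

    def direction_satisfied(node: Node, d: int) -> bool:
        """True when the node's cross section already continues toward d
        (via some sibling's child or parent), so a failed move from this
        particular node is not a real dead end of the tubule."""
        cs = node.cross_section
        members = cs.nodes if cs is not None else [node]
        for m in members:
            mid = m.node_id
            if mid not in graph.nodes:
                continue
            pid = graph.parent.get(mid)
            if pid is not None and np.sign(graph.nodes[pid].z - node.z) == d:
                return True
            for c in graph.children.get(mid, ()):
                if np.sign(graph.nodes[c].z - node.z) == d:
                    return True
        return False

    def effective_dead_ends() -> list[Node]:
        out, seen = [], set()
        for node, d in reversed(dead_ends):  # most recent frontier first
            if node.node_id in seen:
                continue
            if not direction_satisfied(node, d):
                seen.add(node.node_id)
                out.append(node)
        return out

    while True:
        if not open_list:
            frontier = effective_dead_ends()
            if correction_provider is not None:
                bridge = None
                for de in frontier:
                    if de.node_id in asked_corrections:
                        continue
                    asked_corrections.add(de.node_id)
                    graph.correction_requested = True
                    bridge = correction_provider(de, graph)
                    if bridge is not None and bridge.node_id not in graph:
                        graph.add_edge(de, bridge, "manual")
                        graph.corrections.append(bridge.node_id)
                        open_list.append(bridge)
                        break
                    bridge = None
                if bridge is not None:
                    continue
            elif frontier:
                graph.correction_requested = True
            break

        node = open_list.popleft()
        if node.node_id in closed:
            continue
        closed.add(node.node_id)

        # horizontal edges: chain all nodes of the entered cross section
        if node.cross_section is not None:
            for a, b in horizontal_links(node, node.cross_section):
                if b.node_id not in graph:
                    graph.add_edge(a, b, "horizontal")
                    open_list.append(b)

        if unidirectional and dominant_dir is None and direction_buffer:
            vals = list(direction_buffer)
            dominant_dir = 1 if vals.count(1) >= vals.count(-1) else -1
        directions = (dominant_dir,) if (unidirectional and dominant_dir) else (1, -1)

        advanced = False
        for d in directions:
            child, reason = try_move(node, d, 1)
            if child is not None:
                open_list.append(child)
                direction_buffer.append(d)
                moves_since_skip_attempt += 1
                advanced = True
                continue
            if reason in ("oob", "already", "terminated"):
                continue
            # dead end in this direction: attempt a controlled skip
            skipped = False
            if cfg.max_skip >= 1 and skip_allowed(d):
                moves_since_skip_attempt = 0
                for dz in range(2, cfg.max_skip + 2):
                    child, skip_reason = try_move(node, d, dz)
                    if child is not None:
                        open_list.append(child)
                        direction_buffer.append(d)
                        skipped = True
                        break
            if skipped:
                advanced = True
            else:
                dead_ends.append((node, d))
        if unidirectional and not advanced and node.cross_section is not None:
            # hairpin turn of the loop of Henle: the tube folds back on
            # itself, so reverse the dominant direction once the cross
            # section has been traversed horizontally
            if dominant_dir is not None and len(node.cross_section.nodes) >= 2:
                dominant_dir = -dominant_dir

    return graph


# ---------------------------------------------------------------------------
# reconstruction & evaluation


def reconstruct_path(graph: TrackGraph) -> TrackedPath:
    """Longest root-to-leaf path of the tracking tree.

    Length is counted in nodes; ties prefer the branch whose terminal node
    is deepest (largest z), then the lexicographically smallest node id.
    Shorter branches are discarded as ambiguous links or interstitial
    captures.
    """
    if not graph.nodes:
        return TrackedPath()
    root_id = graph.root.node_id

    # iterative DFS computing (length, terminal_z, terminal_id) per subtree
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    stack_ = [root_id]
    while stack_:
        nid = stack_.pop()
        order.append(nid)
        stack_.extend(graph.children.get(nid, ()))
    for nid in reversed(order):
        kids = graph.children.get(nid, ())
        if not kids:
            best[nid] = (1, graph.nodes[nid].z, _neg_id(nid), nid)
        else:
            cl, cz, cni, cid = max(best[k] for k in kids)
            best[nid] = (cl + 1, cz, cni, cid)

    # walk down choosing the child on the best path
    path_ids = [root_id]
    while graph.children.get(path_ids[-1]):
        kids = graph.children[path_ids[-1]]
        nxt = max(kids, key=lambda k: best[k])
        path_ids.append(nxt)

    points = []
    for nid in path_ids:
        n = graph.nodes[nid]
        source = "manual" if nid in graph.corrections else "auto"
        points.append(PathPoint(float(n.x), float(n.y), int(n.z), n.radius, source))
    return TrackedPath(points)


def _neg_id(nid: tuple) -> tuple:
    """Order helper: larger is better, so negate the id lexicographically."""
    return tuple(-v for v in nid)


def _path_array(path) -> np.ndarray:
    if isinstance(path, TrackedPath):
        return path.as_array()[:, :3] if len(path) else np.empty((0, 3))
    arr = np.asarray(path, dtype=float)
    return arr[:, :3]


def evaluate_against_truth(
    path, truth, residual_threshold: float = 15.0
) -> tuple[float, float]:
    """Accuracy (alpha) and extent (beta) of a tracked path, in percent.

    Residuals are per-slice xy distances between tracked and ground-truth
    coordinates.  alpha is the percentage of tracked points lying within
    ``residual_threshold`` pixels of the truth path on the same slice;
    beta is the percentage of truth points matched by some tracked point.
    An empty tracked path has no defined alpha and raises; beta would be 0.
    """
    p = _path_array(path)
    t = _path_array(truth)
    if len(p) == 0:
        raise ValueError("alpha undefined for an empty tracked path")
    if len(t) == 0:
        raise ValueError("empty ground-truth path")
    matched_p = 0
    for x, y, z in p:
        on_slice = t[t[:, 2] == z]
        if len(on_slice) and np.min(np.hypot(on_slice[:, 0] - x, on_slice[:, 1] - y)) < residual_threshold:
            matched_p += 1
    matched_t = 0
    for x, y, z in t:
        on_slice = p[p[:, 2] == z]
        if len(on_slice) and np.min(np.hypot(on_slice[:, 0] - x, on_slice[:, 1] - y)) < residual_threshold:
            matched_t += 1
    alpha = 100.0 * matched_p / len(p)
    beta = 100.0 * matched_t / len(t)
    return alpha, beta
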