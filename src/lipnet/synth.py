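"""Seeded synthetic confocal scene generator with complete ground truth.

Emulates the statistical structure that the downstream analysis assumes:
elliptical cells with offset elliptical nuclei, a branched tubular network
plus vesicle-like puncta in a lipophilic-tracer channel (``clld``), a
nanoparticle channel (``aunc``) whose co-localized signal fraction, spatial
pattern and mean-intensity ratio between conditions are controllable
parameters, and a protease-marker channel (``mt1mmp``).  Every scene comes
with exact ground truth: cell/nucleus/cytoplasm masks, the generating
branch graph of each cell's network (before rasterization and noise), the
realized co-localized dot fraction, and ideal per-channel intensities.

The network of each cell is grown as a random tree (occasionally a forest):
branches are direction-persistent random walks on the 8-connected pixel
grid, attached to interior points of existing branches.  An attachment
splits the host branch, so branch and junction counts in the truth graph
are exact by construction.  Walks keep a clearance distance from existing
structure, which keeps the rendered tubules resolvable after dilation,
blur and noise.

Noise model (applied per channel, in order): Gaussian PSF blur of the ideal
image; a constant background pedestal; Poisson shot noise with the photon
gain chosen so that mean foreground / sigma(background) equals ``snr``;
additive Gaussian read noise with sigma = foreground / (3 * snr).  Setting
``snr`` to infinity disables the pedestal and both noise terms, and
``psf_sigma_px = 0`` disables blur, so noise-free scenes are exactly
segmentable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .exceptions import PlacementError
from .ibna import (
    NetworkMetrics,
    SkeletonEdge,
    SkeletonGraph,
    SkeletonNode,
    build_skeleton_graph,
    classify_skeleton_pixels,
    prune_short_branches,
    simplify_graph,
    skeletonize_binary,
)
from .imgio import MultiChannelImage

__all__ = [
    "SceneParams",
    "SceneTruth",
    "generate_scene",
    "generate_condition_pair",
    "generate_replicated_scene",
    "truth_network_metrics",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("nucleus", "clld", "mt1mmp", "aunc")

# ideal-intensity design (16-bit range)
FOREGROUND = 10000  #: ideal foreground amplitude, all channels scale from it
FILL_LEVEL = 2500  #: diffuse cytosolic fill in the clld channel
BG_PEDESTAL = 2500  #: camera background added before shot noise
TEXTURE_LO_FRAC = 0.7  #: lipophilic-structure texture spans [0.7, 1.0] * FOREGROUND
MT_AMP_FRAC = 0.8
DOT_RADIUS = 2  #: nanoparticle / vesicle dot radius in px
#: Amplitude of off-structure nanoparticle dots, calibrated on the dot
#: geometry so a dot carries the same expected integrated signal whether it
#: lands on the bright network ribbon (where its value tracks the local
#: lipophilic texture) or on the diffuse cytosolic fill: placement must not
#: change the channel's total signal.
OFF_DOT_AMP_FRAC = 0.704

# condition-pair construction
COND1_COLOC_FRACTION = 0.2
COND2_COLOC_FRACTION = 0.75
NETWORK_DENSITY_FACTOR = 2  #: branch-target multiplier for the second condition

_PATTERNS = ("perinuclear_aggregated", "anterior_dotlike")


def child_seed(seed: int, key: int) -> int:
    """Deterministic sub-seed derivation (stays below 2**31)."""
    return int(np.random.SeedSequence([int(seed), int(key)]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SceneParams:
    """Generator settings; the defaults are the reference study conditions.

    ``tubule_width_px`` is the rendered full width of a network tubule (a
    skeleton dilated by ``(width - 1) // 2``).  ``coloc_fraction`` is the
    fraction of nanoparticle dots placed on lipophilic structures;
    ``intensity_ratio`` multiplies every nanoparticle-channel amplitude.
    """

    image_size: int = 256
    n_cells: int = 3
    network_branch_target: int = 10
    tubule_width_px: int = 3
    puncta_count: int = 4
    coloc_fraction: float = 0.5
    intensity_ratio: float = 1.0
    pattern: str = "perinuclear_aggregated"
    snr: float = 10.0
    psf_sigma_px: float = 0.8
    seed: int = 0
    cell_radius_px: float = 42.0
    cell_radius_jitter: float = 0.05
    nucleus_radius_frac: float = 0.35
    aunc_dot_count: int = 12
    branch_len_min: int = 12
    branch_len_max: int = 26
    clearance_px: int = 6

    def problems(self) -> list[str]:
        out = []
        if self.image_size < 32:
            out.append("image_size must be >= 32")
        if self.n_cells < 0:
            out.append("n_cells must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            out.append("coloc_fraction must lie in [0, 1]")
        if self.intensity_ratio <= 0:
            out.append("intensity_ratio must be > 0")
        if self.pattern not in _PATTERNS:
            out.append(f"pattern must be one of {_PATTERNS}")
        if not self.snr > 0:
            out.append("snr must be > 0")
        if self.psf_sigma_px < 0:
            out.append("psf_sigma_px must be >= 0")
        if self.tubule_width_px < 1:
            out.append("tubule_width_px must be >= 1")
        if self.network_branch_target < 0:
            out.append("network_branch_target must be >= 0")
        if self.puncta_count < 0 or self.aunc_dot_count < 0:
            out.append("dot counts must be >= 0")
        if self.cell_radius_px < 8:
            out.append("cell_radius_px must be >= 8")
        return out

    def validate(self) -> None:
        problems = self.problems()
        if problems:
            raise ValueError("invalid SceneParams: " + "; ".join(problems))


@dataclass
class SceneTruth:
    """Exact generator ground truth for one scene.

    ``true_skeletons[i]`` is the generating branch graph of cell *i* (the
    curve network before dilation, blur and noise).  ``true_intensity_means``
    are the ideal foreground amplitudes per channel (so a condition pair
    built at intensity ratio *r* differs by exactly *r* in the ``aunc``
    entry), while ``true_cytoplasm_means[i]`` are per-cell means of the
    ideal noise-free image over the cytoplasm.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    cytoplasm_masks: list[np.ndarray]
    true_skeletons: list[SkeletonGraph]
    true_coloc_fraction: float
    true_intensity_means: dict[str, float]
    true_cytoplasm_means: list[dict[str, float]]
    n_cells: int

    def cytoplasm_mask(self, i: int) -> np.ndarray:
        return self.cytoplasm_masks[i]


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_mask(shape, center, rx, ry, theta) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _place_cells(params: SceneParams, rng) -> list[dict]:
    """Rejection-sample non-overlapping elliptical cells with interior nuclei."""
    size = params.image_size
    cells: list[dict] = []
    for _ in range(params.n_cells):
        placed = False
        for _attempt in range(1000):
            r_base = params.cell_radius_px * (
                1.0 + params.cell_radius_jitter * rng.uniform(-1, 1)
            )
            ar = rng.uniform(0.9, 1.1)
            rx, ry = r_base * ar, r_base / ar
            r_max = max(rx, ry)
            margin = r_max + 3
            if 2 * margin >= size:
                continue
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            ok = all(
                math.hypot(cy - c["center"][0], cx - c["center"][1])
                >= r_max + c["r_max"] + 4
                for c in cells
            )
            if not ok:
                continue
            theta = rng.uniform(0, math.pi)
            r_min = min(rx, ry)
            rn = params.nucleus_radius_frac * r_min * rng.uniform(0.85, 1.05)
            off = rng.uniform(0.2, 0.45) * max(r_min - rn - 2.0, 2.0)
            phi = rng.uniform(0, 2 * math.pi)
            ncy = cy + off * math.sin(phi)
            ncx = cx + off * math.cos(phi)
            cells.append(
                dict(
                    center=(cy, cx),
                    rx=rx,
                    ry=ry,
                    theta=theta,
                    r_max=r_max,
                    nucleus_center=(ncy, ncx),
                    nucleus_r=rn,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {params.n_cells} cells of radius "
                f"~{params.cell_radius_px:.0f}px in a {size}x{size} image"
            )
    return cells


# ---------------------------------------------------------------------------
# network growth

_MIN_NODE_SEP = 9.0  # px between junction/attachment points
_VALIDATE_PRUNE_PX = 4.0
_VALIDATE_MERGE_PX = 4.0


def _render_faithful(skel_mask: np.ndarray, radius: int, n_branches: int, n_junctions: int) -> bool:
    """True if the noise-free ribbon rendering of the skeleton reproduces the
    declared branch and junction counts after re-skeletonization.

    Grown branches that would merge with neighbors at the rendered tubule
    width (e.g. near-parallel segments by a junction) fail this check and
    are rejected, so the ground-truth graph is exactly recoverable from the
    ideal image.
    """
    rows, cols = np.nonzero(skel_mask)
    if rows.size == 0:
        return n_branches == 0 and n_junctions == 0
    pad = radius + 2
    r0 = max(0, rows.min() - pad)
    r1 = min(skel_mask.shape[0], rows.max() + pad + 1)
    c0 = max(0, cols.min() - pad)
    c1 = min(skel_mask.shape[1], cols.max() + pad + 1)
    crop = skel_mask[r0:r1, c0:c1]
    ribbon = (
        ndi.binary_dilation(crop, structure=disk(radius), border_value=0)
        if radius > 0
        else crop
    )
    sk = skeletonize_binary(ribbon)
    sk = prune_short_branches(sk, _VALIDATE_PRUNE_PX)
    classes = classify_skeleton_pixels(sk)
    g = simplify_graph(build_skeleton_graph(sk, classes), _VALIDATE_MERGE_PX)
    return g.n_branches == n_branches and g.n_actual_junctions == n_junctions


def _angle_step(pos, ang):
    dr = int(round(math.sin(ang)))
    dc = int(round(math.cos(ang)))
    return (pos[0] + dr, pos[1] + dc)


def _clear_around(occupied, p, radius, allowed):
    h, w = occupied.shape
    r0, r1 = max(0, p[0] - radius), min(h, p[0] + radius + 1)
    c0, c1 = max(0, p[1] - radius), min(w, p[1] + radius + 1)
    for r, c in zip(*np.nonzero(occupied[r0:r1, c0:c1])):
        if (r + r0, c + c0) not in allowed:
            return False
    return True


def _walk(rng, start, ang, target_len, domain, occupied, params):
    """Direction-persistent random walk on the 8-connected grid.

    Keeps ``clearance_px`` away from existing structure except near its own
    recent tail and its attachment point.
    """
    clearance = params.clearance_px
    near_start = {
        (start[0] + dr, start[1] + dc)
        for dr in range(-clearance - 1, clearance + 2)
        for dc in range(-clearance - 1, clearance + 2)
    }
    path: list[tuple[int, int]] = []
    pos = start
    for _ in range(target_len):
        stepped = False
        for attempt in range(8):
            a = ang + (rng.normal(0, 0.3) if attempt == 0 else rng.uniform(-1.3, 1.3))
            nxt = _angle_step(pos, a)
            if nxt == pos:
                continue
            if not (0 <= nxt[0] < domain.shape[0] and 0 <= nxt[1] < domain.shape[1]):
                continue
            if not domain[nxt]:
                continue
            if nxt in path or nxt == start:
                continue
            allowed = near_start | set(path[-(clearance + 2):])
            if not _clear_around(occupied, nxt, clearance, allowed):
                continue
            # self-avoidance: the walk's own pixels are not yet in `occupied`
            if any(
                max(abs(nxt[0] - q[0]), abs(nxt[1] - q[1])) <= clearance
                for q in path[: -(clearance + 2)]
            ):
                continue
            path.append(nxt)
            pos = nxt
            ang = a
            stepped = True
            break
        if not stepped:
            break
    return path


def _grow_network(rng, cytoplasm, params: SceneParams):
    """Grow the ground-truth branch network of one cell.

    Returns ``(nodes, edges, skeleton_mask)`` where nodes are
    ``(pixel, kind)`` tuples and edges ``[u, v, path]`` with the path
    excluding node pixels.  Exactness of the graph (every branch an edge,
    every attachment a degree-3 junction) is the point: recovery tests
    compare pixel-level measurements against this structure.
    """
    radius = max(0, (params.tubule_width_px - 1) // 2)
    domain = ndi.binary_erosion(cytoplasm, structure=disk(radius + 1), border_value=0)
    occupied = np.zeros(cytoplasm.shape, dtype=bool)
    nodes: list[tuple[tuple[int, int], str]] = []
    edges: list[list] = []  # [u, v, path]
    target = params.network_branch_target
    if target == 0 or not domain.any():
        return nodes, edges, occupied

    domain_px = np.argwhere(domain)

    def _add_root() -> bool:
        for _ in range(200):
            p = tuple(map(int, domain_px[rng.integers(len(domain_px))]))
            if not _clear_around(occupied, p, params.clearance_px + 1, set()):
                continue
            ang = rng.uniform(0, 2 * math.pi)
            length = int(rng.integers(params.branch_len_min, params.branch_len_max + 1))
            path = _walk(rng, p, ang, length, domain, occupied, params)
            if len(path) < params.branch_len_min:
                continue
            u = len(nodes)
            nodes.append((p, "endpoint"))
            v = len(nodes)
            nodes.append((path[-1], "endpoint"))
            edges.append([u, v, path[:-1]])
            occupied[p] = True
            for q in path:
                occupied[q] = True
            return True
        return False

    def _add_attached() -> bool:
        candidates = [
            (ei, j)
            for ei, (_, _, path) in enumerate(edges)
            for j in range(5, len(path) - 5)
        ]
        if not candidates:
            return False
        node_px = [p for p, _ in nodes]
        for _ in range(150):
            ei, j = candidates[rng.integers(len(candidates))]
            x = edges[ei][2][j]
            if any(math.hypot(x[0] - q[0], x[1] - q[1]) < _MIN_NODE_SEP for q in node_px):
                continue
            prev_px = edges[ei][2][j - 1]
            next_px = edges[ei][2][j + 1]
            tang = math.atan2(next_px[0] - prev_px[0], next_px[1] - prev_px[1])
            ang = tang + rng.choice([-1.0, 1.0]) * (math.pi / 2) + rng.normal(0, 0.25)
            length = int(rng.integers(params.branch_len_min, params.branch_len_max + 1))
            path = _walk(rng, x, ang, length, domain, occupied, params)
            if len(path) < params.branch_len_min:
                continue
            # split host edge at x
            u_host, v_host, host_path = edges[ei]
            jn = len(nodes)
            nodes.append((x, "junction"))
            edges[ei] = [u_host, jn, host_path[:j]]
            edges.append([jn, v_host, host_path[j + 1:]])
            tip = len(nodes)
            nodes.append((path[-1], "endpoint"))
            edges.append([jn, tip, path[:-1]])
            for q in path:
                occupied[q] = True
            return True
        return False

    failures = 0
    while len(edges) < target and failures < 60:
        snap = (
            [list(n) for n in ([p, k] for p, k in nodes)],
            [[u, v, list(p)] for u, v, p in edges],
            occupied.copy(),
        )
        if not edges:
            ok = _add_root()
        elif len(edges) == target - 1 or rng.random() < 0.04:
            ok = _add_root()
        else:
            ok = _add_attached()
            if not ok:
                ok = _add_root()
        if ok:
            n_junc = sum(1 for _, kind in nodes if kind == "junction")
            ok = _render_faithful(occupied, radius, len(edges), n_junc)
        if not ok:
            prev_nodes, prev_edges, prev_occ = snap
            nodes[:] = [(tuple(p), k) for p, k in prev_nodes]
            edges[:] = prev_edges
            occupied[:] = prev_occ
        failures = 0 if ok else failures + 1
    return nodes, edges, occupied


def _edges_to_graph(nodes, edges) -> SkeletonGraph:
    g = SkeletonGraph()
    for i, (p, kind) in enumerate(nodes):
        g.nodes.append(
            SkeletonNode(id=i, kind=kind, pixels=(p,), centroid=(float(p[0]), float(p[1])))
        )
    for u, v, path in edges:
        full = [nodes[u][0]] + list(path) + [nodes[v][0]]
        length = sum(
            1.0 if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1 else math.sqrt(2.0)
            for a, b in zip(full[:-1], full[1:])
        )
        g.edges.append(SkeletonEdge(u=u, v=v, path=tuple(path), length=length))
    return g


def truth_network_metrics(truth: SceneTruth, cell_index: int) -> NetworkMetrics:
    """Exact network metrics of one cell, from the generating graph itself."""
    if not 0 <= cell_index < truth.n_cells:
        raise IndexError(f"cell_index {cell_index} out of range (n_cells={truth.n_cells})")
    g = truth.true_skeletons[cell_index]
    n_end = sum(1 for n in g.nodes if n.kind == "endpoint")
    n_junc = sum(1 for n in g.nodes if n.kind == "junction")
    junction_px = sum(len(n.pixels) for n in g.nodes if n.kind == "junction")
    slab_px = sum(len(e.path) for e in g.edges)
    lengths = [e.length for e in g.edges]
    return NetworkMetrics(
        n_branches=len(g.edges),
        n_actual_junctions=n_junc,
        n_endpoint_px=n_end,
        n_slab_px=slab_px,
        n_junction_px=junction_px,
        avg_branch_length=float(np.mean(lengths)) if lengths else None,
        total_skeleton_px=n_end + slab_px + junction_px,
    )


# ---------------------------------------------------------------------------
# dot placement


def _sample_separated(rng, candidates: np.ndarray, count: int, min_sep: float):
    """Pick up to ``count`` candidate pixels pairwise at least min_sep apart
    (separation is relaxed if the region is too small)."""
    chosen: list[tuple[int, int]] = []
    if len(candidates) == 0 or count == 0:
        return chosen
    order = rng.permutation(len(candidates))
    for idx in order:
        p = tuple(map(int, candidates[idx]))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in chosen):
            chosen.append(p)
        if len(chosen) == count:
            return chosen
    for idx in order:  # relaxation pass
        if len(chosen) == count:
            break
        p = tuple(map(int, candidates[idx]))
        if p not in chosen:
            chosen.append(p)
    return chosen


def _paint_disks(target: np.ndarray, centers, radius, values) -> None:
    """values: per-center 2-D patch callback or constant; paints max()."""
    foot = disk(radius).astype(bool)
    h, w = target.shape
    for (r, c), val in zip(centers, values):
        r0, c0 = r - radius, c - radius
        for dr, dc in zip(*np.nonzero(foot)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < h and 0 <= cc < w:
                target[rr, cc] = max(target[rr, cc], val)


# ---------------------------------------------------------------------------
# scene assembly


def _pattern_region(pattern, cytoplasm, cell) -> np.ndarray:
    if pattern == "perinuclear_aggregated":
        dist = ndi.distance_transform_edt(~_nucleus_of(cell))
        region = cytoplasm & (dist <= 10)
    else:  # anterior_dotlike
        cy, cx = cell["center"]
        ncy, ncx = cell["nucleus_center"]
        ur, uc = cy - ncy, cx - ncx  # away from the nucleus offset
        norm = math.hypot(ur, uc)
        if norm < 1e-9:
            ur, uc = 1.0, 0.0
        else:
            ur, uc = ur / norm, uc / norm
        yy, xx = np.mgrid[: cytoplasm.shape[0], : cytoplasm.shape[1]]
        dy, dx = yy - cy, xx - cx
        rad = np.hypot(dy, dx)
        cosang = np.where(rad > 0, (dy * ur + dx * uc) / np.maximum(rad, 1e-9), 1.0)
        region = cytoplasm & (cosang >= math.cos(math.pi / 4))
    return region


def _nucleus_of(cell) -> np.ndarray:
    return cell["nucleus_mask"]


def _render_ideal(params: SceneParams, rng):
    """Rasterize the noise-free, blur-free integer scene plus ground truth."""
    size = params.image_size
    shape = (size, size)
    cells = _place_cells(params, rng)

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(cells, start=1):
        cmask = _ellipse_mask(shape, c["center"], c["rx"], c["ry"], c["theta"])
        nmask = _ellipse_mask(
            shape, c["nucleus_center"], c["nucleus_r"], 0.85 * c["nucleus_r"], c["theta"]
        )
        nmask &= cmask
        c["cell_mask"] = cmask
        c["nucleus_mask"] = nmask
        cell_labels[cmask] = i
        nucleus_labels[nmask] = i

    ideal = {name: np.zeros(shape, dtype=np.int64) for name in CHANNEL_NAMES}
    tex_lo = int(TEXTURE_LO_FRAC * FOREGROUND)
    scale = params.intensity_ratio
    off_amp = int(round(scale * OFF_DOT_AMP_FRAC * FOREGROUND))
    mt_amp = int(MT_AMP_FRAC * FOREGROUND)
    radius = max(0, (params.tubule_width_px - 1) // 2)

    cytoplasm_masks: list[np.ndarray] = []
    skeleton_graphs: list[SkeletonGraph] = []
    n_dots_total = 0
    n_on_total = 0

    for i, c in enumerate(cells):
        cmask, nmask = c["cell_mask"], c["nucleus_mask"]
        cyto = cmask & ~nmask
        cytoplasm_masks.append(cyto)

        ideal["nucleus"][nmask] = FOREGROUND
        ideal["clld"][cmask] = np.maximum(ideal["clld"][cmask], FILL_LEVEL)

        nodes, edges, skel_mask = _grow_network(rng, cyto, params)
        skeleton_graphs.append(_edges_to_graph(nodes, edges))
        ribbon = (
            ndi.binary_dilation(skel_mask, structure=disk(radius), border_value=0)
            if radius > 0
            else skel_mask.copy()
        )
        ribbon &= cmask
        n_ribbon = int(ribbon.sum())
        if n_ribbon:
            ideal["clld"][ribbon] = rng.integers(tex_lo, FOREGROUND + 1, size=n_ribbon)

        # vesicle-like clld puncta off the ribbon
        keepout = ndi.binary_dilation(ribbon, structure=disk(DOT_RADIUS + 3), border_value=0)
        inner = ndi.binary_erosion(cyto, structure=disk(DOT_RADIUS), border_value=0)
        puncta_centers = _sample_separated(
            rng, np.argwhere(inner & ~keepout), params.puncta_count, 2.0 * DOT_RADIUS + 1
        )
        for p in puncta_centers:
            foot = np.zeros(shape, dtype=bool)
            _paint_disks(foot, [p], DOT_RADIUS, [1])
            foot &= cmask
            n = int(foot.sum())
            if n:
                ideal["clld"][foot] = np.maximum(
                    ideal["clld"][foot], rng.integers(tex_lo, FOREGROUND + 1, size=n)
                )

        # nanoparticle dots: on-structure fraction proportional to the local
        # clld signal (accumulation on the lipophilic structure), the rest at
        # independent positions in the condition-specific pattern region
        n_dots = params.aunc_dot_count
        k_on = int(round(params.coloc_fraction * n_dots))
        skel_px = np.argwhere(skel_mask)
        if len(skel_px) == 0:
            k_on = 0
        on_centers = _sample_separated(rng, skel_px, k_on, 2.0 * DOT_RADIUS + 1)
        clld_fg = ribbon.copy()
        for p in puncta_centers:
            _paint_disks(clld_fg, [p], DOT_RADIUS, [True])
        off_region = (
            _pattern_region(params.pattern, cyto, c)
            & inner
            & ~ndi.binary_dilation(clld_fg, structure=disk(DOT_RADIUS + 2), border_value=0)
        )
        if off_region.sum() < 4 * (n_dots - len(on_centers)):
            off_region = inner & ~ndi.binary_dilation(
                clld_fg, structure=disk(DOT_RADIUS + 2), border_value=0
            )
        off_centers = _sample_separated(
            rng, np.argwhere(off_region), n_dots - len(on_centers), 2.0 * DOT_RADIUS + 1
        )
        n_dots_total += len(on_centers) + len(off_centers)
        n_on_total += len(on_centers)

        on_foot = np.zeros(shape, dtype=bool)
        _paint_disks(on_foot, on_centers, DOT_RADIUS, [True] * len(on_centers))
        on_foot &= cmask
        ideal["aunc"][on_foot] = np.maximum(
            ideal["aunc"][on_foot], np.round(scale * ideal["clld"][on_foot]).astype(np.int64)
        )
        off_foot = np.zeros(shape, dtype=bool)
        _paint_disks(off_foot, off_centers, DOT_RADIUS, [True] * len(off_centers))
        off_foot &= cyto
        ideal["aunc"][off_foot] = np.maximum(ideal["aunc"][off_foot], off_amp)

        # marker channel: spatially coupled to the nanoparticle dots in the
        # anterior pattern, independent otherwise
        if params.pattern == "anterior_dotlike":
            mt_centers = [
                (
                    int(np.clip(p[0] + rng.integers(-1, 2), 0, size - 1)),
                    int(np.clip(p[1] + rng.integers(-1, 2), 0, size - 1)),
                )
                for p in on_centers + off_centers
            ]
        else:
            mt_centers = _sample_separated(
                rng, np.argwhere(inner), n_dots, 2.0 * DOT_RADIUS + 1
            )
        mt_foot = np.zeros(shape, dtype=bool)
        _paint_disks(mt_foot, mt_centers, DOT_RADIUS, [True] * len(mt_centers))
        mt_foot &= cmask
        ideal["mt1mmp"][mt_foot] = mt_amp

    true_cyto_means = [
        {name: float(ideal[name][cyto].mean()) if cyto.any() else 0.0 for name in CHANNEL_NAMES}
        for cyto in cytoplasm_masks
    ]
    truth = SceneTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        cytoplasm_masks=cytoplasm_masks,
        true_skeletons=skeleton_graphs,
        true_coloc_fraction=(n_on_total / n_dots_total) if n_dots_total else 0.0,
        true_intensity_means={
            "nucleus": float(FOREGROUND),
            "clld": float((tex_lo + FOREGROUND) / 2.0),
            "mt1mmp": float(mt_amp),
            "aunc": float(scale * OFF_DOT_AMP_FRAC * FOREGROUND),
        },
        true_cytoplasm_means=true_cyto_means,
        n_cells=len(cells),
    )
    return ideal, truth


def _degrade(ideal: np.ndarray, rng, snr: float, psf_sigma_px: float) -> np.ndarray:
    """PSF blur, then Poisson shot noise scaled to ``snr``, then read noise."""
    x = ideal.astype(np.float64)
    if psf_sigma_px > 0:
        x = ndi.gaussian_filter(x, sigma=psf_sigma_px)
    if math.isfinite(snr):
        x = x + BG_PEDESTAL
        gain = BG_PEDESTAL * snr**2 / FOREGROUND**2
        x = rng.poisson(np.maximum(x, 0.0) * gain) / gain
        x = x + rng.normal(0.0, FOREGROUND / (3.0 * snr), size=x.shape)
    return np.clip(np.round(x), 0, 65535).astype(np.uint16)


def generate_scene(params: SceneParams) -> tuple[MultiChannelImage, SceneTruth]:
    """Generate one multi-channel scene plus its ground truth.

    Identical parameters (including the seed) produce bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ideal, truth = _render_ideal(params, rng)
    channels = {
        name: _degrade(ideal[name], rng, params.snr, params.psf_sigma_px)
        for name in CHANNEL_NAMES
    }
    return MultiChannelImage(channels=channels), truth


def generate_condition_pair(params: SceneParams):
    """Two matched scenes emulating the passive vs receptor-targeted contrast.

    Condition 1: perinuclear aggregated pattern, low co-localized fraction
    (0.2), unit intensity, the given branch target.  Condition 2: anterior
    dot-like pattern, high co-localized fraction (0.75), nanoparticle
    amplitudes multiplied by ``params.intensity_ratio``, and a denser
    network (branch target scaled by ``NETWORK_DENSITY_FACTOR``).  Scene
    seeds derive deterministically from ``params.seed``.
    """
    params.validate()
    p1 = replace(
        params,
        pattern="perinuclear_aggregated",
        coloc_fraction=COND1_COLOC_FRACTION,
        intensity_ratio=1.0,
        seed=child_seed(params.seed, 1),
    )
    p2 = replace(
        params,
        pattern="anterior_dotlike",
        coloc_fraction=COND2_COLOC_FRACTION,
        intensity_ratio=params.intensity_ratio,
        network_branch_target=NETWORK_DENSITY_FACTOR * params.network_branch_target,
        seed=child_seed(params.seed, 2),
    )
    return generate_scene(p1), generate_scene(p2)


def generate_replicated_scene(params: SceneParams, k: int):
    """A scene of ``k`` identical copies of one generated cell.

    The cell (geometry, network, dots) is generated once and stamped at
    ``k`` non-overlapping grid positions; blur and noise are then applied to
    the assembled field, so the copies share structure but not noise.  Used
    to test that per-cell-normalized multi-cell metrics reproduce
    single-cell metrics.
    """
    params.validate()
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(params.seed)
    tile = int(2 * math.ceil(params.cell_radius_px * (1 + params.cell_radius_jitter)) + 12)
    tparams = replace(params, image_size=tile, n_cells=1)
    ideal, truth1 = _render_ideal(tparams, rng)

    ncols = int(math.ceil(math.sqrt(k)))
    nrows = int(math.ceil(k / ncols))
    shape = (nrows * tile, ncols * tile)
    big_ideal = {name: np.zeros(shape, dtype=np.int64) for name in CHANNEL_NAMES}
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cyto_masks: list[np.ndarray] = []
    graphs: list[SkeletonGraph] = []
    for i in range(k):
        r0 = (i // ncols) * tile
        c0 = (i % ncols) * tile
        for name in CHANNEL_NAMES:
            big_ideal[name][r0 : r0 + tile, c0 : c0 + tile] = ideal[name]
        cell_labels[r0 : r0 + tile, c0 : c0 + tile][truth1.cell_labels == 1] = i + 1
        nucleus_labels[r0 : r0 + tile, c0 : c0 + tile][truth1.nucleus_labels == 1] = i + 1
        cyto = np.zeros(shape, dtype=bool)
        cyto[r0 : r0 + tile, c0 : c0 + tile] = truth1.cytoplasm_masks[0]
        cyto_masks.append(cyto)
        g0 = truth1.true_skeletons[0]
        g = SkeletonGraph()
        for n in g0.nodes:
            px = tuple((p[0] + r0, p[1] + c0) for p in n.pixels)
            g.nodes.append(
                SkeletonNode(
                    id=n.id,
                    kind=n.kind,
                    pixels=px,
                    centroid=(n.centroid[0] + r0, n.centroid[1] + c0),
                )
            )
        for e in g0.edges:
            g.edges.append(
                SkeletonEdge(
                    u=e.u,
                    v=e.v,
                    path=tuple((p[0] + r0, p[1] + c0) for p in e.path),
                    length=e.length,
                )
            )
        graphs.append(g)

    channels = {
        name: _degrade(big_ideal[name], rng, params.snr, params.psf_sigma_px)
        for name in CHANNEL_NAMES
    }
    truth = SceneTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        cytoplasm_masks=cyto_masks,
        true_skeletons=graphs,
        true_coloc_fraction=truth1.true_coloc_fraction,
        true_intensity_means=dict(truth1.true_intensity_means),
        true_cytoplasm_means=[dict(truth1.true_cytoplasm_means[0]) for _ in range(k)],
        n_cells=k,
    )
    return MultiChannelImage(channels=channels), truth
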