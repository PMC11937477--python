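"""Airway tree extraction and cross-section geometry.

The CT-like volume is the morphological reference: the lumen is segmented by
thresholded region growing from a tracheal seed, skeletonized to a rooted
centerline tree, generations are counted from the trachea (generation 0),
and the four third-generation lobar paths (RUL, RLL, LUL, LLL) are selected
for measurement.  Cross-sections perpendicular to the local bronchial axis
are resampled at sub-voxel spacing for wall quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .volume import ImageVolume

#: CT-like air threshold (HU-analog) separating lumen air from wall tissue
AIR_THRESHOLD = -500.0
#: CT-like intensity above which a proximal lumen counts as mucus-plugged
PLUG_THRESHOLD = -300.0


class SeedError(ValueError):
    """Seed point does not lie in air-range intensity."""


class SelectionError(ValueError):
    """A requested lobe has no branch at the requested generation."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"no generation-3 branch found for lobes: {', '.join(self.missing)}")


def segment_lumen(
    ct: ImageVolume, seed_mm, threshold: float = AIR_THRESHOLD, connectivity: int = 1
) -> np.ndarray:
    """Segment the airway lumen as the air-range component containing the seed.

    Leakage into background air is prevented by connectivity: only the
    connected component of sub-threshold voxels reachable from the internal
    tracheal seed is kept.  Face connectivity (``connectivity=1``) is the
    default: it cannot jump a wall thinner than the voxel diagonal, which
    full 26-connectivity (``connectivity=3``) can.
    """
    seed_idx = np.round(ct.world_to_index(np.asarray(seed_mm, dtype=float))).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(ct.shape)):
        raise SeedError(f"seed index {tuple(seed_idx)} outside the volume")
    if ct.data[tuple(seed_idx)] >= threshold:
        raise SeedError(
            f"seed intensity {ct.data[tuple(seed_idx)]:.0f} is not in the air range (< {threshold})"
        )
    air = ct.data < threshold
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, _ = ndimage.label(air, structure=structure)
    return labels == labels[tuple(seed_idx)]


@dataclass
class BranchPath:
    """A centerline branch between two topology events (root/bifurcation/tip)."""

    id: int
    parent: int | None
    points_mm: np.ndarray  # (N, 3) ordered proximal -> distal
    generation: int = -1
    lobe: str | None = None
    children: list = field(default_factory=list)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)))

    def tangents(self) -> np.ndarray:
        """Unit tangents from centered finite differences of the smoothed line."""
        p = self.points_mm
        if len(p) < 2:
            raise ValueError("branch needs >= 2 points for tangents")
        t = np.gradient(p, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at_arclength(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (position, unit tangent) at arc length s from the proximal end."""
        seg = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = float(np.clip(s, 0.0, cum[-1]))
        pos = np.array([np.interp(s, cum, self.points_mm[:, k]) for k in range(3)])
        tans = self.tangents()
        tan = np.array([np.interp(s, cum, tans[:, k]) for k in range(3)])
        return pos, tan / np.linalg.norm(tan)


@dataclass
class AirwayTree:
    """Rooted centerline tree: branches keyed by id, root id, source affine."""

    branches: dict
    root: int
    affine: np.ndarray

    def branch(self, branch_id: int) -> BranchPath:
        return self.branches[branch_id]

    def branches_at_generation(self, generation: int) -> list[BranchPath]:
        return [b for b in self.branches.values() if b.generation == generation]

    def terminal_branches(self) -> list[BranchPath]:
        return [b for b in self.branches.values() if not b.children]

    def max_generation(self) -> int:
        return max(b.generation for b in self.branches.values())

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "branches": [
                {
                    "id": b.id,
                    "parent": b.parent,
                    "generation": b.generation,
                    "lobe": b.lobe,
                    "points_mm": b.points_mm.tolist(),
                }
                for b in self.branches.values()
            ],
        }


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """26-connected graph over skeleton voxels with Euclidean edge weights."""
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    for i, c in enumerate(coords):
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None:
                g.add_edge(i, j, weight=float(np.linalg.norm(off)))
    return g, coords


def _smooth_polyline(points: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-smooth a polyline along its arc, keeping the endpoints fixed."""
    if len(points) < 5:
        return points
    sm = np.stack(
        [ndimage.gaussian_filter1d(points[:, k], sigma, mode="nearest") for k in range(3)], axis=1
    )
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def extract_centerline(
    lumen_mask: np.ndarray,
    affine: np.ndarray,
    seed_mm=None,
    prune_length_mm: float = 3.0,
) -> AirwayTree:
    """Skeletonize the lumen mask and build a rooted branch tree.

    The skeleton voxel graph is reduced to a spanning tree from the voxel
    nearest the tracheal seed (or the most superior skeleton voxel when no
    seed is given); terminal twigs shorter than ``prune_length_mm`` are
    pruned iteratively, then maximal non-branching paths become
    :class:`BranchPath` objects with smoothed point coordinates.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    skel = skeletonize(lumen_mask)
    if not skel.any():
        raise ValueError("skeletonization produced an empty result")
    g, coords = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton graph")

    aff = np.asarray(affine, dtype=float)
    world = coords @ aff[:3, :3].T + aff[:3, 3]
    if seed_mm is not None:
        anchor = int(np.argmin(np.linalg.norm(world - np.asarray(seed_mm), axis=1)))
    else:
        anchor = int(np.argmax(world[:, 2]))
    if not nx.is_connected(g):
        comp = nx.node_connected_component(g, anchor)
        if len(comp) < 0.5 * g.number_of_nodes():
            raise ValueError("lumen skeleton is disconnected from the seed component")
        g = g.subgraph(comp).copy()

    # spanning tree (drops any small skeleton cycles)
    und = nx.bfs_tree(g, anchor).to_undirected()

    def edge_len(u, v):
        return float(np.linalg.norm(world[u] - world[v]))

    # iterative twig pruning on the voxel tree
    changed = True
    while changed:
        changed = False
        junctions = {n for n in und.nodes if und.degree(n) >= 3}
        leaves = [n for n in und.nodes if und.degree(n) == 1]
        for leaf in leaves:
            if leaf not in und:
                continue
            path = [leaf]
            cur = leaf
            length = 0.0
            nxt = None
            while True:
                nbrs = [n for n in und.neighbors(cur) if n not in path]
                if not nbrs:
                    nxt = None
                    break
                nxt = nbrs[0]
                length += edge_len(cur, nxt)
                if nxt in junctions:
                    break
                path.append(nxt)
                cur = nxt
            if nxt is not None and length < prune_length_mm:
                und.remove_nodes_from(path)
                changed = True

    # root at the remaining skeleton endpoint nearest the tracheal seed
    endpoints = [n for n in und.nodes if und.degree(n) <= 1]
    if not endpoints:
        raise ValueError("skeleton has no endpoints after pruning")
    if seed_mm is not None:
        root_vox = min(endpoints, key=lambda n: float(np.linalg.norm(world[n] - np.asarray(seed_mm))))
    else:
        root_vox = max(endpoints, key=lambda n: world[n][2])

    # decompose into maximal non-branching paths
    deg = dict(und.degree())
    events = {n for n, d in deg.items() if d != 2} | {root_vox}
    branches: dict[int, BranchPath] = {}
    visited_edges = set()
    queue = [(root_vox, None)]
    next_id = 0
    while queue:
        start, parent_id = queue.pop(0)
        for nb in und.neighbors(start):
            if (start, nb) in visited_edges:
                continue
            path = [start, nb]
            visited_edges.add((start, nb))
            visited_edges.add((nb, start))
            cur, prev = nb, start
            while cur not in events:
                nxts = [n for n in und.neighbors(cur) if n != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                visited_edges.add((prev, cur))
                visited_edges.add((cur, prev))
                path.append(cur)
            pts = _smooth_polyline(world[path])
            br = BranchPath(id=next_id, parent=parent_id, points_mm=pts)
            branches[next_id] = br
            if parent_id is not None:
                branches[parent_id].children.append(next_id)
            queue.append((cur, next_id))
            next_id += 1

    if not branches:
        raise ValueError("no branches extracted from the skeleton")
    result = AirwayTree(branches=branches, root=0, affine=aff)
    return label_generations(result)


def label_generations(tree: AirwayTree) -> AirwayTree:
    """Label generations: trachea = 0, +1 at each bifurcation.

    A node with a single child continues its parent's generation (a branch
    split by a pruned twig is not a bifurcation).  Idempotent.
    """
    if tree.root not in tree.branches:
        raise ValueError("tree has no root branch")
    tree.branches[tree.root].generation = 0
    stack = [tree.root]
    while stack:
        bid = stack.pop()
        b = tree.branches[bid]
        inc = 1 if len(b.children) >= 2 else 0
        for cid in b.children:
            tree.branches[cid].generation = b.generation + inc
            stack.append(cid)
    return tree


def check_mucus_plug(
    ct: ImageVolume,
    branch: BranchPath,
    threshold: float = PLUG_THRESHOLD,
) -> tuple[bool, float]:
    """Automated mucus-plug surrogate for the visual exclusion call.

    Samples the CT-like intensity along the proximal third of the branch
    centerline; a mean above ``threshold`` (HU-analog) means the lumen there
    is filled with soft-tissue-range material and the bronchus is excluded.
    """
    pts = branch.points_mm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    prox = pts[cum <= cum[-1] / 3.0]
    if len(prox) < 2:
        prox = pts[:2]
    idx = ct.world_to_index(prox)
    vals = ndimage.map_coordinates(ct.data, idx.T, order=1, mode="nearest")
    mean_val = float(np.mean(vals))
    return mean_val > threshold, mean_val


@dataclass
class PathSelection:
    """Outcome of lobar path selection: kept paths plus exclusion records."""

    paths: dict  # lobe -> BranchPath
    exclusions: list  # list of {"lobe", "reason", "value"}


def select_paths(
    tree: AirwayTree,
    lobe_map: dict,
    generation: int = 3,
    ct: ImageVolume | None = None,
    lumen_mask: np.ndarray | None = None,
    gate_mm: float = 4.0,
) -> PathSelection:
    """Select one generation-3 path per lobe (RUL, RLL, LUL, LLL).

    ``lobe_map`` maps each lobe label to a reference point in mm (from
    phantom ground truth, or user-supplied for real data); the branch at the
    requested generation whose midpoint lies within ``gate_mm`` of the
    reference is chosen.  When a CT-like volume is given, selected paths
    failing the mucus-plug check are recorded and dropped; a lobe whose
    branch is missing from the tree is probed at its reference point — a
    soft-tissue reading or an air pocket disconnected from the segmented
    lumen means proximal plugging (exclusion record), anything else is a
    selection error.
    """
    candidates = tree.branches_at_generation(generation)
    if not candidates:
        raise SelectionError(sorted(lobe_map))
    missing = []
    chosen: dict[str, BranchPath] = {}
    exclusions: list[dict] = []
    taken: set[int] = set()

    def probe_reference(lobe: str, ref: np.ndarray) -> bool:
        """True if the missing branch is explained by proximal plugging."""
        if ct is None:
            return False
        idx = np.round(ct.world_to_index(ref)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(ct.shape)):
            return False
        val = float(ct.data[tuple(idx)])
        if val >= AIR_THRESHOLD:
            exclusions.append(
                {"lobe": lobe, "reason": "proximal mucus plugging", "value": val}
            )
            return True
        if lumen_mask is not None and not lumen_mask[tuple(idx)]:
            exclusions.append(
                {
                    "lobe": lobe,
                    "reason": "proximal mucus plugging (distal lumen disconnected)",
                    "value": val,
                }
            )
            return True
        return False

    for lobe, ref in lobe_map.items():
        ref = np.asarray(ref, dtype=float)
        free = [b for b in candidates if b.id not in taken]
        dists = [
            float(np.linalg.norm(b.points_mm[len(b.points_mm) // 2] - ref)) for b in free
        ]
        in_gate = [(d, b) for d, b in zip(dists, free) if d <= gate_mm]
        if not in_gate:
            if not probe_reference(lobe, ref):
                missing.append(lobe)
            continue
        best = min(in_gate, key=lambda t: t[0])[1]
        chosen[lobe] = best
        best.lobe = lobe
        taken.add(best.id)
    if missing:
        raise SelectionError(missing)

    if ct is not None:
        for lobe in list(chosen):
            plugged, mean_val = check_mucus_plug(ct, chosen[lobe])
            if plugged:
                exclusions.append(
                    {"lobe": lobe, "reason": "proximal mucus plugging", "value": mean_val}
                )
                del chosen[lobe]
    return PathSelection(paths=chosen, exclusions=exclusions)


@dataclass
class SectionRequest:
    center_mm: np.ndarray
    normal: np.ndarray
    size_mm: float = 16.0
    spacing_mm: float | None = None  # default: half the source voxel size
    path_label: str | None = None
    site: int = 0
    arc_position_mm: float = 0.0


@dataclass
class CrossSection:
    """A 2D plane resampled perpendicular to the bronchial axis."""

    image: np.ndarray
    spacing_mm: float
    center_mm: np.ndarray
    normal: np.ndarray
    axes: np.ndarray  # (2, 3) in-plane orthonormal basis
    path_label: str | None = None
    site: int = 0
    arc_position_mm: float = 0.0
    out_of_bounds: bool = False


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    """Deterministic in-plane orthonormal basis perpendicular to ``normal``."""
    n = normal / np.linalg.norm(normal)
    helper = np.eye(3)[int(np.argmin(np.abs(n)))]
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.stack([e1, e2])


def reformat_cross_section(
    volume: ImageVolume, request: SectionRequest, fill_value: float = np.nan
) -> CrossSection:
    """Resample a 2D plane through the volume perpendicular to ``request.normal``.

    Trilinear interpolation at sub-voxel spacing (default half the voxel
    size); samples outside the volume are padded with ``fill_value`` and the
    section is flagged ``out_of_bounds``.
    """
    normal = np.asarray(request.normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("section normal must be unit length")
    center = np.asarray(request.center_mm, dtype=float)
    idx_c = volume.world_to_index(center)
    if np.any(idx_c < 0) or np.any(idx_c > np.asarray(volume.shape) - 1):
        raise ValueError("section center lies outside the volume")

    spacing = request.spacing_mm or float(np.min(volume.spacing)) / 2.0
    half = request.size_mm / 2.0
    coords_1d = np.arange(-half, half + spacing / 2.0, spacing)
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    basis = _plane_basis(normal)
    pts = center + uu[..., None] * basis[0] + vv[..., None] * basis[1]
    idx = volume.world_to_index(pts.reshape(-1, 3)).T

    inside = np.all((idx >= 0) & (idx <= (np.asarray(volume.shape)[:, None] - 1)), axis=0)
    vals = ndimage.map_coordinates(
        volume.data.astype(float), idx, order=1, mode="constant", cval=0.0
    )
    vals[~inside] = fill_value
    img = vals.reshape(uu.shape)
    return CrossSection(
        image=img,
        spacing_mm=spacing,
        center_mm=center,
        normal=normal / np.linalg.norm(normal),
        axes=basis,
        path_label=request.path_label,
        site=request.site,
        arc_position_mm=request.arc_position_mm,
        out_of_bounds=bool((~inside).any()),
    )


def pick_measurement_sites(
    path: BranchPath,
    n_sites: int = 2,
    lumen_diameter_mm: float | None = None,
    section_size_mm: float = 16.0,
) -> list[SectionRequest]:
    """Centerline locations for wall measurement at fixed arc-length fractions.

    Two sites sit at 1/3 and 2/3 of the branch arc length (one site: the
    midpoint), which keeps them clear of both bifurcation zones on branches
    that satisfy the length precondition.  Branches shorter than two lumen
    diameters are rejected.
    """
    length = path.arc_length
    if lumen_diameter_mm is not None and length < 2.0 * lumen_diameter_mm:
        raise ValueError(
            f"branch too short for measurement: {length:.1f} mm < 2 lumen diameters "
            f"({2.0 * lumen_diameter_mm:.1f} mm)"
        )
    fractions = [(i + 1) / (n_sites + 1) for i in range(n_sites)]
    requests = []
    for site, frac in enumerate(fractions):
        s = frac * length
        pos, tan = path.point_at_arclength(s)
        requests.append(
            SectionRequest(
                center_mm=pos,
                normal=tan,
                size_mm=section_size_mm,
                path_label=path.lobe,
                site=site,
                arc_position_mm=s,
            )
        )
    return requests
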