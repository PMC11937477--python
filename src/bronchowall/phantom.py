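"""Synthetic airway phantom: co-registered CT-like / UTE-like / T2w-like volumes.

The phantom is a symmetric dichotomous airway tree (trachea = generation 0)
rendered as capsule tubes with an annular wall of known lumen radius and wall
thickness per generation, so every downstream measurement has an analytic
ground truth.  The UTE-like volume and the ground truth live on the fixed
grid; the CT-like and T2w-like volumes are rendered through a known smooth
sinusoidal displacement field, emulating breath-hold misalignment between
acquisitions.  MR-like volumes carry Rician noise, the CT-like volume
additive Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume

LOBES = ("RUL", "RLL", "LUL", "LLL")

# label codes used by the analytic scene
_PARENCHYMA, _WALL, _LUMEN, _PLUG = 0, 1, 2, 3

#: per-modality (parenchyma, wall, lumen) mean intensities; the T2w wall
#: entry is overridden by ``wall_t2_signal`` per subject.
DEFAULT_INTENSITIES = {
    "CT-like": (-850.0, 0.0, -1000.0),
    "UTE-like": (30.0, 80.0, 5.0),
    "T2w-like": (40.0, None, 10.0),
}

# noise sigma ratios relative to the T2w sigma, keeping wall SNR comparable
# across modalities (CT wall/parenchyma contrast 850 HU vs T2w wall 60 Au)
_NOISE_RATIO = {"CT-like": 850.0 / 60.0, "UTE-like": 80.0 / 60.0, "T2w-like": 1.0}

#: reference parenchymal texture std per modality (vessel-scale contrast)
_TEXTURE_SCALE = {"CT-like": 50.0, "UTE-like": 8.0, "T2w-like": 5.0}


class PhantomSizingError(ValueError):
    """Grid too small to contain the airway tree at the requested radii."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic airway phantom subject.

    Geometry follows a symmetric dichotomous tree: branch angle 35 degrees,
    generation length ratio 0.85, with the bifurcation plane rotated 90
    degrees at each generation so the eight terminal branches of a depth-3
    tree do not collide.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 0.625  # mm, isotropic
    tree_depth: int = 3  # generations beyond the trachea
    lumen_radius_by_generation: tuple[float, ...] = (3.0, 2.5, 2.1, 1.8)  # mm
    # walls stay well above the voxel size so the rendered shell remains
    # watertight for face-connected region growing even under the shear of
    # the default deformation, and thick enough for the LoG scales to resolve
    wall_thickness_by_generation: tuple[float, ...] = (2.0, 1.8, 1.65, 1.5)  # mm
    trachea_length: float = 15.0  # mm
    length_ratio: float = 0.9
    branch_angle_deg: float = 35.0
    wall_t2_signal: float = 60.0  # Au; the ground-truth inflammation signal
    noise_sigma: float = 6.0  # Au on the T2w-like volume; 0 disables all noise
    #: std of the smooth vascular-like parenchymal texture, as a fraction of
    #: each modality's reference texture contrast; texture is anatomical
    #: (shared across modalities, warped with the scene), unlike noise
    texture_amplitude: float = 1.0
    texture_wavelength_mm: tuple[float, float] = (4.0, 12.0)
    mucus_plug_paths: tuple[str, ...] = ()
    deformation_amplitude: float = 3.0  # mm
    deformation_period: float = 40.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.tree_depth + 1
        if len(self.lumen_radius_by_generation) < n or len(self.wall_thickness_by_generation) < n:
            raise ValueError("need one radius and one wall thickness per generation 0..tree_depth")
        if any(r <= 0 for r in self.lumen_radius_by_generation[:n]):
            raise ValueError("lumen radii must be positive")
        if any(t <= 0 for t in self.wall_thickness_by_generation[:n]):
            raise ValueError("wall thicknesses must be positive")
        if self.deformation_amplitude > 0:
            # strict fold-free bound for a sinusoid: A * 2*pi / P < 1
            if self.deformation_amplitude * 2.0 * np.pi / self.deformation_period >= 1.0:
                raise ValueError(
                    "deformation amplitude too large for the period: displacement would fold"
                )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def outer_radius(self, generation: int) -> float:
        return (
            self.lumen_radius_by_generation[generation]
            + self.wall_thickness_by_generation[generation]
        )

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size


@dataclass
class Branch:
    """One straight tube segment of the airway tree."""

    id: int
    parent: int | None
    generation: int
    p0: np.ndarray  # proximal end, mm
    p1: np.ndarray  # distal end, mm
    axis: np.ndarray  # bifurcation-plane normal used for the children
    lumen_radius: float
    wall_thickness: float
    lobe: str | None = None
    child_index: int = 0

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def outer_radius(self) -> float:
        return self.lumen_radius + self.wall_thickness


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of vector v about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle))
    )


def build_tree(spec: PhantomSpec) -> list[Branch]:
    """Construct the branch list of the symmetric dichotomous tree."""
    extent = spec.extent_mm
    center_xy = extent[:2] / 2.0
    top_margin = spec.outer_radius(0) + 2.0 * spec.voxel_size
    p0 = np.array([center_xy[0], center_xy[1], extent[2] - top_margin])
    d0 = np.array([0.0, 0.0, -1.0])
    a0 = np.array([1.0, 0.0, 0.0])

    branches: list[Branch] = [
        Branch(
            id=0,
            parent=None,
            generation=0,
            p0=p0,
            p1=p0 + d0 * spec.trachea_length,
            axis=a0,
            lumen_radius=spec.lumen_radius_by_generation[0],
            wall_thickness=spec.wall_thickness_by_generation[0],
        )
    ]
    angle = np.deg2rad(spec.branch_angle_deg)
    frontier = [branches[0]]
    for gen in range(1, spec.tree_depth + 1):
        length = spec.trachea_length * spec.length_ratio**gen
        new_frontier = []
        for parent in frontier:
            d = parent.direction
            for ci, sign in enumerate((+1.0, -1.0)):
                cd = _rotate(d, parent.axis, sign * angle)
                cd /= np.linalg.norm(cd)
                ca = np.cross(d, parent.axis)
                ca -= np.dot(ca, cd) * cd
                ca /= np.linalg.norm(ca)
                br = Branch(
                    id=len(branches),
                    parent=parent.id,
                    generation=gen,
                    p0=parent.p1.copy(),
                    p1=parent.p1 + cd * length,
                    axis=ca,
                    lumen_radius=spec.lumen_radius_by_generation[gen],
                    wall_thickness=spec.wall_thickness_by_generation[gen],
                    child_index=ci,
                )
                branches.append(br)
                new_frontier.append(br)
        frontier = new_frontier

    _assign_lobes(branches)
    _check_fits(branches, spec)
    return branches


def _assign_lobes(branches: list[Branch]) -> None:
    """Label the four generation-2 branches RUL/RLL/LUL/LLL; descendants inherit.

    Laterality from the branch midpoint's first in-plane coordinate relative
    to the trachea (radiological convention: smaller x = patient right), and
    upper/lower from the superior-inferior midpoint within each side.
    """
    by_id = {b.id: b for b in branches}
    gen2 = [b for b in branches if b.generation == 2]
    if not gen2:
        return
    root = by_id[0]
    lateral_axes = [0, 1]
    mids = {b.id: (b.p0 + b.p1) / 2.0 for b in gen2}
    # pick the lateral axis with the larger spread among gen-2 midpoints
    spread = [np.ptp([mids[b.id][ax] for b in gen2]) for ax in lateral_axes]
    ax = lateral_axes[int(np.argmax(spread))]
    x0 = root.p0[ax]
    right = sorted((b for b in gen2 if mids[b.id][ax] <= x0), key=lambda b: -mids[b.id][2])
    left = sorted((b for b in gen2 if mids[b.id][ax] > x0), key=lambda b: -mids[b.id][2])
    for side, names in ((right, ("RUL", "RLL")), (left, ("LUL", "LLL"))):
        for b, name in zip(side, names):
            b.lobe = name
    # descendants inherit the lobe of their generation-2 ancestor
    for b in branches:
        if b.generation > 2 and b.lobe is None:
            anc = b
            while anc.generation > 2:
                anc = by_id[anc.parent]
            b.lobe = anc.lobe


def _check_fits(branches: list[Branch], spec: PhantomSpec) -> None:
    extent = spec.extent_mm
    for b in branches:
        margin = b.outer_radius + spec.voxel_size
        for p in (b.p0, b.p1):
            if np.any(p - margin < 0) or np.any(p + margin > extent):
                raise PhantomSizingError(
                    f"branch {b.id} (generation {b.generation}) does not fit the "
                    f"{tuple(spec.grid_shape)} grid at voxel size {spec.voxel_size} mm"
                )


# ---------------------------------------------------------------------------
# analytic scene


def _segment_params(points: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Distance from points (N,3) to segment p0-p1 plus the arc parameter t."""
    ab = p1 - p0
    denom = float(np.dot(ab, ab))
    t = np.clip(((points - p0) @ ab) / denom, 0.0, 1.0)
    closest = p0 + t[:, None] * ab
    d = np.linalg.norm(points - closest, axis=1)
    return d, t


def is_designated_path(branch: Branch, depth: int) -> bool:
    """The measured path of a lobe: the child-0 branch at the terminal generation."""
    return branch.generation == depth and branch.child_index == 0


def scene_labels(points: np.ndarray, branches: list[Branch], plug_lobes=()) -> np.ndarray:
    """Material label (parenchyma/wall/lumen/plug) at arbitrary world points.

    A point is lumen if it lies inside any branch's lumen capsule (plugged
    proximal thirds excluded), plug if only inside a plugged region, wall if
    inside any outer capsule but not lumen/plug.  Plugging occludes the
    proximal third of the designated (measured) branch of the named lobes.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    lumen = np.zeros(n, dtype=bool)
    plug = np.zeros(n, dtype=bool)
    wall = np.zeros(n, dtype=bool)
    plug_lobes = set(plug_lobes)
    depth = max(b.generation for b in branches)
    for b in branches:
        d, t = _segment_params(points, b.p0, b.p1)
        in_lumen = d <= b.lumen_radius
        in_wall = d <= b.outer_radius
        plugged_here = b.lobe in plug_lobes and is_designated_path(b, depth)
        if plugged_here:
            blocked = in_lumen & (t <= 1.0 / 3.0)
            lumen |= in_lumen & ~blocked
            plug |= blocked
        else:
            lumen |= in_lumen
        wall |= in_wall
    labels = np.zeros(n, dtype=np.uint8)
    labels[wall] = _WALL
    labels[plug & ~lumen] = _PLUG
    labels[lumen] = _LUMEN
    return labels


def _intensity_lut(modality: str, wall_t2_signal: float) -> np.ndarray:
    par, wall, lumen = DEFAULT_INTENSITIES[modality]
    if wall is None:
        wall = wall_t2_signal
    return np.array([par, wall, lumen, wall], dtype=float)  # plug renders as wall


def scene_distances(points: np.ndarray, branches: list[Branch], plug_lobes=()):
    """Signed distances (mm) to the open-lumen and outer-wall surfaces.

    Negative inside.  Plugged proximal thirds are excluded from the open
    lumen (they belong to the wall-intensity plug material but still lie
    inside the outer capsule).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    sd_lumen = np.full(n, np.inf)
    sd_outer = np.full(n, np.inf)
    plug_lobes = set(plug_lobes)
    depth = max(b.generation for b in branches)
    for b in branches:
        d, _ = _segment_params(points, b.p0, b.p1)
        np.minimum(sd_outer, d - b.outer_radius, out=sd_outer)
        if b.lobe in plug_lobes and is_designated_path(b, depth):
            # open lumen is the distal two thirds, cut by a flat plug face
            # (intersection with the half-space beyond t = 1/3, not a capsule,
            # so no end-sphere reaches back through the plug)
            length = b.length
            s_mm = (points - b.p0) @ (b.p1 - b.p0) / length
            sd_open = np.maximum(d - b.lumen_radius, length / 3.0 - s_mm)
            np.minimum(sd_lumen, sd_open, out=sd_lumen)
        else:
            np.minimum(sd_lumen, d - b.lumen_radius, out=sd_lumen)
    return sd_lumen, sd_outer


@dataclass
class CosineTexture:
    """Smooth random scalar field: a sum of random 3D cosines, unit std.

    Evaluated analytically at arbitrary world points, so the texture warps
    exactly with the scene.  Emulates the vascular texture that gives real
    parenchyma its registration traction; the same field underlies all
    modalities of a subject.
    """

    wavevectors: np.ndarray  # (K, 3) rad/mm
    phases: np.ndarray  # (K,)
    amplitudes: np.ndarray  # (K,)

    @classmethod
    def random(cls, rng: np.random.Generator, wavelength_mm=(4.0, 12.0), k: int = 32):
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wl = rng.uniform(wavelength_mm[0], wavelength_mm[1], k)
        wavevectors = dirs * (2.0 * np.pi / wl)[:, None]
        phases = rng.uniform(0.0, 2.0 * np.pi, k)
        amps = rng.uniform(0.5, 1.0, k)
        amps = amps / np.sqrt(0.5 * np.sum(amps**2))  # unit field std
        return cls(wavevectors, phases, amps)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = np.zeros(points.shape[:-1])
        for kv, ph, a in zip(self.wavevectors, self.phases, self.amplitudes):
            out += a * np.cos(points @ kv + ph)
        return out


# ---------------------------------------------------------------------------
# deformation


@dataclass
class SinusoidDeformation:
    """Smooth low-frequency sinusoidal displacement field, analytically defined.

    ``u`` maps a world position to a displacement in mm.  Each displacement
    component is a sine of one of the other two coordinates, with phases
    drawn once from the seed, so the field is fold-free whenever
    amplitude * 2*pi / period < 1.
    """

    amplitude: float
    period: float
    phases: np.ndarray

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if self.amplitude == 0:
            return np.zeros_like(points)
        w = 2.0 * np.pi / self.period
        out = np.empty_like(points)
        out[..., 0] = np.sin(w * points[..., 2] + self.phases[0])
        out[..., 1] = np.sin(w * points[..., 0] + self.phases[1])
        out[..., 2] = np.sin(w * points[..., 1] + self.phases[2])
        return self.amplitude * out

    def inverse_map(self, points: np.ndarray, tol: float = 1e-4, max_iter: int = 50) -> np.ndarray:
        """Solve y + u(y) = x for y by fixed-point iteration (contraction)."""
        x = np.asarray(points, dtype=float)
        y = x - self(x)
        for _ in range(max_iter):
            y_new = x - self(y)
            if np.max(np.abs(y_new - y)) < tol:
                y = y_new
                break
            y = y_new
        return y


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the phantom knows analytically about itself."""

    spec: PhantomSpec
    branches: list[Branch]
    deformation: SinusoidDeformation
    wall_t2_signal: float
    lobe_map: dict  # lobe -> reference midpoint (mm) of the designated gen-depth path
    trachea_seed_mm: np.ndarray
    affine: np.ndarray

    def analytic_areas(self, generation: int) -> dict:
        """Analytic LA, WA (mm^2) and WA% of a circular section at a generation."""
        r_in = self.spec.lumen_radius_by_generation[generation]
        r_out = self.spec.outer_radius(generation)
        la = np.pi * r_in**2
        wa = np.pi * (r_out**2 - r_in**2)
        return {"LA": la, "WA": wa, "WA_percent": 100.0 * wa / (wa + la)}

    def centerline(self, branch_id: int, step_mm: float = 0.5) -> np.ndarray:
        b = next(br for br in self.branches if br.id == branch_id)
        n = max(int(np.ceil(b.length / step_mm)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)
        return b.p0 + t[:, None] * (b.p1 - b.p0)

    def displacement_on_grid(self, shape=None) -> np.ndarray:
        """True displacement field sampled on the fixed grid, (X,Y,Z,3) mm."""
        shape = shape or self.spec.grid_shape
        pts = _grid_points(shape, self.affine)
        return self.deformation(pts).reshape(*shape, 3)

    def material_masks(self, shape=None) -> dict:
        """Boolean lumen / wall masks of the undeformed scene on the fixed grid."""
        shape = shape or self.spec.grid_shape
        pts = _grid_points(shape, self.affine)
        labels = scene_labels(
            pts.reshape(-1, 3), self.branches, self.spec.mucus_plug_paths
        ).reshape(shape)
        return {"lumen": labels == _LUMEN, "wall": labels == _WALL, "plug": labels == _PLUG}

    def terminal_branches(self) -> list[Branch]:
        return [b for b in self.branches if b.generation == self.spec.tree_depth]

    def to_json(self, path) -> None:
        payload = {
            "wall_t2_signal": self.wall_t2_signal,
            "seed": self.spec.seed,
            "deformation": {
                "amplitude": self.deformation.amplitude,
                "period": self.deformation.period,
                "phases": self.deformation.phases.tolist(),
            },
            "trachea_seed_mm": self.trachea_seed_mm.tolist(),
            "lobe_map": {k: np.asarray(v).tolist() for k, v in self.lobe_map.items()},
            "branches": [
                {
                    "id": b.id,
                    "parent": b.parent,
                    "generation": b.generation,
                    "lobe": b.lobe,
                    "p0": b.p0.tolist(),
                    "p1": b.p1.tolist(),
                    "lumen_radius": b.lumen_radius,
                    "wall_thickness": b.wall_thickness,
                }
                for b in self.branches
            ],
            "analytic_areas_by_generation": [
                self.analytic_areas(g) for g in range(self.spec.tree_depth + 1)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _grid_points(shape, affine) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float32).reshape(3, -1).T
    return idx @ affine[:3, :3].T + affine[:3, 3]


# ---------------------------------------------------------------------------
# generation


def _render(points: np.ndarray, branches, plug_lobes, modality: str, wall_t2: float,
            texture: CosineTexture | None = None, texture_std: float = 0.0,
            aa_width: float = 0.625, chunk: int = 400_000) -> np.ndarray:
    """Anti-aliased analytic rendering: material intensities are blended
    linearly over ``aa_width`` mm across each surface (partial-volume model),
    so interpolated isocontours stay orientation-unbiased."""
    lut = _intensity_lut(modality, wall_t2)
    i_par, i_wall, i_lumen = lut[_PARENCHYMA], lut[_WALL], lut[_LUMEN]
    out = np.empty(len(points), dtype=np.float32)
    w = max(aa_width, 1e-6)
    for s in range(0, len(points), chunk):
        block = points[s : s + chunk]
        sd_lumen, sd_outer = scene_distances(block, branches, plug_lobes)
        f_inside = np.clip(0.5 - sd_outer / w, 0.0, 1.0)  # wall-or-lumen fraction
        f_lumen = np.clip(0.5 - sd_lumen / w, 0.0, 1.0)
        vals = i_par * (1.0 - f_inside) + i_wall * f_inside
        vals = vals * (1.0 - f_lumen) + i_lumen * f_lumen
        if texture is not None and texture_std > 0:
            par_w = 1.0 - f_inside
            sel = par_w > 0
            if sel.any():
                vals[sel] += texture_std * par_w[sel] * texture(block[sel])
        out[s : s + chunk] = vals
    return out


def _add_noise(data: np.ndarray, sigma: float, rician: bool, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return data
    if rician:
        n1 = rng.normal(0.0, sigma, data.shape)
        n2 = rng.normal(0.0, sigma, data.shape)
        return np.sqrt((data + n1) ** 2 + n2**2).astype(np.float32)
    return (data + rng.normal(0.0, sigma, data.shape)).astype(np.float32)


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom subject.

    Returns
    -------
    (ct, ute, t2w, truth):
        CT-like and T2w-like :class:`ImageVolume` rendered through the true
        displacement field, the UTE-like reference volume, and the
        :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    branches = build_tree(spec)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    shape = tuple(spec.grid_shape)

    phases = rng.uniform(0.0, 2.0 * np.pi, 3)
    deformation = SinusoidDeformation(spec.deformation_amplitude, spec.deformation_period, phases)

    pts = _grid_points(shape, affine)
    # moving volumes sample the scene at the preimage of each fixed-grid point
    # under the warp T(y) = y + u(y); registering them back to the UTE-like
    # frame should therefore recover u on the fixed grid.
    if spec.deformation_amplitude > 0:
        pts_moving = deformation.inverse_map(pts)
    else:
        pts_moving = pts

    texture = (
        CosineTexture.random(rng, spec.texture_wavelength_mm)
        if spec.texture_amplitude > 0
        else None
    )
    plug = spec.mucus_plug_paths
    amp = spec.texture_amplitude

    def render(p, modality):
        return _render(
            p, branches, plug, modality, spec.wall_t2_signal,
            texture=texture, texture_std=amp * _TEXTURE_SCALE[modality],
            aa_width=spec.voxel_size,
        ).reshape(shape)

    ute = render(pts, "UTE-like")
    ct = render(pts_moving, "CT-like")
    t2 = render(pts_moving, "T2w-like")

    sig = spec.noise_sigma
    ct = _add_noise(ct, sig * _NOISE_RATIO["CT-like"], rician=False, rng=rng)
    ute = _add_noise(ute, sig * _NOISE_RATIO["UTE-like"], rician=True, rng=rng)
    t2 = _add_noise(t2, sig * _NOISE_RATIO["T2w-like"], rician=True, rng=rng)

    trachea = branches[0]
    seed_mm = trachea.p0 + trachea.direction * (2.0 * spec.voxel_size + trachea.lumen_radius)

    depth = spec.tree_depth
    lobe_map: dict = {}
    for lobe in LOBES:
        cands = [b for b in branches if b.generation == depth and b.lobe == lobe]
        if cands:
            primary = min(cands, key=lambda b: b.child_index)
            lobe_map[lobe] = (primary.p0 + primary.p1) / 2.0

    truth = GroundTruth(
        spec=spec,
        branches=branches,
        deformation=deformation,
        wall_t2_signal=spec.wall_t2_signal,
        lobe_map=lobe_map,
        trachea_seed_mm=seed_mm,
        affine=affine,
    )
    return (
        ImageVolume(ct, affine, "CT-like"),
        ImageVolume(ute, affine, "UTE-like"),
        ImageVolume(t2, affine, "T2w-like"),
        truth,
    )
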