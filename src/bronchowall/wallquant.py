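"""Bronchial wall quantification on cross-sections.

Lumen area (LA) and wall area (WA) are measured on planes perpendicular to
the bronchial axis with a Laplacian-of-Gaussian (LoG) filter: along each of
R radial rays from the lumen centroid, the inner and outer wall boundaries
are the LoG zero-crossings bracketing the wall's (negative) response
extremum, with sub-sample positions by linear interpolation.  The boundary
polygons give LA and WA by the shoelace formula; WA% = 100*WA/(WA+LA).
Wall masks rasterized back into 3D and applied to the normalized T2w volume
yield the per-patient bronchial-wall T2 mean intensity signal
(BrWall_T2-MIS): site means are averaged per path, path means per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .airway import CrossSection
from .volume import ImageVolume

#: default LoG scale sweep in mm; per section the response-maximizing scale wins
DEFAULT_SIGMA_SWEEP = (0.3, 0.5, 0.8)
N_RAYS = 64
MAX_FAILED_RAY_FRACTION = 0.25


class WallMeasurementError(RuntimeError):
    """The section has no measurable wall (recorded per section, not fatal)."""


@dataclass
class WallMeasurement:
    """Per-cross-section wall measurement."""

    LA: float  # mm^2
    WA: float  # mm^2
    WA_percent: float
    inner_boundary: np.ndarray  # (R, 2) in-plane mm, section coordinates
    outer_boundary: np.ndarray  # (R, 2)
    centroid: np.ndarray  # (2,) lumen centroid, in-plane mm
    section: CrossSection | None = None
    sigma_mm: float = np.nan
    n_failed_rays: int = 0

    @property
    def path_label(self):
        return self.section.path_label if self.section is not None else None

    @property
    def site(self):
        return self.section.site if self.section is not None else None


def wa_percent(WA: float, LA: float) -> float:
    """Normalized wall area: the percentage of WA in the total airway area."""
    if WA < 0 or LA < 0:
        raise ValueError("areas must be non-negative")
    total = WA + LA
    if total <= 0:
        raise ValueError("WA + LA must be positive")
    return 100.0 * WA / total


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _lumen_region(section: CrossSection) -> np.ndarray:
    """Connected low-intensity region around the section center (the lumen)."""
    img = section.image
    finite = np.nan_to_num(img, nan=np.nanmax(img))
    c = (img.shape[0] // 2, img.shape[1] // 2)
    lo, hi = float(finite[c]), float(np.percentile(finite, 99))
    if hi - lo < 1e-9:
        raise WallMeasurementError("uniform section: no lumen/wall contrast")
    thresh = lo + 0.5 * (hi - lo)
    low = finite < thresh
    labels, _ = ndimage.label(low)
    if labels[c] == 0:
        raise WallMeasurementError("section center is not inside a low-intensity lumen")
    return labels == labels[c]


def _crossing_near(log_vals, radii, i_from, i_to) -> float | None:
    """Sub-sample zero-crossing between i_from (outside, >=0) and i_to (inside, <0)."""
    step = 1 if i_to > i_from else -1
    for m in range(i_from, i_to, step):
        if log_vals[m] >= 0 and log_vals[m + step] < 0:
            return _interp_zero(radii[m], radii[m + step], log_vals[m], log_vals[m + step])
    return None


def _ray_profile_boundaries(
    log_vals: np.ndarray,
    radii: np.ndarray,
    r_start: float,
    ref: float,
    max_thickness: float = np.inf,
) -> tuple[float, float] | None:
    """Inner/outer boundary radii from one ray's LoG profile.

    Candidate walls are strong negative LoG local minima (magnitude at least
    30% of the section-level reference response ``ref``) beyond ``r_start``;
    the innermost candidate wins.  The bracketing zero-crossings are found
    with hysteresis: the walk from the extremum continues until the profile
    rises convincingly positive (10% of ``ref``), so weak noise blips inside
    the wall band are skipped, then the actual sign change of that strong
    transition is interpolated to sub-sample precision.  Returns None when
    no zero-crossing pair exists.
    """
    n = len(log_vals)
    pos_thresh = 0.1 * ref
    start = int(np.searchsorted(radii, r_start))
    for i in range(max(start, 1), n - 1):
        if log_vals[i] > -0.3 * ref:
            continue
        if not (log_vals[i] <= log_vals[i - 1] and log_vals[i] <= log_vals[i + 1]):
            continue
        j = i
        while j > 0 and log_vals[j] < pos_thresh:
            j -= 1
        if log_vals[j] < pos_thresh:
            continue
        k = i
        while k < n - 1 and log_vals[k] < pos_thresh:
            k += 1
        if log_vals[k] < pos_thresh:
            continue
        r_in = _crossing_near(log_vals, radii, j, i)
        r_out = _crossing_near(log_vals, radii, k, i)
        if r_in is None or r_out is None:
            continue
        if r_out - r_in > max_thickness:
            # the walk ran past the wall (e.g. onto a neighbouring branch)
            continue
        return r_in, r_out
    return None


def _interp_zero(r0: float, r1: float, v0: float, v1: float) -> float:
    if v1 == v0:
        return 0.5 * (r0 + r1)
    return r0 + (r1 - r0) * (0.0 - v0) / (v1 - v0)


#: widest plausible bronchial wall at the measured generations (mm)
MAX_WALL_THICKNESS_MM = 3.0


def _measure_at_sigma(section: CrossSection, sigma_mm: float,
                      max_thickness_mm: float = MAX_WALL_THICKNESS_MM):
    img = np.nan_to_num(section.image, nan=float(np.nanmedian(section.image)))
    spacing = section.spacing_mm
    lumen = _lumen_region(section)
    cy, cx = ndimage.center_of_mass(lumen)
    centroid_px = np.array([cy, cx])

    sigma_px = sigma_mm / spacing
    # scale-normalized LoG (sigma^2 factor) so responses compare across scales
    log_img = sigma_px**2 * ndimage.gaussian_laplace(img.astype(float), sigma_px)
    ref = float(max(-log_img.min(), 1e-12))

    # mean lumen radius as the search start for each ray
    lumen_area_px = lumen.sum()
    r_lumen_px = np.sqrt(lumen_area_px / np.pi)

    half_px = min(img.shape) / 2.0 - 1
    step_px = 0.5
    radii_px = np.arange(0.0, half_px, step_px)
    angles = np.linspace(0.0, 2.0 * np.pi, N_RAYS, endpoint=False)

    inner, outer = np.full(N_RAYS, np.nan), np.full(N_RAYS, np.nan)
    ext_mags = []
    for a_i, ang in enumerate(angles):
        direction = np.array([np.cos(ang), np.sin(ang)])
        pts = centroid_px[:, None] + direction[:, None] * radii_px[None, :]
        prof = ndimage.map_coordinates(log_img, pts, order=1, mode="nearest")
        res = _ray_profile_boundaries(
            prof, radii_px, max(r_lumen_px * 0.5, 1.0), ref, max_thickness_mm / spacing
        )
        if res is None:
            continue
        r_in_px, r_out_px = res
        inner[a_i], outer[a_i] = r_in_px, r_out_px
        band = (radii_px >= r_in_px) & (radii_px <= r_out_px)
        ext_mags.append(float(-np.min(prof[band])) if band.any() else float(-np.min(prof)))

    ok = ~np.isnan(inner)
    n_failed = int(N_RAYS - ok.sum())
    if n_failed > MAX_FAILED_RAY_FRACTION * N_RAYS:
        raise WallMeasurementError(
            f"no zero-crossing pair on {n_failed}/{N_RAYS} rays at sigma {sigma_mm} mm"
        )
    # fill failed rays by periodic interpolation from neighbours
    for arr in (inner, outer):
        bad = np.isnan(arr)
        if bad.any():
            idx = np.arange(N_RAYS)
            arr[bad] = np.interp(idx[bad], idx[~bad], arr[~bad], period=N_RAYS)

    mm = spacing
    centroid_mm = (centroid_px - (np.asarray(img.shape) - 1) / 2.0) * mm
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    # first-order curvature correction: the LoG zero-crossing of a circular
    # edge of radius R sits outward of the true edge by ~ sigma^2 / (2 R)
    inner_r = inner * mm
    outer_r = outer * mm
    inner_r = inner_r - sigma_mm**2 / (2.0 * np.maximum(inner_r, sigma_mm))
    outer_r = outer_r - sigma_mm**2 / (2.0 * np.maximum(outer_r, sigma_mm))
    inner_pts = centroid_mm + dirs * inner_r[:, None]
    outer_pts = centroid_mm + dirs * outer_r[:, None]

    la = _shoelace(inner_pts)
    total = _shoelace(outer_pts)
    wa = total - la
    if wa <= 0 or la <= 0:
        raise WallMeasurementError("degenerate boundaries (non-positive area)")
    score = (int(ok.sum()), float(np.mean(ext_mags)) if ext_mags else 0.0)
    meas = WallMeasurement(
        LA=la,
        WA=wa,
        WA_percent=wa_percent(wa, la),
        inner_boundary=inner_pts,
        outer_boundary=outer_pts,
        centroid=centroid_mm,
        section=section,
        sigma_mm=sigma_mm,
        n_failed_rays=n_failed,
    )
    return meas, score


def detect_wall(
    section: CrossSection,
    sigma_mm: float | None = None,
    sigma_sweep=DEFAULT_SIGMA_SWEEP,
) -> WallMeasurement:
    """Measure LA/WA on one cross-section by LoG boundary detection.

    With ``sigma_mm`` given, that single scale is used; otherwise the sweep
    is run and the consensus scale is kept: the one whose (LA, WA) lie
    closest to the cross-scale median, which discards scales too coarse to
    resolve the wall (their areas drift away from the consensus) while
    retaining noise robustness.
    """
    sigmas = (sigma_mm,) if sigma_mm is not None else tuple(sigma_sweep)
    results: list[WallMeasurement] = []
    last_err: Exception | None = None
    for s in sigmas:
        try:
            meas, _score = _measure_at_sigma(section, s)
        except WallMeasurementError as err:
            last_err = err
            continue
        results.append(meas)
    if not results:
        raise last_err if last_err is not None else WallMeasurementError("measurement failed")
    if len(results) == 1:
        return results[0]
    areas = np.array([[m.LA, m.WA] for m in results])
    med = np.median(areas, axis=0)
    dist = np.linalg.norm(areas / med - 1.0, axis=1)
    return results[int(np.argmin(dist))]


# ---------------------------------------------------------------------------
# 3D wall masks and the T2 biomarker


@dataclass
class WallMaskSet:
    """Labeled wall-mask volume; label i+1 marks ``records[i]`` = (path, site)."""

    labels: np.ndarray
    records: list  # list of (path_label, site)
    affine: np.ndarray

    def mask_for(self, path_label, site=None) -> np.ndarray:
        sel = np.zeros_like(self.labels, dtype=bool)
        for i, (p, s) in enumerate(self.records):
            if p == path_label and (site is None or s == site):
                sel |= self.labels == i + 1
        return sel


def wall_mask_3d(
    measurements: list,
    grid: ImageVolume,
    slab_thickness_mm: float = 2.5,
    lumen_mask: np.ndarray | None = None,
    margin_mm: float = 0.0,
) -> WallMaskSet:
    """Rasterize measured wall annuli into a labeled 3D mask on ``grid``.

    Each measurement contributes a slab of ``slab_thickness_mm`` centred on
    its section plane; a voxel joins the mask when its in-plane radius from
    the lumen centroid lies between the (angle-interpolated) inner and outer
    boundary radii.  ``margin_mm`` shrinks the annulus from both boundaries
    (partial-volume guard for intensity sampling).  Lumen voxels are
    excluded when a lumen mask is given.
    """
    if not measurements:
        raise ValueError("empty measurement set")
    labels = np.zeros(grid.shape, dtype=np.uint16)
    records = []
    shape = np.asarray(grid.shape)
    for meas in measurements:
        sec = meas.section
        if sec is None:
            raise ValueError("measurement lacks section provenance")
        rec_id = len(records) + 1
        records.append((sec.path_label, sec.site))

        angles = np.arctan2(
            meas.outer_boundary[:, 1] - meas.centroid[1],
            meas.outer_boundary[:, 0] - meas.centroid[0],
        )
        order = np.argsort(angles)
        ang_s = angles[order]
        r_in_s = np.linalg.norm(meas.inner_boundary - meas.centroid, axis=1)[order]
        r_out_s = np.linalg.norm(meas.outer_boundary - meas.centroid, axis=1)[order]

        r_max = float(r_out_s.max()) + 1.0
        center_world = sec.center_mm + meas.centroid[0] * sec.axes[0] + meas.centroid[1] * sec.axes[1]
        lo = grid.world_to_index(center_world - r_max - slab_thickness_mm)
        hi = grid.world_to_index(center_world + r_max + slab_thickness_mm)
        lo_i = np.maximum(np.floor(np.minimum(lo, hi)).astype(int), 0)
        hi_i = np.minimum(np.ceil(np.maximum(lo, hi)).astype(int) + 1, shape)
        if np.any(hi_i <= lo_i):
            continue
        sub_idx = np.stack(
            np.meshgrid(*[np.arange(lo_i[k], hi_i[k]) for k in range(3)], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        pts = grid.index_to_world(sub_idx)
        rel = pts - center_world
        d_ax = rel @ sec.normal
        in_slab = np.abs(d_ax) <= slab_thickness_mm / 2.0
        u = rel @ sec.axes[0]
        v = rel @ sec.axes[1]
        theta = np.arctan2(v, u)
        r = np.hypot(u, v)
        ri = np.interp(theta, ang_s, r_in_s, period=2.0 * np.pi) + margin_mm
        ro = np.interp(theta, ang_s, r_out_s, period=2.0 * np.pi) - margin_mm
        inside = in_slab & (r >= ri) & (r <= ro)
        sel = sub_idx[inside]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = rec_id
    if lumen_mask is not None:
        labels[lumen_mask] = 0
    if not labels.any():
        raise ValueError("wall mask rasterization produced an empty mask")
    return WallMaskSet(labels=labels, records=records, affine=grid.affine.copy())


class BiomarkerError(RuntimeError):
    """All paths empty: no wall voxels to measure."""


@dataclass
class PatientBiomarkers:
    """Per-patient biomarkers with per-path / per-site provenance."""

    brwall_t2_mis: float  # Au, on the normalized T2w scale
    wa_percent: float
    per_path: dict  # path -> {"t2": value, "wa_percent": value, "sites": {...}}
    exclusions: list = field(default_factory=list)
    replicates: list = field(default_factory=list)  # additional readings


def brwall_t2_mis(
    masks: WallMaskSet,
    normalized_t2: ImageVolume,
    measurements: list | None = None,
) -> PatientBiomarkers:
    """Mean normalized T2w signal over the bronchial wall masks.

    Aggregation is site -> path -> patient, each an unweighted mean.  WA% is
    aggregated the same way from the measurements when given.
    """
    if masks.labels.shape != normalized_t2.shape:
        raise ValueError("mask and T2w volumes must share one grid")
    per_path: dict = {}
    excluded = []
    for i, (path, site) in enumerate(masks.records):
        m = masks.labels == i + 1
        if not m.any():
            excluded.append({"lobe": path, "site": site, "reason": "empty wall mask"})
            continue
        val = float(np.mean(normalized_t2.data[m]))
        per_path.setdefault(path, {"sites": {}})["sites"][site] = val
    if not per_path:
        raise BiomarkerError("all per-path wall masks are empty")

    wa_by_path_site: dict = {}
    if measurements:
        for meas in measurements:
            wa_by_path_site.setdefault(meas.path_label, {})[meas.site] = meas.WA_percent

    path_means = []
    wa_path_means = []
    for path, entry in per_path.items():
        entry["t2"] = float(np.mean(list(entry["sites"].values())))
        path_means.append(entry["t2"])
        if path in wa_by_path_site:
            entry["wa_percent"] = float(np.mean(list(wa_by_path_site[path].values())))
            wa_path_means.append(entry["wa_percent"])
    return PatientBiomarkers(
        brwall_t2_mis=float(np.mean(path_means)),
        wa_percent=float(np.mean(wa_path_means)) if wa_path_means else np.nan,
        per_path=per_path,
        exclusions=excluded,
    )
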