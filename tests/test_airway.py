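"""Airway tree extraction, generation labeling, path selection, reformatting."""

import numpy as np
import pytest

from bronchowall.airway import (
    BranchPath,
    SectionRequest,
    SeedError,
    SelectionError,
    extract_centerline,
    label_generations,
    pick_measurement_sites,
    reformat_cross_section,
    segment_lumen,
    select_paths,
)
from bronchowall.phantom import PhantomSpec, generate_phantom, scene_labels
from bronchowall.wallquant import detect_wall


def _fine_scene_volume(truth, label, step=0.45):
    """Oracle: scene volume by fine-grid sampling of the analytic labels."""
    extent = truth.spec.extent_mm
    axes = [np.arange(step / 2, e, step) for e in extent]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    labs = scene_labels(pts, truth.branches, truth.spec.mucus_plug_paths)
    code = {"wall": 1, "lumen": 2}[label]
    return (labs == code).sum() * step**3


def test_segment_lumen_matches_analytic_volume(clean_phantom, clean_lumen_tree):
    lumen = clean_lumen_tree["lumen"]
    truth = clean_phantom["truth"]
    vol = lumen.sum() * truth.spec.voxel_size**3
    oracle = _fine_scene_volume(truth, "lumen")
    assert abs(vol - oracle) / oracle < 0.05
    # on the noise-free phantom the mask equals the rendered lumen exactly
    assert np.array_equal(lumen, truth.material_masks()["lumen"])


def test_segment_lumen_seed_in_wall_raises(clean_phantom):
    truth = clean_phantom["truth"]
    trachea = truth.branches[0]
    wall_point = trachea.p0 + np.array([trachea.lumen_radius + 0.8, 0.0, -5.0])
    with pytest.raises(SeedError):
        segment_lumen(clean_phantom["ct"], wall_point)


def test_plugged_path_distal_lumen_absent(plugged_phantom):
    ct = plugged_phantom["ct"]
    truth = plugged_phantom["truth"]
    lumen = segment_lumen(ct, truth.trachea_seed_mm)
    designated = [
        b for b in truth.branches if b.lobe == "RUL" and b.generation == 3 and b.child_index == 0
    ][0]
    distal = designated.p0 + 0.8 * (designated.p1 - designated.p0)
    idx = tuple(np.round(distal / truth.spec.voxel_size).astype(int))
    assert not lumen[idx]
    # the sibling branch's lumen is still present
    sibling = [
        b for b in truth.branches if b.lobe == "RUL" and b.generation == 3 and b.child_index == 1
    ][0]
    mid = (sibling.p0 + sibling.p1) / 2
    assert lumen[tuple(np.round(mid / truth.spec.voxel_size).astype(int))]


def test_straight_tube_centerline(straight_tube_phantom):
    ct = straight_tube_phantom["ct"]
    truth = straight_tube_phantom["truth"]
    lumen = segment_lumen(ct, truth.trachea_seed_mm)
    tree = extract_centerline(lumen, ct.affine, truth.trachea_seed_mm)
    assert len(tree.branches) == 1
    assert len(tree.terminal_branches()) == 1
    branch = tree.branches[tree.root]
    assert branch.generation == 0
    axis = truth.branches[0].direction
    tangents = branch.tangents()
    angles = np.degrees(np.arccos(np.clip(np.abs(tangents @ axis), -1, 1)))
    assert angles.mean() < 5.0


def test_depth3_phantom_has_8_terminal_branches(clean_lumen_tree):
    tree = clean_lumen_tree["tree"]
    assert len(tree.terminal_branches()) == 2**3
    counts = {g: len(tree.branches_at_generation(g)) for g in range(4)}
    assert counts == {0: 1, 1: 2, 2: 4, 3: 8}


def test_centerline_accuracy_within_one_voxel(clean_phantom, clean_lumen_tree):
    """Mean detected-to-true centerline distance < 1 voxel on the clean phantom."""
    tree = clean_lumen_tree["tree"]
    truth = clean_phantom["truth"]
    dists = []
    for b in tree.branches.values():
        for p in b.points_mm:
            d = min(
                _point_segment_distance(p, tb.p0, tb.p1) for tb in truth.branches
            )
            dists.append(d)
    assert np.mean(dists) < truth.spec.voxel_size


def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def test_pruning_leaves_topology_unchanged(clean_phantom, clean_lumen_tree):
    """A sub-prune-length twig added to the mask does not change the tree.

    The skeleton twig created by a surface bump runs from the centerline to
    the bump tip, so its arc length is about lumen radius + bump height
    (~4.9 mm here); a prune length above that must restore the topology.
    """
    lumen = clean_lumen_tree["lumen"].copy()
    truth = clean_phantom["truth"]
    trachea = truth.branches[0]
    mid = (trachea.p0 + trachea.p1) / 2.0
    vox = truth.spec.voxel_size
    idx = np.round(mid / vox).astype(int)
    for k in range(int(np.ceil((trachea.lumen_radius + 1.9) / vox))):
        lumen[idx[0] + k, idx[1], idx[2]] = True
    tree = extract_centerline(
        lumen, clean_phantom["ct"].affine, truth.trachea_seed_mm, prune_length_mm=6.0
    )
    counts = {g: len(tree.branches_at_generation(g)) for g in range(4)}
    assert counts == {0: 1, 1: 2, 2: 4, 3: 8}
    assert len(tree.terminal_branches()) == 8


def test_label_generations_idempotent(clean_lumen_tree):
    tree = clean_lumen_tree["tree"]
    before = {b.id: b.generation for b in tree.branches.values()}
    label_generations(tree)
    after = {b.id: b.generation for b in tree.branches.values()}
    assert before == after


def test_rotation_equivariance(clean_phantom):
    """90-degree-rotated phantom yields identical per-generation branch counts."""
    ct = clean_phantom["ct"]
    truth = clean_phantom["truth"]
    rot = ct.copy_with(np.rot90(ct.data, 1, axes=(0, 1)).copy())
    n = ct.shape[1]
    seed_idx = ct.world_to_index(truth.trachea_seed_mm)
    rot_idx = np.array([n - 1 - seed_idx[1], seed_idx[0], seed_idx[2]])
    rot_seed = rot.index_to_world(rot_idx)
    lumen = segment_lumen(rot, rot_seed)
    tree = extract_centerline(lumen, rot.affine, rot_seed)
    counts = {g: len(tree.branches_at_generation(g)) for g in range(4)}
    assert counts == {0: 1, 1: 2, 2: 4, 3: 8}


def test_select_paths_standard_phantom(clean_phantom, clean_lumen_tree):
    sel = select_paths(
        clean_lumen_tree["tree"],
        clean_phantom["truth"].lobe_map,
        ct=clean_phantom["ct"],
        lumen_mask=clean_lumen_tree["lumen"],
    )
    assert sorted(sel.paths) == ["LLL", "LUL", "RLL", "RUL"]
    assert sel.exclusions == []


def test_select_paths_plugged_lobe_excluded(plugged_phantom):
    ct = plugged_phantom["ct"]
    truth = plugged_phantom["truth"]
    lumen = segment_lumen(ct, truth.trachea_seed_mm)
    tree = extract_centerline(lumen, ct.affine, truth.trachea_seed_mm)
    sel = select_paths(tree, truth.lobe_map, ct=ct, lumen_mask=lumen)
    assert sorted(sel.paths) == ["LLL", "LUL", "RLL"]
    assert len(sel.exclusions) == 1
    assert sel.exclusions[0]["lobe"] == "RUL"
    assert "plugging" in sel.exclusions[0]["reason"]


def test_select_paths_shallow_tree_raises(straight_tube_phantom, clean_phantom):
    ct = straight_tube_phantom["ct"]
    truth = straight_tube_phantom["truth"]
    lumen = segment_lumen(ct, truth.trachea_seed_mm)
    tree = extract_centerline(lumen, ct.affine, truth.trachea_seed_mm)
    with pytest.raises(SelectionError):
        select_paths(tree, clean_phantom["truth"].lobe_map)


def _circle_fit_eccentricity(sec, thresh=-500.0):
    """Circle-fit oracle: sub-pixel lumen-boundary radii per angle, then the
    eccentricity of the best-fit cos(2*theta) ellipse mode."""
    from scipy import ndimage

    img = np.nan_to_num(sec.image, nan=0.0)
    low = img < thresh
    lab, _ = ndimage.label(low)
    reg = lab == lab[tuple(np.array(img.shape) // 2)]
    cy, cx = ndimage.center_of_mass(reg)
    angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    rs = np.arange(0, img.shape[0] / 2 - 1, 0.25)
    radii = []
    for a in angles:
        d = np.array([np.cos(a), np.sin(a)])
        prof = ndimage.map_coordinates(
            img, np.array([cy, cx])[:, None] + d[:, None] * rs[None, :], order=1
        )
        above = np.where(prof > thresh)[0]
        if len(above) == 0 or above[0] == 0:
            continue
        i = above[0]
        radii.append((a, np.interp(thresh, [prof[i - 1], prof[i]], [rs[i - 1], rs[i]])))
    ang, rr = np.array(radii).T
    r0 = rr.mean()
    amp = np.hypot(np.mean(rr * np.cos(2 * ang)) * 2, np.mean(rr * np.sin(2 * ang)) * 2)
    ratio = (r0 - amp) / (r0 + amp)
    return np.sqrt(1.0 - ratio**2)


def test_reformat_axis_aligned_section_is_circular(straight_tube_phantom):
    """Tube along z with normal (0,0,1): the lumen boundary fits a circle."""
    ct = straight_tube_phantom["ct"]
    truth = straight_tube_phantom["truth"]
    trachea = truth.branches[0]
    center = (trachea.p0 + trachea.p1) / 2.0
    sec = reformat_cross_section(
        ct, SectionRequest(center_mm=center, normal=np.array([0.0, 0.0, -1.0]), size_mm=18.0)
    )
    assert _circle_fit_eccentricity(sec) < 0.2


def test_reformat_oblique_section_is_circular(clean_phantom):
    """Oblique branch (35 deg) cut perpendicular to its axis: annulus, not ellipse.

    A deliberately wrong (axial) cut of the same branch must look clearly
    elliptical, confirming the oracle separates the two cases.
    """
    truth = clean_phantom["truth"]
    branch = [b for b in truth.branches if b.generation == 1][0]
    center = (branch.p0 + branch.p1) / 2.0
    sec = reformat_cross_section(
        clean_phantom["ct"],
        SectionRequest(center_mm=center, normal=branch.direction, size_mm=14.0),
    )
    assert _circle_fit_eccentricity(sec) < 0.2
    axial = reformat_cross_section(
        clean_phantom["ct"],
        SectionRequest(center_mm=center, normal=np.array([0.0, 0.0, 1.0]), size_mm=14.0),
    )
    assert _circle_fit_eccentricity(axial) > 0.4


def test_reformat_rejects_non_unit_normal(clean_phantom):
    with pytest.raises(ValueError):
        reformat_cross_section(
            clean_phantom["ct"],
            SectionRequest(center_mm=np.array([30.0, 30.0, 30.0]), normal=np.array([0, 0, 2.0])),
        )


def test_reformat_out_of_bounds_flagged(clean_phantom):
    sec = reformat_cross_section(
        clean_phantom["ct"],
        SectionRequest(
            center_mm=np.array([2.0, 30.0, 30.0]), normal=np.array([0.0, 0.0, 1.0]), size_mm=20.0
        ),
    )
    assert sec.out_of_bounds
    assert np.isnan(sec.image).any()


def _straight_branch(length_mm=30.0, n=61):
    t = np.linspace(0, 1, n)
    pts = np.stack([np.full(n, 10.0), np.full(n, 10.0), 10.0 + t * length_mm], axis=1)
    return BranchPath(id=0, parent=None, points_mm=pts, generation=3)


def test_measurement_sites_at_arclength_fractions():
    """30 mm branch: two sites at 10 and 20 mm; one site at the midpoint."""
    reqs = pick_measurement_sites(_straight_branch(), n_sites=2, lumen_diameter_mm=4.0)
    assert [round(r.arc_position_mm, 6) for r in reqs] == [10.0, 20.0]
    (req,) = pick_measurement_sites(_straight_branch(), n_sites=1, lumen_diameter_mm=4.0)
    assert req.arc_position_mm == pytest.approx(15.0)


def test_measurement_sites_short_branch_rejected():
    with pytest.raises(ValueError):
        pick_measurement_sites(_straight_branch(length_mm=7.0), lumen_diameter_mm=4.0)
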