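"""Extract the airway tree, label generations and pick the four lobar paths.

The lumen is grown from a tracheal seed on the CT-like volume, skeletonized
into a rooted centerline tree (trachea = generation 0), and one
third-generation path per lobe (RUL, RLL, LUL, LLL) is selected for
measurement, with automated mucus-plug exclusion.
"""

from bronchowall import (
    PhantomSpec,
    extract_centerline,
    generate_phantom,
    pick_measurement_sites,
    segment_lumen,
    select_paths,
)

spec = PhantomSpec(seed=3, noise_sigma=0.0, deformation_amplitude=0.0)
ct, ute, t2w, truth = generate_phantom(spec)

lumen = segment_lumen(ct, truth.trachea_seed_mm)
print(f"lumen voxels: {lumen.sum()}")

tree = extract_centerline(lumen, ct.affine, truth.trachea_seed_mm)
for g in range(tree.max_generation() + 1):
    print(f"generation {g}: {len(tree.branches_at_generation(g))} branches")

selection = select_paths(tree, truth.lobe_map, ct=ct, lumen_mask=lumen)
for lobe, path in sorted(selection.paths.items()):
    sites = pick_measurement_sites(path, n_sites=2, lumen_diameter_mm=3.6)
    positions = ", ".join(f"{r.arc_position_mm:.1f} mm" for r in sites)
    print(f"{lobe}: arc length {path.arc_length:.1f} mm, sites at {positions}")
# two measurement sites per path, at 1/3 and 2/3 of the branch arc length,
# clear of both bifurcation zones
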