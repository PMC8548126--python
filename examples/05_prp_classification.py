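"""Rule-based PRP diagnosis from lesion maps.

Renders one panretinally treated and one partially treated synthetic eye,
then applies the spatial rule set (exclusion zones around disc and macula,
mark count, quadrant coverage) to their ground-truth lesion masks.
"""

from lasermark.anatomy import AnatomyFit, BinaryRegion, estimate_scale, fit_od_ellipse
from lasermark.fundus_io import ProbabilityMap
from lasermark.prp_rules import PrpConfig, classify_prp
from lasermark.synthetic import SynthConfig, _image_rng, render_scene

for pattern in ("prp", "partial", "none"):
    cfg = SynthConfig(seed=5, n_images=1, pattern=pattern,
                      size_range=(150, 190), n_laser_marks_range=(30, 40),
                      laser_radius_range=(3, 4))
    scene = render_scene(cfg, _image_rng(5, 0))

    ellipse, extent = fit_od_ellipse(BinaryRegion(scene.od_mask, 1))
    fit = AnatomyFit(od_ellipse=ellipse, od_extent=extent,
                     macula_center=scene.macula_center,
                     microns_per_pixel=estimate_scale(extent))
    decision = classify_prp(ProbabilityMap(scene.lesion_mask.astype(float)),
                            fit, PrpConfig(min_area=4))
    quadrants = sum(1 for q in decision.quadrant_counts if q > 0)
    print(f"{pattern:8s}: marks={decision.n_marks:3d} "
          f"quadrants covered={quadrants} -> PRP={decision.is_prp}")

print()
print("an eye counts as panretinally treated when enough marks survive the "
      "disc/macula exclusion rules (>= 30) and they cover >= 3 of the four "
      "macula-centered quadrants; the partial and untreated eyes fail one "
      "or both conditions")
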