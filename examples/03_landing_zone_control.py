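"""Locate the Watchman landing zone and take Control measurements.

The landing plane is scanned over the 1-2 cm anterior offset from the
LUPV limbus until it is perpendicular to the cavity centerline; the
diameters come from the cut contour (max caliper distance = the D1-D2
fiducial pair).
"""

import laaview as lv

anatomy = lv.generate_case(
    lv.AnatomyParams(lv.MorphologyLabel.WINDSOCK, 25, 20, 30), rng_seed=1)
zone = lv.locate_landing_zone(anatomy)
ctrl = lv.control_measurement(anatomy, zone)

print(f"selected LUPV offset      : {zone.lupv_offset_mm:.1f} mm")
print(f"plane perpendicularity    : {zone.perpendicularity:.4f} (1 = ideal)")
print(f"max diameter (D1-D2)      : {ctrl.max_diameter_mm:.2f} mm  (truth 25)")
print(f"min diameter              : {ctrl.min_diameter_mm:.2f} mm  (truth 20)")
print(f"length, centerline arc    : {ctrl.length_mm:.2f} mm  (truth 30)")
print(f"length, implantation chord: {ctrl.length_chord_mm:.2f} mm")
print(f"eccentricity              : {ctrl.eccentricity:.3f}")
print(f"absolute eccentricity     : {ctrl.absolute_eccentricity_mm:.2f} mm")
# Control measurements recover the generator's ground truth within the
# mesh discretization tolerance (~2%): this is the reference against
# which the fluoroscopic strategies are scored.
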