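"""Generate a synthetic left-atrial-appendage anatomy with known ground truth.

Builds a windsock-type appendage (25 x 20 mm elliptical orifice, 30 mm
long) attached to an ellipsoidal left-atrium body, prints the mesh
summary and the constructive landmarks, and exports an STL file with a
JSON landmark sidecar.
"""

import laaview as lv

params = lv.AnatomyParams(
    morphology=lv.MorphologyLabel.WINDSOCK,
    orifice_long_axis_mm=25.0,
    orifice_short_axis_mm=20.0,
    length_mm=30.0,
)
anatomy = lv.generate_case(params, rng_seed=1)

print(f"morphology        : {anatomy.morphology.value}")
print(f"appendage faces   : {len(anatomy.appendage_mesh.faces)}")
print(f"watertight        : {anatomy.appendage_mesh.is_watertight}")
for name, p in anatomy.landmarks.items():
    print(f"landmark {name:20s}: ({p[0]:7.2f}, {p[1]:7.2f}, {p[2]:7.2f}) mm")

path = lv.export_stl(anatomy, "scratch_example_case.stl")
print(f"exported STL + sidecar to {path}")
# The landmarks are the anatomy's measurement anchors: the landing zone is
# drawn from the inferior deflection toward a point 1-2 cm anterior of the
# LUPV limbus, and length is measured from the landing zone to the tip.
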