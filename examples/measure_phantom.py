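"""Measure rubric features from a polygonal capillary annotation.

Builds a geometry phantom with known ground truth (220 nm BM in 3 layers,
mildly activated endothelium, 6 ensheathing processes), measures it back
with the morphometry engine, and scores the measured features.
"""

from capscore import (
    CapillaryFeatures,
    extract_features,
    score_capillary,
    synthesize_geometry,
)

truth = CapillaryFeatures(
    bm_thickness_nm=220.0,
    bm_layer_count=3,
    activation_grade="mild",
    process_count=6,
    process_prominence="prominent",
)
geometry = synthesize_geometry(truth, seed=7)
measured = extract_features(geometry)

print(f"BM thickness : {measured.bm_thickness_nm:8.1f} nm   (truth 220.0)")
print(f"BM layers    : {measured.bm_layer_count:8d}      (truth 3)")
print(f"endo area    : {measured.endothelial_area_um2:8.2f} um^2")
print(f"processes    : {measured.process_count:8d}      (truth 6)")
print("prominence   :", measured.process_prominence.value)
print("score        :", score_capillary(measured))
# The radial-ray median recovers the constructed thickness within ~2%, and
# counts are recovered exactly, so re-scoring lands in the same rubric bands.
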