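"""Score a single capillary cross-section with the five-category rubric.

Builds a raw feature record for a visibly diseased capillary — a 250 nm
basement membrane split into 5 layers, markedly activated endothelium,
8 ensheathing pericyte processes and one large tubuloreticular inclusion —
and prints its category scores and four-category sum.
"""

from capscore import CapillaryFeatures, TriObservation, score_capillary

features = CapillaryFeatures(
    bm_thickness_nm=250.0,
    bm_layer_count=5,
    activation_grade="marked",
    process_count=8,
    process_prominence="very_prominent",
    tri=[TriObservation("large", 1)],
)
score = score_capillary(features)

print("BM thickening        :", score.bm_thickening)
print("BM reduplication     :", score.bm_reduplication)
print("endothelial activation:", score.endothelial_activation)
print("ensheathment         :", score.ensheathment)
print("TRI                  :", score.tri)
print("four-category sum    :", score.four_category_sum)
# Each category score is 0 (normal), 1 (mild) or 2 (marked); the sum of the
# first four (0-8) is what the case-level AS statistic averages. TRI is
# reported but never enters the sum.
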