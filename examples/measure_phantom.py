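"""Measure exophthalmos on one synthetic axial slice with a known answer.

Renders a phantom (two globes, two lateral orbital-rim arcs, watermark
strokes, mild noise), runs the geometric pipeline with the true eye mask,
and compares the measured corneal-apex-to-rim-line distances with the
phantom's analytic ground truth.
"""

from exoct import phantom
from exoct.measure import measure_slice

sample = phantom.render_phantom(phantom.random_spec("axial", seed=21))
meas = measure_slice(sample.slice, sample.eye_mask_true,
                     phantom.rim_config_for(sample.spec))

print(f"rim line through {meas.landmarks.rim_apex_a} and {meas.landmarks.rim_apex_b}")
for eye in sorted(meas.distances_px):
    d_px = meas.distances_px[eye]
    d_mm = meas.distances_mm[eye]
    d_true = sample.distance_true_mm[eye]
    print(f"{eye}: {d_px:6.2f} px = {d_mm:5.2f} mm   (true {d_true:5.2f} mm)")

# The distances are the axial exophthalmometric parameters: the perpendicular
# distance from each corneal apex to the line joining the two most protruding
# lateral orbital-rim points. Agreement within ~0.75 mm (1.5 px at 0.5 mm/px)
# is the discretization budget of integer-pixel landmarks.
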