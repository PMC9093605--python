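"""Quantify sprouting from a single synthetic spheroid image.

Renders one spheroid with known geometry, runs the full analysis, and
compares the measured metrics against the generator's exact ground truth.
"""

from sproutquant import PipelineConfig, SyntheticSpec, analyze_image, generate

spec = SyntheticSpec(n_attached=5, n_detached=2, seed=42)
img, truth = generate(spec)
metrics = analyze_image(img, PipelineConfig(), image_id="demo")

print(f"total spheroid area : {metrics.total_area_px} px")
print(f"sprouting area      : {metrics.sprout_area_px} px")
print(f"attached sprouts    : {metrics.n_attached}  (truth: {truth.n_attached})")
print(f"migrated sprouts    : {metrics.n_migrated}  (truth: {truth.n_detached})")
print(f"cumulative length   : {metrics.csl_px} px = {metrics.csl_um:.0f} um "
      f"(truth centerline: {truth.total_centerline_px} px)")

# The attached/migrated counts should match the rendered geometry exactly;
# the cumulative sprout length (CSL) tracks the rendered centerline length
# to within a few percent — the skeleton is cut a few pixels outside the
# bright body, which is the method's documented, systematic behavior.
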