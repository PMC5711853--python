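"""Compute the ten RGB vegetation indices for one plot image.

Builds a small synthetic seedling scene with 20% green cover under strong
chlorosis (phosphorus-starved foliage shifted toward yellow), then reduces
it to the plot-level color summary.  GA is the fraction of pixels with hue
in 60-180 deg (green canopy cover); GGA restricts to 80-180 deg, so the
yellow-green chlorotic fraction counts toward GA but not GGA; a* < 0 means
the average color leans green.
"""

from canopyvi import SceneParams, generate_canopy_scene, summarize_rgb_plot

image, _, truth = generate_canopy_scene(
    SceneParams(green_fraction=0.20, chlorosis=0.8, image_size=(384, 256), seed=42))
summary = summarize_rgb_plot(image)

print(f"true green cover (pixel bookkeeping): {truth.true_green_fraction:.3f}")
print(f"GA  (hue 60-180 deg):  {summary.ga:.3f}")
print(f"GGA (hue 80-180 deg):  {summary.gga:.3f}   <= GA, excludes yellow-green")
print(f"mean hue: {summary.hue_deg:6.1f} deg   (soil pulls it below 60)")
print(f"a*: {summary.a_star:6.2f}   (negative = greener average color)")
print(f"u*: {summary.u_star:6.2f}   b*: {summary.b_star:6.2f}   L*: {summary.lightness:5.1f}")
print(f"intensity {summary.intensity:.3f}, saturation {summary.saturation:.3f}, "
      f"n={summary.n_pixels} px")
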