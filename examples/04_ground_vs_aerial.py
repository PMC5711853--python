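"""Emulate the aerial platform and compare index robustness to resolution.

Ground plot images are block-mean downsampled (factor 10), creating mixed
vegetation/soil pixels at canopy edges.  Mean-color indices (a*, u*, Hue)
are nearly conserved by block averaging, while the threshold-based GGA
reclassifies mixed pixels — so its ground-aerial agreement over plots is
the weakest.  This is the mechanism behind ground/aerial divergence of
cover indices at coarse resolution.
"""

from scipy import stats as sps

from canopyvi import TrialDesign, degrade_resolution, generate_trial, summarize_rgb_plot

plots = generate_trial(TrialDesign(image_size=(384, 256), seed=13))
ground, aerial = [], []
for p in plots:
    ground.append(summarize_rgb_plot(p.rgb))
    aerial.append(summarize_rgb_plot(degrade_resolution(p.rgb, 10)))

print("index      ground-vs-aerial r over 52 plots")
for name in ("a_star", "u_star", "hue_deg", "ga", "gga"):
    g = [getattr(s, name) for s in ground]
    a = [getattr(s, name) for s in aerial]
    r = sps.pearsonr(g, a)[0]
    print(f"{name:10s} {r:.4f}")

print("\nGGA sits lowest: coarse pixels blend green canopy with soil and drop")
print("out of the 80-180 deg hue window, while mean-color indices survive.")
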