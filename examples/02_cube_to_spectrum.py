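"""From raw camera counts to a trimmed mean ROI spectrum.

Renders one synthetic leaf into a raw hypercube with dark/white reference
frames, then runs the extraction pipeline: black-white correction
I = (S − B)/(W − B), Otsu leaf segmentation on the 800 nm band, ROI
averaging, and trimming to the retained 475–980 nm window.
"""

import numpy as np

import leafspec as ls

design = ls.StudyDesign("unpackaged", (0,), 1, 1, ("vnir",), seed=4)
sm, panels = ls.simulate_spectra(design, camera="vnir")
spectrum = sm.spectra[0]

raw, refs = ls.render_cube(spectrum, sm.grid, ls.SceneConfig(noise_sigma=2.0), seed=4)
print(f"raw cube: {raw.counts.shape} counts in [{raw.counts.min():.0f}, "
      f"{raw.counts.max():.0f}]")

cube = ls.calibrate_cube(raw, refs)
mask = ls.segment_leaf(cube)
mean_spectrum = ls.extract_mean_spectrum(cube, mask)
print(f"leaf mask: {mask.sum()} px; recovered spectrum max deviation "
      f"{np.abs(mean_spectrum - spectrum).max():.2e} (sensor noise only)")

trimmed = ls.trim_wavelengths(sm)
print(f"trimmed: {len(sm.grid)} bands ({sm.grid.values[0]:.0f}-"
      f"{sm.grid.values[-1]:.0f} nm) -> {len(trimmed.grid)} bands "
      f"({trimmed.grid.values[0]:.0f}-{trimmed.grid.values[-1]:.0f} nm)")
print("\nThe deviation is the residual of inverting the imaging model; with "
      "zero sensor noise it is exact to machine precision.")
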