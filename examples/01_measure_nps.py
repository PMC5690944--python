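"""Measure a noise power spectrum from a simulated uniform-phantom scan pair.

Builds two repeat scans of a uniform phantom carrying noise with a known
bell-shaped spectrum, runs the ROI-based NPS estimator with both detrending
methods, and checks that the spectrum integral recovers the noise variance.
"""

import numpy as np

import dirqa

# CBCT-like spectral shape, scaled so the noise magnitude is 40 HU
model = dirqa.NPSParams(a1=100.0, a2=0.3, a3=0.2, a4=10.0)
noise = dirqa.NoiseSpec("model", model, target_sigma=40.0, seed=1)
phantom = dirqa.PhantomSpec(shape=(20, 512, 512), spacing=(0.475, 0.475, 2.5),
                            background_hu=0.0,
                            trend=(10.0, 0.0, 0.0, -15.0, 0.0, -15.0),  # cupping
                            noise=noise)
scan1, scan2 = dirqa.generate_uniform_phantom(phantom)

# 16 ROIs of 40 px on a radius-80 px circle, over 20 slices -> 320 patches
spec = dirqa.ROISamplingSpec()
rois1 = dirqa.extract_rois(scan1, spec)
rois2 = dirqa.extract_rois(scan2, spec)

poly = [dirqa.detrend_roi(p, "poly2d") for p in rois1]
sub = [dirqa.detrend_roi(a, "subtraction", b) for a, b in zip(rois1, rois2)]

for name, patches in (("poly2d", poly), ("subtraction", sub)):
    nps2d = dirqa.roi_nps_2d(patches, (0.475, 0.475))
    profile = dirqa.radial_profile(nps2d)
    var = dirqa.nps_variance(profile)
    peak_f = profile.frequencies[np.argmax(profile.power)]
    print(f"{name:12s}: integral = {var:7.1f} HU^2  (sigma = {np.sqrt(var):.2f} HU), "
          f"peak at {peak_f:.3f} / mm")

print("\nThe integral of the NPS equals the noise variance; both detrending")
print("methods should land near 1600 HU^2 (sigma 40), with the spectral peak")
print("near the model's centre frequency a2 = 0.3 / mm.")
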