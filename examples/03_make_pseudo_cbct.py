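"""Turn a CT volume into pseudo-CBCTs over a ladder of noise magnitudes.

Each axial slice receives an independent inverse-FFT noise realization whose
2D spectrum follows the model, rescaled so the whole-volume noise magnitude
hits the requested sigma exactly. This emulates registering a planning CT
against in-room CBCT at different exposure levels with anatomy held fixed.
"""

import numpy as np

import dirqa

model = dirqa.NPSParams(a1=100.0, a2=0.3, a3=0.2, a4=10.0)

# a simple CT stand-in: water cylinder in air
z, y, x = np.mgrid[0:20, 0:256, 0:256]
ct_vox = np.where((x - 128) ** 2 + (y - 128) ** 2 < 100**2, 0.0, -1000.0)
ct = dirqa.ImageVolume(ct_vox, (0.5, 0.5, 2.5))

print("target sigma (HU)   measured sigma in water (HU)")
for sigma in (18.0, 36.0, 72.0, 108.0):
    spec = dirqa.NoiseSpec("model", model, target_sigma=sigma, seed=13)
    pseudo = dirqa.make_pseudo_cbct(ct, spec)
    water = pseudo.voxels[(x - 128) ** 2 + (y - 128) ** 2 < 90**2]
    print(f"{sigma:12.0f}        {water.std():.2f}")

print("\nThe measured noise inside the water region tracks each target; the")
print("same seed gives bit-identical volumes on rerun, and geometry (spacing,")
print("origin, shape) is never altered by noise injection.")
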