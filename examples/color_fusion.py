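"""Fuse a grayscale anatomical image with a pseudo-color functional one.

The color image (think SPECT/PET uptake rendered through a colormap) is
split into luminance + chrominance; only the luminance is fused with
the anatomical image, so structural detail improves while the color
coding of activity is preserved exactly.
"""

import numpy as np
from skimage.color import rgb2yiq

from nsctfuse import FusionConfig, fuse_gray_color
from nsctfuse.synthetic import PhantomSpec, make_functional_pair

gray, color, masks = make_functional_pair(
    PhantomSpec(size=(128, 128), seed=3, noise_sigma=0.0))
out = fuse_gray_color(gray, color, FusionConfig())

lum_in = rgb2yiq(color)[..., 0]
lum_out = rgb2yiq(out)[..., 0]
print(f"input functional luminance  mean {lum_in.mean():.3f}")
print(f"fused luminance             mean {lum_out.mean():.3f}")

unclipped = np.all((out > 1e-6) & (out < 1 - 1e-6), axis=2)
drift = np.abs(rgb2yiq(out)[..., 1:] - rgb2yiq(color)[..., 1:])
print(f"max chrominance drift on unclipped pixels "
      f"({100 * unclipped.mean():.0f}% of image): "
      f"{drift[unclipped].max():.2e} — the activity color coding passes "
      "through; only pixels the brighter fused luminance pushes out of "
      "RGB range get clipped")

act = masks["activity"]
print(f"activity blob luminance {lum_out[act].mean():.3f} vs "
      f"background {lum_out[~act & masks['interior']].mean():.3f} "
      "-> uptake still stands out after fusion")
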