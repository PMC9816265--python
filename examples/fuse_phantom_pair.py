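"""Fuse a synthetic CT/MR-like phantom pair and score the result.

Generates a 128x128 complementary-contrast pair (each modality shows
structures the other hides), fuses with the default NSCT+PCNN pipeline,
and prints the seven quality metrics.  Higher EN/MI/QABF/SD/AG means
more source information and contrast survived; QNCIE near 0.81 is the
typical scale for genuinely fused (not copied) images.
"""

from nsctfuse import FusionConfig, fuse_images, report, sd
from nsctfuse.synthetic import PhantomSpec, make_pair

a, b, masks = make_pair(PhantomSpec(size=(128, 128), seed=7))
cfg = FusionConfig()
fused = fuse_images(a, b, cfg)

rep = report(a, b, fused)
for name, value in rep.as_dict().items():
    print(f"{name:>6}: {value:.4f}")

print(f"\nstructure visible only in A, fused-image mean: "
      f"{fused[masks['a_only']].mean():.3f}")
print(f"structure visible only in B, fused-image mean: "
      f"{fused[masks['b_only']].mean():.3f}")
print(f"plain tissue mean:                             "
      f"{fused[masks['free']].mean():.3f}")
print("-> both modality-exclusive structures stand out above tissue")

sd_avg = sd(fuse_images(a, b, cfg.with_rule("average")))
print(f"\nSD selection rule {rep.sd:.2f} vs averaging {sd_avg:.2f}: "
      "winner-take-all keeps contrast that averaging halves")
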