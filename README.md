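# nsctfuse

Multimodal medical image fusion with the **nonsubsampled contourlet
transform (NSCT)** and **pulse-coupled neural networks (PCNN)**, plus the
standard seven-metric fusion-quality evaluation suite.

Different modalities see different things: CT shows bone, MR shows soft
tissue, PET/SPECT show metabolic activity. Given two co-registered slices
`A` and `B`, the pipeline produces a single image that keeps the salient
content of both:

1. **Decompose** both images with the NSCT — an undecimated multiscale,
   multidirectional filter bank. Every subband keeps the source's size
   and the transform is shift-invariant and exactly invertible (the filter
   banks satisfy the perfect-reconstruction identity
   `h0*g0 + h1*g1 = δ`).
2. **Select** each subband coefficient by PCNN firing counts. A spiking
   neuron sits on every pixel; over `N = 100` iterations the count
   `T = Σ Y(n)` measures local salience, and the fused coefficient is
   copied from the source with the larger count:
   `F(i,j) = A(i,j) if T_A(i,j) > T_B(i,j) else B(i,j)` — for the lowpass
   band and every directional band independently. The rule selects, never
   blends.
3. **Reconstruct** with the inverse NSCT and clip to [0, 1].

Quality is scored with entropy (EN), mutual information (MI), edge
preservation (Q^AB/F), PSNR, standard deviation (SD), average gradient
(AG) and nonlinear correlation information entropy (Q_ncie); each metric
is validated against an independent brute-force implementation.

A deterministic phantom generator produces co-registered
complementary-contrast pairs (shared skull/anatomy, structures bright in
exactly one modality, seeded noise) with ground-truth masks, so the whole
pipeline runs and is tested without any image downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from nsctfuse import FusionConfig, fuse_images, report
from nsctfuse.synthetic import PhantomSpec, make_pair

a, b, masks = make_pair(PhantomSpec(size=(128, 128), seed=7))
fused = fuse_images(a, b, FusionConfig())
for name, value in report(a, b, fused).as_dict().items():
    print(f"{name:>6}: {value:.4f}")
```

prints (from `examples/fuse_phantom_pair.py`):

```
    EN: 4.8116
    MI: 4.1962
  QABF: 0.9089
  PSNR: 20.0432
    SD: 87.8023
    AG: 10.8824
 QNCIE: 0.8121
```

EN/SD/AG say the fused image is information-rich and high-contrast; MI and
QABF say that information and those edges actually came from the sources
(QABF = 1 would mean perfect edge transfer); QNCIE ≈ 0.81 is the typical
value for a genuinely mixed triple. The example also verifies the point of
the method: structures visible in only one modality end up bright in the
fused image (mean ≈ 0.81–0.85 inside the ground-truth masks vs ≈ 0.25 for
plain tissue), and the selection rule keeps more contrast than averaging
(SD 87.8 vs 82.1).

More narrative scripts in `examples/`: `transform_roundtrip.py` (exact
invertibility and shift invariance), `pcnn_dynamics.py` (the firing-count
mechanism), `color_fusion.py` (anatomical gray + pseudo-color functional
fusion through the luminance channel).

## Command line

```sh
nsctfuse phantom -o pair/ --size 256 --seed 1        # synthetic test pair
nsctfuse fuse pair/a.png pair/b.png -o fused.png --report scores.json
nsctfuse metrics pair/a.png pair/b.png fused.png -o scores.csv
```

Defaults are the reference setting (4 levels, directional depths 3,3,2,2,
`pyrexc`/`vk` banks, PCNN β=3, α_l=1, v_l=1.8, α_h=0.2, v_h=20, N=100);
every flag (`--levels`, `--dirs`, `--rule`, `--beta`, `--iterations`, ...)
or a YAML config via `--config` overrides them. Exit codes: 0 success,
2 usage/config error, 3 I/O error.

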