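"""Synthetic complementary-modality phantom pairs.

Real multimodal brain pairs (CT bone vs MR soft tissue, MR anatomy vs
SPECT/PET activity) share anatomy while each modality highlights
structures the other barely shows.  The generator emulates exactly that
geometry on a head-phantom layout so every pipeline stage can be
exercised, with ground-truth masks returned for assertions:

* a shared elliptical "skull" ring, bright in both modalities;
* a shared soft-tissue interior at a low base intensity;
* ellipse structures placed inside the head, each bright in exactly one
  modality and at base intensity in the other;
* additive Gaussian noise (seeded), then clipping to [0, 1].

No scanner physics is simulated — no partial-volume blur, no bias
fields, no projection geometry.  Identical (spec, seed) input yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "make_pair", "make_functional_pair"]


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise settings of one phantom pair.

    size : (height, width); 256 x 256 by default.
    seed : RNG seed; the pair is a pure function of (spec, seed).
    n_structures : ellipses inside the head, alternately assigned to
        modality A and modality B.
    base, skull, structure : intensity of soft tissue, skull ring, and
        modality-visible structures, on [0, 1].
    noise_sigma : std of the additive Gaussian noise (0.01 default).
    n_activity_blobs : smooth "uptake" blobs for the functional path.
    """

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    n_structures: int = 4
    base: float = 0.25
    skull: float = 0.95
    structure: float = 0.85
    noise_sigma: float = 0.01
    n_activity_blobs: int = 3
    activity_baseline: float = 0.2

    def __post_init__(self) -> None:
        h, w = self.size
        if h <= 0 or w <= 0:
            raise ValueError("phantom size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")


def _grids(size):
    h, w = size
    yy = (np.arange(h) - (h - 1) / 2) / ((h - 1) / 2)
    xx = (np.arange(w) - (w - 1) / 2) / ((w - 1) / 2)
    return np.meshgrid(yy, xx, indexing="ij")


def _ellipse(yy, xx, cy, cx, ry, rx, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    y = (yy - cy) * ca + (xx - cx) * sa
    x = -(yy - cy) * sa + (xx - cx) * ca
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _head_layout(spec: PhantomSpec, rng: np.random.Generator):
    yy, xx = _grids(spec.size)
    outer = _ellipse(yy, xx, 0.0, 0.0, 0.92, 0.78)
    inner = _ellipse(yy, xx, 0.0, 0.0, 0.80, 0.66)
    skull = outer & ~inner
    structures = []
    for k in range(spec.n_structures):
        for _ in range(50):  # rejection sampling inside the head
            cy = rng.uniform(-0.45, 0.45)
            cx = rng.uniform(-0.38, 0.38)
            ry = rng.uniform(0.08, 0.18)
            rx = rng.uniform(0.08, 0.18)
            ang = rng.uniform(0.0, np.pi)
            m = _ellipse(yy, xx, cy, cx, ry, rx, ang)
            inside = m & ~inner
            overlap = any(np.any(m & prev) for prev in structures)
            if not np.any(inside) and not overlap:
                structures.append(m)
                break
        else:  # fall back to whatever fits, overlapping if need be
            structures.append(_ellipse(yy, xx, cy, cx, 0.08, 0.08))
    return skull, inner, structures


def make_pair(spec: PhantomSpec | None = None):
    """Generate a complementary-contrast phantom pair.

    Returns ``(a, b, masks)``: two [0, 1] float images plus a dict of
    boolean ground-truth masks — ``skull``, ``interior`` (inside the
    skull), ``a_only`` / ``b_only`` (union of structures visible only in
    that modality), ``free`` (interior tissue clear of any structure)
    and ``background`` (outside the head).
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    skull, interior, structures = _head_layout(spec, rng)

    a = np.zeros(spec.size)
    b = np.zeros(spec.size)
    for img in (a, b):
        img[interior] = spec.base
        img[skull] = spec.skull

    a_only = np.zeros(spec.size, dtype=bool)
    b_only = np.zeros(spec.size, dtype=bool)
    for k, m in enumerate(structures):
        if k % 2 == 0:
            a[m] = spec.structure
            a_only |= m
        else:
            b[m] = spec.structure
            b_only |= m

    if spec.noise_sigma > 0:
        a = a + rng.normal(0.0, spec.noise_sigma, spec.size)
        b = b + rng.normal(0.0, spec.noise_sigma, spec.size)
    a = np.clip(a, 0.0, 1.0)
    b = np.clip(b, 0.0, 1.0)

    masks = {
        "skull": skull,
        "interior": interior,
        "a_only": a_only,
        "b_only": b_only,
        "free": interior & ~(a_only | b_only),
        "background": ~(skull | interior),
    }
    return a, b, masks


def _pseudo_color(activity: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Map activity onto RGB with luminance = baseline + 0.5925 * activity.

    Channels are R = baseline + activity, G = baseline + activity/2,
    B = baseline; with YIQ luminance weights (0.299, 0.587, 0.114) the
    luminance is exactly the smooth baseline wherever activity is zero.
    """
    r = np.clip(baseline + activity, 0.0, 1.0)
    g = np.clip(baseline + 0.5 * activity, 0.0, 1.0)
    return np.stack([r, g, baseline], axis=-1)


def make_functional_pair(spec: PhantomSpec | None = None):
    """Generate an anatomical grayscale image plus a pseudo-color
    functional image sharing the head outline.

    The functional image is a smooth low-spatial-frequency "uptake" map
    (Gaussian blobs blurred inside the head) rendered through a fixed
    pseudo-color map.  Returns ``(gray, color, masks)`` where ``masks``
    adds ``activity`` (uptake above half maximum) to the anatomical
    masks.
    """
    if spec is None:
        spec = PhantomSpec()
    gray, _, masks = make_pair(spec)

    rng = np.random.default_rng(spec.seed + 1)
    yy, xx = _grids(spec.size)
    act = np.zeros(spec.size)
    for _ in range(spec.n_activity_blobs):
        cy = rng.uniform(-0.4, 0.4)
        cx = rng.uniform(-0.35, 0.35)
        amp = rng.uniform(0.5, 0.9)
        width = rng.uniform(0.10, 0.22)
        act += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / width ** 2)
    act = np.clip(act, 0.0, 1.0)
    act[~masks["interior"]] = 0.0
    sigma_px = max(1.0, 0.02 * min(spec.size))
    act = gaussian_filter(act, sigma_px)
    act = np.clip(act, 0.0, 1.0)

    baseline = np.full(spec.size, spec.activity_baseline)
    baseline[masks["background"]] = 0.05
    baseline = gaussian_filter(baseline, 2.0)

    color = _pseudo_color(act, baseline)
    if spec.noise_sigma > 0:
        color = np.clip(
            color + rng.normal(0.0, spec.noise_sigma, color.shape), 0.0, 1.0
        )
    out_masks = dict(masks)
    peak = act.max()
    out_masks["activity"] = act > 0.5 * peak if peak > 0 else act > 0
    return gray, color, out_masks
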