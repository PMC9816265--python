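"""Pulse-coupled neural network firing-count maps.

One PCNN neuron sits on every pixel of a stimulus image.  Per iteration
each neuron updates, in order:

    feeding      F(n) = S                      (simplified; see below)
    linking      L(n) = exp(-alpha_l) L(n-1) + v_l * sum_kl w[kl] Y_kl(n-1)
    modulation   U(n) = F(n) * (1 + beta L(n))
    firing       Y(n) = 1  where U(n) > H(n-1)   (strict; ties do not fire)
    threshold    H(n) = exp(-alpha_h) H(n-1) + v_h * Y(n)

All state starts at zero, so any neuron with positive internal activity
fires on the first step.  The accumulated firing count T = sum_n Y(n)
is the salience measure the fusion rule compares between sources: a
stronger stimulus recharges past its decaying threshold sooner and so
fires more often within the N iterations.

The feeding channel defaults to the pure-stimulus simplification
``F(n) = S`` standard in fusion work; the full leaky recurrence
``F(n) = exp(-alpha_f) F(n-1) + v_f * sum m Y(n-1) + S`` is enabled by
setting ``alpha_f``/``v_f``.  Neighborhood sums are zero-padded at the
image border.  The model is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve as _ndconvolve

__all__ = ["PCNNParams", "linking_kernel", "pcnn_firing_map",
           "normalize_stimulus"]


def linking_kernel(link_arrange: int) -> np.ndarray:
    """Inverse-distance linking weights on a square neighborhood.

    Weight at offset (p, q) is ``1/sqrt(p^2 + q^2)``; the center
    (self-coupling) weight is zero.  ``link_arrange`` is the odd side
    length of the neighborhood.
    """
    if link_arrange <= 0 or link_arrange % 2 == 0:
        raise ValueError("link_arrange must be an odd positive integer")
    r = link_arrange // 2
    p, q = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1),
                       indexing="ij")
    d2 = p.astype(float) ** 2 + q.astype(float) ** 2
    with np.errstate(divide="ignore"):
        w = np.where(d2 > 0, 1.0 / np.sqrt(d2), 0.0)
    return w


@dataclass
class PCNNParams:
    """Neuron constants; defaults follow the reference experimental setting.

    beta : linking strength (how much neighbor firing boosts activity).
    alpha_l, v_l : linking leak rate and amplification.
    alpha_h, v_h : threshold decay rate and recharge voltage.
    link_arrange : odd side length of the coupling neighborhood.
    n_iter : number of simulated steps N.
    alpha_f, v_f : optional full feeding recurrence; ``None`` selects
        the F = S simplification.
    kernel_m, kernel_w : coupling weight matrices for the feeding and
        linking sums; default :func:`linking_kernel`.
    """

    beta: float = 3.0
    alpha_l: float = 1.0
    v_l: float = 1.8
    alpha_h: float = 0.2
    v_h: float = 20.0
    link_arrange: int = 3
    n_iter: int = 100
    alpha_f: float | None = None
    v_f: float | None = None
    kernel_m: np.ndarray | None = field(default=None, repr=False)
    kernel_w: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.link_arrange <= 0 or self.link_arrange % 2 == 0:
            raise ValueError("link_arrange must be an odd positive integer")
        for name in ("alpha_l", "alpha_h", "v_l", "v_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kernel_w is None:
            self.kernel_w = linking_kernel(self.link_arrange)
        if self.kernel_m is None:
            self.kernel_m = self.kernel_w.copy()
        for k in (self.kernel_m, self.kernel_w):
            if k.shape != (self.link_arrange, self.link_arrange):
                raise ValueError("coupling kernels must be "
                                 "link_arrange x link_arrange")
            if k[self.link_arrange // 2, self.link_arrange // 2] != 0:
                raise ValueError("coupling kernels must have zero "
                                 "self-weight at the center")


def _neighbor_sum(y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # zero padding outside the image
    return _ndconvolve(y, kernel, mode="constant", cval=0.0)


def pcnn_firing_map(stimulus, params: PCNNParams | None = None) -> np.ndarray:
    """Run the network on a stimulus in [0, 1]; return integer firing counts.

    The returned array T satisfies 0 <= T <= ``params.n_iter`` and is a
    deterministic function of the inputs.
    """
    s = np.asarray(stimulus, dtype=float)
    if s.ndim != 2:
        raise ValueError("stimulus must be a 2-D array")
    if not np.all(np.isfinite(s)):
        raise ValueError("stimulus contains non-finite values")
    if params is None:
        params = PCNNParams()

    shape = s.shape
    f = np.zeros(shape)
    ell = np.zeros(shape)
    y = np.zeros(shape)
    h = np.zeros(shape)
    t = np.zeros(shape, dtype=np.int64)

    full_feeding = params.alpha_f is not None or params.v_f is not None
    dec_f = np.exp(-params.alpha_f) if params.alpha_f is not None else 0.0
    v_f = params.v_f if params.v_f is not None else 0.0
    dec_l = np.exp(-params.alpha_l)
    dec_h = np.exp(-params.alpha_h)

    for _ in range(params.n_iter):
        if full_feeding:
            f = dec_f * f + v_f * _neighbor_sum(y, params.kernel_m) + s
        else:
            f = s
        ell = dec_l * ell + params.v_l * _neighbor_sum(y, params.kernel_w)
        u = f * (1.0 + params.beta * ell)
        y = (u > h).astype(float)
        h = dec_h * h + params.v_h * y
        t += y.astype(np.int64)
    return t


def normalize_stimulus(band, is_highpass: bool) -> np.ndarray:
    """Map an NSCT subband onto the [0, 1] stimulus range of the network.

    Highpass bands carry signed detail coefficients: salience is their
    magnitude, so the stimulus is ``|band|`` scaled by its maximum (an
    all-zero band stays zero).  Lowpass bands are min-max rescaled; a
    constant band maps to a uniform 0.5.
    """
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")
    if is_highpass:
        mag = np.abs(band)
        peak = mag.max() if mag.size else 0.0
        return mag / peak if peak > 0 else np.zeros_like(band)
    lo = band.min()
    hi = band.max()
    if hi == lo:
        return np.full_like(band, 0.5)
    return (band - lo) / (hi - lo)
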