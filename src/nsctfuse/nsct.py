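"""Nonsubsampled contourlet transform: decomposition and exact inverse.

The transform has two cascaded stages, both fully undecimated so every
subband keeps the source image's shape:

* nonsubsampled pyramid (NSPFB): a two-channel lowpass/highpass split
  applied iteratively to the running lowpass, with the filters à trous
  upsampled by ``2^j I`` at level ``j`` (scale j);
* nonsubsampled directional filter bank (NSDFB): a binary tree of fan
  filter splits applied to each scale's bandpass image, producing
  ``2^d`` directional subbands per scale.

With perfect-reconstruction (Bezout) filter pairs, each split/merge is
exactly invertible, so the whole tree is.  Boundary handling:

* ``"periodic"`` (default): circular convolution; reconstruction,
  linearity and shift invariance are exact to machine precision.
* ``"symmetric"``: half-sample mirror extension; visually preferable on
  real images but exactly invertible only away from the borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .filters import FilterBank, upsampled_taps

__all__ = [
    "SubbandPyramid",
    "nspfb_split",
    "nspfb_merge",
    "nsdfb_split",
    "nsdfb_merge",
    "nsct_decompose",
    "nsct_reconstruct",
    "BOUNDARY_MODES",
]

BOUNDARY_MODES = ("periodic", "symmetric")

# Quincunx matrix for the second directional level and the four
# unimodular shears used (scaled) from the third level on.
_QUINCUNX = np.array([[1, 1], [1, -1]])
_SHEARS = (
    np.array([[1, 1], [0, 1]]),
    np.array([[1, -1], [0, 1]]),
    np.array([[1, 0], [1, 1]]),
    np.array([[1, 0], [-1, 1]]),
)


def _check_image(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("expected a non-empty 2-D image array")
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    return x


def _check_boundary(boundary: str) -> str:
    if boundary not in BOUNDARY_MODES:
        raise ValueError(
            f"unknown boundary mode {boundary!r}; supported: "
            f"{', '.join(BOUNDARY_MODES)}"
        )
    return boundary


def _filter2(x: np.ndarray, kernel: np.ndarray, sampling, boundary: str):
    """Same-size zero-phase filtering with the à trous upsampled kernel."""
    values, offsets = upsampled_taps(kernel, sampling)
    h, w = x.shape
    if boundary == "periodic":
        k = np.zeros((h, w))
        np.add.at(k, (offsets[:, 0] % h, offsets[:, 1] % w), values)
        y = np.fft.irfft2(np.fft.rfft2(x) * np.fft.rfft2(k), s=(h, w))
        return y
    # symmetric: mirror-pad by the kernel radius, dense conv, crop
    r0 = int(np.max(np.abs(offsets[:, 0])))
    r1 = int(np.max(np.abs(offsets[:, 1])))
    k = np.zeros((2 * r0 + 1, 2 * r1 + 1))
    np.add.at(k, (offsets[:, 0] + r0, offsets[:, 1] + r1), values)
    xp = np.pad(x, ((r0, r0), (r1, r1)), mode="symmetric")
    y = fftconvolve(xp, k, mode="same")
    return y[r0:r0 + h, r1:r1 + w]


@dataclass
class SubbandPyramid:
    """NSCT coefficient set: one lowpass band plus per-scale directional bands.

    ``highs[0]`` is the finest scale; ``highs[j]`` holds
    ``2**dirs_per_level[j]`` directional bands, each the source's shape.
    """

    low: np.ndarray
    highs: list[list[np.ndarray]]
    levels: int
    dirs_per_level: tuple[int, ...]

    def band_count(self) -> int:
        return 1 + sum(len(h) for h in self.highs)

    def validate(self) -> None:
        if self.levels != len(self.highs) or self.levels != len(
            self.dirs_per_level
        ):
            raise ValueError("pyramid levels inconsistent with band lists")
        shape = self.low.shape
        for d, bands in zip(self.dirs_per_level, self.highs):
            if len(bands) != 2 ** d:
                raise ValueError(
                    f"expected {2 ** d} directional bands, found {len(bands)}"
                )
            for b in bands:
                if b.shape != shape:
                    raise ValueError("subband shapes differ within pyramid")

    def map(self, fn) -> "SubbandPyramid":
        """New pyramid with ``fn`` applied to every band."""
        return SubbandPyramid(
            low=fn(self.low),
            highs=[[fn(b) for b in bands] for bands in self.highs],
            levels=self.levels,
            dirs_per_level=self.dirs_per_level,
        )


def nspfb_split(x, bank: FilterBank, level: int = 0, boundary: str = "periodic"):
    """One nonsubsampled pyramid split at the given scale.

    Returns ``(low, high)``, both the shape of ``x``, filtered with the
    analysis pair upsampled by ``2**level * I``.
    """
    x = _check_image(x)
    _check_boundary(boundary)
    if level < 0:
        raise ValueError("level must be >= 0")
    s = (2 ** level) * np.eye(2, dtype=int)
    return (
        _filter2(x, bank.h0, s, boundary),
        _filter2(x, bank.h1, s, boundary),
    )


def nspfb_merge(low, high, bank: FilterBank, level: int = 0,
                boundary: str = "periodic"):
    """Inverse of :func:`nspfb_split` (synthesis pair, same scale)."""
    low = _check_image(low)
    high = _check_image(high)
    _check_boundary(boundary)
    s = (2 ** level) * np.eye(2, dtype=int)
    return _filter2(low, bank.g0, s, boundary) + _filter2(
        high, bank.g1, s, boundary
    )


def _dfb_matrix(level: int, channel: int) -> np.ndarray:
    """Upsampling matrix for the split of `channel` at tree depth `level`."""
    if level == 1:
        return np.eye(2, dtype=int)
    if level == 2:
        return _QUINCUNX
    return (2 ** (level - 3)) * (_QUINCUNX @ _SHEARS[channel % 4])


def nsdfb_split(x, bank: FilterBank, n_levels: int,
                boundary: str = "periodic") -> list[np.ndarray]:
    """Binary-tree nonsubsampled directional split into ``2**n_levels`` bands.

    Level 1 applies the fan pair directly; level 2 applies it upsampled
    by the quincunx matrix; deeper levels use quincunx-times-shear
    matrices so the wedge supports keep narrowing.  ``n_levels = 0``
    returns ``[x]``.
    """
    x = _check_image(x)
    _check_boundary(boundary)
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    channels = [x]
    for level in range(1, n_levels + 1):
        nxt: list[np.ndarray] = []
        for c, chan in enumerate(channels):
            s = _dfb_matrix(level, c)
            nxt.append(_filter2(chan, bank.h0, s, boundary))
            nxt.append(_filter2(chan, bank.h1, s, boundary))
        channels = nxt
    return channels


def nsdfb_merge(bands: list[np.ndarray], bank: FilterBank, n_levels: int,
                boundary: str = "periodic") -> np.ndarray:
    """Inverse of :func:`nsdfb_split` (synthesis filters, reversed tree)."""
    _check_boundary(boundary)
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    if len(bands) != 2 ** n_levels:
        raise ValueError(
            f"expected {2 ** n_levels} bands for a depth-{n_levels} tree, "
            f"found {len(bands)}"
        )
    channels = [np.asarray(b, dtype=float) for b in bands]
    for level in range(n_levels, 0, -1):
        nxt = []
        for c in range(len(channels) // 2):
            s = _dfb_matrix(level, c)
            rec = _filter2(channels[2 * c], bank.g0, s, boundary) + _filter2(
                channels[2 * c + 1], bank.g1, s, boundary
            )
            nxt.append(rec)
        channels = nxt
    return channels[0]


def nsct_decompose(x, levels: int, dirs, pyr: FilterBank, fan: FilterBank,
                   boundary: str = "periodic") -> SubbandPyramid:
    """Full NSCT analysis.

    At each scale (finest first) the running lowpass is split by the
    pyramid bank, and the bandpass output is split into ``2**dirs[j]``
    directional subbands by the fan tree.

    Parameters
    ----------
    levels : int
        Number of pyramid scales (>= 1).
    dirs : sequence of int
        Directional tree depth per scale, finest first; entry ``d``
        yields ``2**d`` bands at that scale.
    """
    x = _check_image(x)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    dirs = tuple(int(d) for d in dirs)
    if len(dirs) != levels:
        raise ValueError(
            f"dirs must have one entry per level ({levels}), got {len(dirs)}"
        )
    if any(d < 0 for d in dirs):
        raise ValueError("directional depths must be >= 0")
    low = x
    highs: list[list[np.ndarray]] = []
    for j in range(levels):
        low, high = nspfb_split(low, pyr, level=j, boundary=boundary)
        highs.append(nsdfb_split(high, fan, dirs[j], boundary=boundary))
    return SubbandPyramid(low=low, highs=highs, levels=levels,
                          dirs_per_level=dirs)


def nsct_reconstruct(p: SubbandPyramid, pyr: FilterBank, fan: FilterBank,
                     boundary: str = "periodic") -> np.ndarray:
    """Exact inverse of :func:`nsct_decompose` (same banks and boundary)."""
    p.validate()
    low = p.low
    for j in range(p.levels - 1, -1, -1):
        high = nsdfb_merge(p.highs[j], fan, p.dirs_per_level[j],
                           boundary=boundary)
        low = nspfb_merge(low, high, pyr, level=j, boundary=boundary)
    return low
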