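"""Two-channel nonsubsampled filter banks and à trous kernel upsampling.

The nonsubsampled contourlet transform is built from two undecimated
two-channel banks: a *pyramid* pair (lowpass/highpass, the multiscale
stage) and a *fan* pair (two complementary directional wedges, the
directional stage).  Because no signal decimation takes place, exact
invertibility reduces to the Bezout (perfect-reconstruction) identity

    h0 * g0 + h1 * g1 = delta

as a 2-D polynomial identity, which survives à trous upsampling of all
four kernels by any nonsingular integer matrix.  Every bank built here
is checked against that identity at construction time; the identity,
not the provenance of the taps, is the correctness contract.

The shipped pyramid pair (registered under the conventional name
``"pyrexc"``) is derived from the 1-D maxflat halfband filter
``[-1, 0, 9, 16, 9, 0, -1]/32`` through the McClellan transform with the
diamond kernel, giving a zero-phase 7x7 lowpass ``h0`` with DC gain 1.
The highpass is ``h1 = delta - h0*h0`` with synthesis ``g0 = h0``,
``g1 = delta``, so the Bezout identity holds exactly in dyadic-rational
float64 arithmetic.  The fan pair (``"vk"``) is the same construction
modulated by (-1)^n1, which shifts the diamond passband onto the fan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "FilterBank",
    "FilterNameError",
    "build_pyramid_filters",
    "build_fan_filters",
    "atrous_upsample",
    "bezout_residual",
    "PYRAMID_FILTER_NAMES",
    "FAN_FILTER_NAMES",
]


class FilterNameError(ValueError):
    """Requested filter bank name is not registered."""


@dataclass(frozen=True)
class FilterBank:
    """Analysis/synthesis kernel quadruple of an undecimated two-channel bank.

    Attributes
    ----------
    h0, h1 : ndarray
        2-D analysis kernels (lowpass/fan and its complement).
    g0, g1 : ndarray
        2-D synthesis kernels.
    name : str
        Registered identifier ("pyrexc" pyramid pair, "vk" fan pair).
    kind : str
        Either ``"pyramid"`` or ``"fan"``.
    """

    h0: np.ndarray = field(repr=False)
    h1: np.ndarray = field(repr=False)
    g0: np.ndarray = field(repr=False)
    g1: np.ndarray = field(repr=False)
    name: str = ""
    kind: str = ""

    def kernels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.h0, self.h1, self.g0, self.g1


# McClellan diamond kernel: cos(w) -> (cos w1 + cos w2)/2.
_DIAMOND = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]) / 4.0


def _delta(shape: tuple[int, int]) -> np.ndarray:
    """Centered unit impulse with odd side lengths."""
    out = np.zeros(shape)
    out[shape[0] // 2, shape[1] // 2] = 1.0
    return out


def _add_centered(acc: np.ndarray, kern: np.ndarray, scale: float) -> None:
    """acc += scale * kern, with both centers aligned (odd sizes)."""
    r0 = (acc.shape[0] - kern.shape[0]) // 2
    r1 = (acc.shape[1] - kern.shape[1]) // 2
    acc[r0:r0 + kern.shape[0], r1:r1 + kern.shape[1]] += scale * kern


def _maxflat_lowpass() -> np.ndarray:
    """7x7 zero-phase diamond maxflat lowpass: 1/2 d + 3/4 t - 1/4 t^3."""
    t1 = _DIAMOND
    t3 = convolve2d(convolve2d(t1, t1), t1)  # 7x7
    h0 = np.zeros((7, 7))
    _add_centered(h0, _delta((1, 1)), 0.5)
    _add_centered(h0, t1, 0.75)
    _add_centered(h0, t3, -0.25)
    return h0


def _modulate_rows(kern: np.ndarray) -> np.ndarray:
    """Multiply by (-1)^n1 (row offset from the center tap)."""
    c0 = kern.shape[0] // 2
    rows = np.arange(kern.shape[0]) - c0
    return kern * ((-1.0) ** np.abs(rows))[:, None]


def bezout_residual(bank: FilterBank) -> float:
    """Max abs deviation of h0*g0 + h1*g1 from the unit impulse (per tap)."""
    acc_shape = (
        bank.h0.shape[0] + bank.g0.shape[0] - 1,
        bank.h0.shape[1] + bank.g0.shape[1] - 1,
    )
    s1 = convolve2d(bank.h0, bank.g0)
    s2 = convolve2d(bank.h1, bank.g1)
    acc = np.zeros(
        (max(s1.shape[0], s2.shape[0]), max(s1.shape[1], s2.shape[1]))
    )
    _add_centered(acc, s1, 1.0)
    _add_centered(acc, s2, 1.0)
    _add_centered(acc, _delta((1, 1)), -1.0)
    # silence unused: acc_shape kept for readability of intent
    del acc_shape
    return float(np.max(np.abs(acc)))


def _checked(bank: FilterBank) -> FilterBank:
    res = bezout_residual(bank)
    if res > 1e-10:
        raise AssertionError(
            f"filter bank {bank.name!r} violates the perfect-reconstruction "
            f"identity (residual {res:.3e})"
        )
    return bank


def _build_pyrexc() -> FilterBank:
    h0 = _maxflat_lowpass()
    g0 = h0.copy()
    h1 = _delta((13, 13)) - convolve2d(h0, h0)
    g1 = np.array([[1.0]])
    return _checked(FilterBank(h0, h1, g0, g1, name="pyrexc", kind="pyramid"))


def _build_vk() -> FilterBank:
    u0 = _modulate_rows(_maxflat_lowpass())
    y0 = u0.copy()
    u1 = _delta((13, 13)) - convolve2d(u0, u0)
    y1 = np.array([[1.0]])
    return _checked(FilterBank(u0, u1, y0, y1, name="vk", kind="fan"))


_PYRAMID_BUILDERS = {"pyrexc": _build_pyrexc}
_FAN_BUILDERS = {"vk": _build_vk}

PYRAMID_FILTER_NAMES = tuple(sorted(_PYRAMID_BUILDERS))
FAN_FILTER_NAMES = tuple(sorted(_FAN_BUILDERS))

_CACHE: dict[tuple[str, str], FilterBank] = {}


def build_pyramid_filters(name: str = "pyrexc") -> FilterBank:
    """Return the named nonsubsampled pyramid (lowpass/highpass) bank.

    The lowpass analysis kernel has DC gain 1 and the highpass DC gain 0,
    so a constant image passes untouched through the lowpass channel.

    Raises
    ------
    FilterNameError
        If ``name`` is not a registered pyramid bank.
    """
    if name not in _PYRAMID_BUILDERS:
        raise FilterNameError(
            f"unknown pyramid filter {name!r}; supported: "
            f"{', '.join(PYRAMID_FILTER_NAMES)}"
        )
    key = ("pyramid", name)
    if key not in _CACHE:
        _CACHE[key] = _PYRAMID_BUILDERS[name]()
    return _CACHE[key]


def build_fan_filters(name: str = "vk") -> FilterBank:
    """Return the named nonsubsampled fan (directional) bank.

    Raises
    ------
    FilterNameError
        If ``name`` is not a registered fan bank.
    """
    if name not in _FAN_BUILDERS:
        raise FilterNameError(
            f"unknown fan filter {name!r}; supported: "
            f"{', '.join(FAN_FILTER_NAMES)}"
        )
    key = ("fan", name)
    if key not in _CACHE:
        _CACHE[key] = _FAN_BUILDERS[name]()
    return _CACHE[key]


def _as_sampling_matrix(sampling) -> np.ndarray:
    s = np.asarray(sampling)
    if s.shape != (2, 2):
        raise ValueError("sampling matrix must be 2x2")
    if not np.all(s == np.rint(s)):
        raise ValueError("sampling matrix must have integer entries")
    s = s.astype(int)
    if round(abs(np.linalg.det(s))) == 0:
        raise ValueError("sampling matrix is singular")
    return s


def upsampled_taps(
    kernel: np.ndarray, sampling
) -> tuple[np.ndarray, np.ndarray]:
    """Tap values and center-relative integer offsets of the à trous kernel.

    Offsets are ``sampling @ (k - c)`` for every index ``k`` of ``kernel``
    with ``c = floor(shape/2)``.  This sparse form is what the transform
    engine consumes; :func:`atrous_upsample` densifies it.
    """
    s = _as_sampling_matrix(sampling)
    kernel = np.asarray(kernel, dtype=float)
    c = np.array([kernel.shape[0] // 2, kernel.shape[1] // 2])
    idx = np.indices(kernel.shape).reshape(2, -1).T - c
    offsets = idx @ s.T
    return kernel.ravel().copy(), offsets


def atrous_upsample(kernel: np.ndarray, sampling) -> np.ndarray:
    """Zero-insert a kernel so the tap at index k moves to ``sampling @ k``.

    Tap values (hence the tap sum / DC gain) are unchanged; the output
    array is the bounding box of the mapped positions.

    Raises
    ------
    ValueError
        If the sampling matrix is singular or not integer.
    """
    values, offsets = upsampled_taps(kernel, sampling)
    lo = offsets.min(axis=0)
    hi = offsets.max(axis=0)
    out = np.zeros(tuple(hi - lo + 1))
    out[offsets[:, 0] - lo[0], offsets[:, 1] - lo[1]] = values
    return out
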