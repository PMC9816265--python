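"""Fusion-quality metrics: EN, MI, Q^AB/F, PSNR, SD, AG, Q_ncie.

All functions take images on the package's internal [0, 1] scale and
evaluate on the 8-bit convention: intensities are mapped to 0..255,
histogram-based measures (EN, MI, Q_ncie) quantize to 256 integer gray
levels, and PSNR/SD/AG are reported in 0..255 intensity units, matching
how these scores are conventionally printed.

Definitions
-----------
EN      -sum p_l log2 p_l over the 256-bin histogram (bits).
MI      MI_AF + MI_BF, each from the 256x256 joint histogram (bits).
Q^AB/F  Sobel edge strength/orientation preservation factors pushed
        through sigmoids and weighted by source edge strength; the
        sigmoids are normalized so perfect preservation scores 1.
PSNR    10 log10(255^2 / MSE); infinite for identical images.  Against
        an (A, B) source pair the reported value is the mean of the two
        single-reference scores.
SD      population standard deviation about the mean intensity.
AG      mean over valid pixels of sqrt((dx^2 + dy^2) / 2) with forward
        differences (average gradient, a sharpness measure).
Q_ncie  nonlinear correlation information entropy: eigenvalue entropy
        of the 3x3 nonlinear-correlation matrix of (A, B, F), each
        off-diagonal entry the joint-histogram NCC (base-256 logs,
        uniform-marginal normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FusionReport", "entropy", "mutual_information", "q_abf", "psnr",
           "sd", "avg_gradient", "ncc", "q_ncie", "report", "QabfConstants"]

_LEVELS = 256


def _quantize(img) -> np.ndarray:
    """[0, 1] float -> integer gray levels 0..255."""
    img = np.asarray(img, dtype=float)
    return np.clip(np.rint(img * (_LEVELS - 1)), 0, _LEVELS - 1).astype(
        np.int64
    )


def _scale255(img) -> np.ndarray:
    return np.asarray(img, dtype=float) * (_LEVELS - 1.0)


def entropy(img) -> float:
    """Shannon entropy of the 256-level histogram, in bits (0..8)."""
    q = _quantize(img)
    p = np.bincount(q.ravel(), minlength=_LEVELS) / q.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _mi_pair(x: np.ndarray, y: np.ndarray) -> float:
    joint = np.bincount(
        (x.ravel() * _LEVELS + y.ravel()), minlength=_LEVELS * _LEVELS
    ).reshape(_LEVELS, _LEVELS) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(a, b, f) -> tuple[float, float, float]:
    """Return ``(MI, MI_AF, MI_BF)`` for a source pair and fused image."""
    qa, qb, qf = _quantize(a), _quantize(b), _quantize(f)
    if not (qa.shape == qb.shape == qf.shape):
        raise ValueError("images must share one shape")
    mi_af = _mi_pair(qa, qf)
    mi_bf = _mi_pair(qb, qf)
    return mi_af + mi_bf, mi_af, mi_bf


@dataclass(frozen=True)
class QabfConstants:
    """Sigmoid constants of the edge-preservation model (strength g,
    orientation a); the defaults are the conventional values."""

    gamma_g: float = 0.9994
    k_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    k_a: float = -22.0
    sigma_a: float = 0.8


def _sobel_strength_orientation(img255: np.ndarray):
    gx = ndimage.sobel(img255, axis=1, mode="reflect")
    gy = ndimage.sobel(img255, axis=0, mode="reflect")
    g = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(gx != 0, np.arctan(np.divide(
            gy, gx, out=np.zeros_like(gy), where=gx != 0)), np.pi / 2)
    return g, alpha


def _preservation(g_src, a_src, g_fus, a_fus, c: QabfConstants):
    hi = np.maximum(g_src, g_fus)
    ratio = np.divide(np.minimum(g_src, g_fus), hi,
                      out=np.zeros_like(hi), where=hi > 0)
    ang = 1.0 - np.abs(a_src - a_fus) / (np.pi / 2)

    def sig(x, gamma, k, s):
        return gamma / (1.0 + np.exp(k * (x - s)))

    qg = sig(ratio, c.gamma_g, c.k_g, c.sigma_g) / sig(
        1.0, c.gamma_g, c.k_g, c.sigma_g)
    qa = sig(ang, c.gamma_a, c.k_a, c.sigma_a) / sig(
        1.0, c.gamma_a, c.k_a, c.sigma_a)
    return qg * qa


def q_abf(a, b, f, constants: QabfConstants | None = None) -> float:
    """Edge-information preservation score in [0, 1].

    Gradient-weighted average of how well each source's Sobel edge
    strength and orientation survive into the fused image.  A fused
    image identical to both sources scores exactly 1; a constant fused
    image scores near 0.  Returns 0 when both sources are edge-free.
    """
    if constants is None:
        constants = QabfConstants()
    a255, b255, f255 = _scale255(a), _scale255(b), _scale255(f)
    if not (a255.shape == b255.shape == f255.shape):
        raise ValueError("images must share one shape")
    gf, af_ = _sobel_strength_orientation(f255)
    out = 0.0
    wsum = 0.0
    for src in (a255, b255):
        gs, as_ = _sobel_strength_orientation(src)
        q = _preservation(gs, as_, gf, af_, constants)
        out += float(np.sum(q * gs))
        wsum += float(np.sum(gs))
    if wsum == 0:
        return 0.0
    return out / wsum


def psnr(ref, out) -> float:
    """Peak signal-to-noise ratio in dB on the 0..255 scale.

    Identical inputs return ``inf`` (the zero-MSE sentinel).
    """
    r, o = _scale255(ref), _scale255(out)
    if r.shape != o.shape:
        raise ValueError("images must share one shape")
    mse = float(np.mean((r - o) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / mse))


def sd(img) -> float:
    """Population standard deviation in 0..255 intensity units."""
    x = _scale255(img)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def avg_gradient(img) -> float:
    """Average gradient (sharpness) in 0..255 intensity units.

    Forward differences dx = F(m,n) - F(m+1,n), dy = F(m,n) - F(m,n+1)
    on the (M-1) x (N-1) valid region; per-pixel magnitude
    sqrt((dx^2 + dy^2)/2), averaged.
    """
    x = _scale255(img)
    if x.shape[0] < 2 or x.shape[1] < 2:
        return 0.0
    dx = x[:-1, :-1] - x[1:, :-1]
    dy = x[:-1, :-1] - x[:-1, 1:]
    return float(np.mean(np.sqrt((dx ** 2 + dy ** 2) / 2.0)))


def ncc(x, y) -> float:
    """Nonlinear correlation coefficient of two images, in [0, 1].

    Defined from the b x b joint histogram (b = 256) in its
    uniform-marginal normalization, i.e. the mutual information in
    base-b logs, ``H_b(X) + H_b(Y) - H_b(X, Y)``.  For uniform
    marginals this equals the classic ``2 + sum (n_i/N) log_b (n_i/N)``
    joint-entropy form: 1 for a perfectly dependent uniform pair, 0 for
    an independent uniform pair.  (Without the normalization the
    joint-entropy form is unbounded for non-uniform images, which is
    why the original metric rank-transforms its inputs.)
    """
    qx, qy = _quantize(x), _quantize(y)
    if qx.shape != qy.shape:
        raise ValueError("images must share one shape")
    return float(_mi_pair(qx, qy) / np.log2(_LEVELS))


def q_ncie(a, b, f) -> float:
    """Nonlinear correlation information entropy of the (A, B, F) triple.

    The 3x3 nonlinear-correlation matrix R has unit diagonal and
    pairwise :func:`ncc` values off the diagonal; the score is
    ``1 + sum_i (lam_i/3) log_256 (lam_i/3)`` over its eigenvalues.
    Three mutually independent images give about 0.80; perfectly
    dependent ones give 1.
    """
    r = np.array([
        [1.0, ncc(a, b), ncc(a, f)],
        [0.0, 1.0, ncc(b, f)],
        [0.0, 0.0, 1.0],
    ])
    r = r + np.triu(r, 1).T
    lam = np.linalg.eigvalsh(r)
    lam = np.clip(lam, 0.0, None) / 3.0
    nz = lam > 0
    return float(1.0 + np.sum(lam[nz] * np.log(lam[nz]) / np.log(_LEVELS)))


@dataclass
class FusionReport:
    """The seven quality scores for one (A, B, fused) triple."""

    en: float
    mi: float
    mi_af: float
    mi_bf: float
    q_abf: float
    psnr: float
    sd: float
    ag: float
    q_ncie: float

    def as_dict(self) -> dict[str, float]:
        return {
            "EN": self.en, "MI": self.mi, "QABF": self.q_abf,
            "PSNR": self.psnr, "SD": self.sd, "AG": self.ag,
            "QNCIE": self.q_ncie,
        }


def report(a, b, f) -> FusionReport:
    """Evaluate all seven metrics for a fused image against its sources.

    PSNR has no single noise-free reference in fusion, so the reported
    value averages ``psnr(A, F)`` and ``psnr(B, F)``.
    """
    mi, mi_af, mi_bf = mutual_information(a, b, f)
    p = 0.5 * (psnr(a, f) + psnr(b, f))
    return FusionReport(
        en=entropy(f),
        mi=mi, mi_af=mi_af, mi_bf=mi_bf,
        q_abf=q_abf(a, b, f),
        psnr=p,
        sd=sd(f),
        ag=avg_gradient(f),
        q_ncie=q_ncie(a, b, f),
    )
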