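"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written the slow, literal way — explicit
loops, dict histograms, naive convolutions — and shares no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

import math

import numpy as np


def naive_conv_full(a, b):
    """Full 2-D linear convolution by four nested loops."""
    ah, aw = a.shape
    bh, bw = b.shape
    out = np.zeros((ah + bh - 1, aw + bw - 1))
    for i in range(ah):
        for j in range(aw):
            for k in range(bh):
                for l in range(bw):
                    out[i + k, j + l] += a[i, j] * b[k, l]
    return out


def bezout_residual_naive(h0, h1, g0, g1):
    """Max deviation of h0*g0 + h1*g1 from a centered unit impulse."""
    s1 = naive_conv_full(h0, g0)
    s2 = naive_conv_full(h1, g1)
    hh = max(s1.shape[0], s2.shape[0])
    ww = max(s1.shape[1], s2.shape[1])
    acc = np.zeros((hh, ww))
    for s in (s1, s2):
        r0 = (hh - s.shape[0]) // 2
        r1 = (ww - s.shape[1]) // 2
        acc[r0:r0 + s.shape[0], r1:r1 + s.shape[1]] += s
    acc[hh // 2, ww // 2] -= 1.0
    return float(np.max(np.abs(acc)))


def _q(img):
    return np.clip(np.rint(np.asarray(img, float) * 255.0), 0, 255).astype(int)


def entropy_oracle(img):
    counts = {}
    for v in _q(img).ravel():
        counts[v] = counts.get(v, 0) + 1
    n = img.size
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _joint_counts(x, y):
    counts = {}
    for u, v in zip(_q(x).ravel(), _q(y).ravel()):
        counts[(u, v)] = counts.get((u, v), 0) + 1
    return counts


def mi_pair_oracle(x, y):
    n = x.size
    joint = _joint_counts(x, y)
    px, py = {}, {}
    for (u, v), c in joint.items():
        px[u] = px.get(u, 0) + c
        py[v] = py.get(v, 0) + c
    out = 0.0
    for (u, v), c in joint.items():
        p = c / n
        out += p * math.log2(p / ((px[u] / n) * (py[v] / n)))
    return out


def psnr_oracle(ref, out):
    r = np.asarray(ref, float) * 255.0
    o = np.asarray(out, float) * 255.0
    mse = 0.0
    for a, b in zip(r.ravel(), o.ravel()):
        mse += (a - b) ** 2
    mse /= r.size
    if mse == 0:
        return float("inf")
    return 10.0 * math.log10(255.0 ** 2 / mse)


def sd_oracle(img):
    x = np.asarray(img, float) * 255.0
    mu = sum(x.ravel()) / x.size
    acc = sum((v - mu) ** 2 for v in x.ravel())
    return math.sqrt(acc / x.size)


def avg_gradient_oracle(img):
    x = np.asarray(img, float) * 255.0
    m, n = x.shape
    acc = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dx = x[i, j] - x[i + 1, j]
            dy = x[i, j] - x[i, j + 1]
            acc += math.sqrt((dx ** 2 + dy ** 2) / 2.0)
    return acc / ((m - 1) * (n - 1))


def ncc_oracle(x, y):
    """Mutual information in base-256 logs (the uniform-marginal reading
    of the joint-histogram nonlinear correlation coefficient)."""
    return mi_pair_oracle(x, y) / math.log2(256)


def q_ncie_oracle(a, b, f):
    r = np.array([
        [1.0, ncc_oracle(a, b), ncc_oracle(a, f)],
        [ncc_oracle(a, b), 1.0, ncc_oracle(b, f)],
        [ncc_oracle(a, f), ncc_oracle(b, f), 1.0],
    ])
    lam = sorted(np.real(np.linalg.eigvals(r)))
    out = 1.0
    for v in lam:
        v = max(v, 0.0) / 3.0
        if v > 0:
            out += v * math.log(v) / math.log(256)
    return out


def _sobel_oracle(img255):
    """Standard Sobel pair via explicit correlation with half-sample
    mirror extension (matches ndimage's 'reflect')."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    xp = np.pad(img255, 1, mode="symmetric")
    m, n = img255.shape
    gx = np.zeros((m, n))
    gy = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            win = xp[i:i + 3, j:j + 3]
            gx[i, j] = float(np.sum(win * kx))
            gy[i, j] = float(np.sum(win * ky))
    g = np.sqrt(gx ** 2 + gy ** 2)
    alpha = np.where(gx != 0,
                     np.arctan(np.divide(gy, gx, out=np.zeros_like(gy),
                                         where=gx != 0)),
                     math.pi / 2)
    return g, alpha


def q_abf_oracle(a, b, f):
    """Edge-preservation score with normalized sigmoids (scalar loops)."""
    cg, kg, sg = 0.9994, -15.0, 0.5
    ca, ka, sa = 0.9879, -22.0, 0.8

    def sig(x, gamma, k, s):
        return gamma / (1.0 + math.exp(k * (x - s)))

    a255 = np.asarray(a, float) * 255.0
    b255 = np.asarray(b, float) * 255.0
    f255 = np.asarray(f, float) * 255.0
    gf, af = _sobel_oracle(f255)
    num = 0.0
    den = 0.0
    for src in (a255, b255):
        gs, asrc = _sobel_oracle(src)
        for i in range(gs.shape[0]):
            for j in range(gs.shape[1]):
                hi = max(gs[i, j], gf[i, j])
                ratio = (min(gs[i, j], gf[i, j]) / hi) if hi > 0 else 0.0
                ang = 1.0 - abs(asrc[i, j] - af[i, j]) / (math.pi / 2)
                q = (sig(ratio, cg, kg, sg) / sig(1.0, cg, kg, sg)) * (
                    sig(ang, ca, ka, sa) / sig(1.0, ca, ka, sa))
                num += q * gs[i, j]
                den += gs[i, j]
    return num / den if den > 0 else 0.0


def pcnn_single_neuron_trace(s, beta, alpha_l, v_l, alpha_h, v_h, n_iter):
    """Scalar hand-stepped recurrence for one uncoupled neuron.

    Returns the list of firing steps (1-based).
    """
    ell = 0.0
    h = 0.0
    fires = []
    for n in range(1, n_iter + 1):
        f = s
        ell = math.exp(-alpha_l) * ell  # no neighbors: coupling sum is 0
        u = f * (1.0 + beta * ell)
        y = 1.0 if u > h else 0.0
        h = math.exp(-alpha_h) * h + v_h * y
        if y:
            fires.append(n)
    return fires
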