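"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (explicit loops,
dense oversampling, finite differences) without calling the package
implementation it checks.
"""

import numpy as np

# angle -> unit offset (row down); independent restatement of the convention
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(quantized, d, theta, levels, symmetric=True, normalized=True, mask=None):
    """Co-occurrence counts by explicit per-pixel pair enumeration."""
    grid = np.asarray(quantized)
    h, w = grid.shape
    drow, dcol = ANGLE_OFFSETS[theta][0] * d, ANGLE_OFFSETS[theta][1] * d
    table = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + drow, c + dcol
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            table[grid[r, c], grid[r2, c2]] += 1
    if symmetric:
        table = table + table.T
    if normalized and table.sum() > 0:
        table = table / table.sum()
    return table


def haralick_bruteforce(P):
    """The four texture features by direct double loops over a normalized table."""
    levels = P.shape[0]
    contrast = energy = homog = 0.0
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = sum(i * p_i[i] for i in range(levels))
    mu_j = sum(j * p_j[j] for j in range(levels))
    var_i = sum((i - mu_i) ** 2 * p_i[i] for i in range(levels))
    var_j = sum((j - mu_j) ** 2 * p_j[j] for j in range(levels))
    cov = 0.0
    for i in range(levels):
        for j in range(levels):
            contrast += (i - j) ** 2 * P[i, j]
            energy += P[i, j] ** 2
            homog += P[i, j] / (1.0 + (i - j) ** 2)
            cov += (i - mu_i) * (j - mu_j) * P[i, j]
    sigma = np.sqrt(var_i * var_j)
    correlation = cov / sigma if sigma > 0 else 0.0
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homog,
    }


def convolve_bruteforce(image, kernel):
    """Nested-loop 2-D convolution with reflect (mirror) border handling."""
    h, w = image.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2

    def reflect(i, n):
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            if i >= n:
                i = 2 * n - i - 1
        return i

    out = np.zeros_like(image, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for a in range(-rh, rh + 1):
                for b in range(-rw, rw + 1):
                    rr = reflect(r - a, h)
                    cc = reflect(c - b, w)
                    acc += kernel[a + rh, b + rw] * image[rr, cc]
            out[r, c] = acc
    return out


def bilinear_clamped(fm, r, c):
    h, w = fm.shape
    r = min(max(r, 0.0), h - 1.0)
    c = min(max(c, 0.0), w - 1.0)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
    fr, fc = r - r0, c - c0
    top = fm[r0, c0] * (1 - fc) + fm[r0, c1] * fc
    bot = fm[r1, c0] * (1 - fc) + fm[r1, c1] * fc
    return top * (1 - fr) + bot * fr


def roi_align_oversampled(fm, box, out_size, oversample=100):
    """RoI Align by dense oversampling: mean of a fine bilinear sample grid."""
    r_min, c_min, r_max, c_max = box
    out_h, out_w = out_size
    bin_h = (r_max - r_min) / out_h
    bin_w = (c_max - c_min) / out_w
    out = np.zeros(out_size)
    frac = (np.arange(oversample) + 0.5) / oversample
    for bi in range(out_h):
        for bj in range(out_w):
            vals = []
            for fr in frac:
                for fc in frac:
                    rr = r_min + (bi + fr) * bin_h - 0.5
                    cc = c_min + (bj + fc) * bin_w - 0.5
                    vals.append(bilinear_clamped(fm, rr, cc))
            out[bi, bj] = np.mean(vals)
    return out


def roi_align_scipy(fm, box, out_size, samples_per_bin):
    """RoI Align at the defined sample points, via scipy's bilinear resampler."""
    from scipy.ndimage import map_coordinates

    r_min, c_min, r_max, c_max = box
    out_h, out_w = out_size
    bin_h = (r_max - r_min) / out_h
    bin_w = (c_max - c_min) / out_w
    s = samples_per_bin
    frac = (np.arange(s) + 0.5) / s
    out = np.zeros(out_size)
    h, w = fm.shape
    for bi in range(out_h):
        for bj in range(out_w):
            rr = np.clip(r_min + (bi + frac) * bin_h - 0.5, 0, h - 1)
            cc = np.clip(c_min + (bj + frac) * bin_w - 0.5, 0, w - 1)
            grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
            vals = map_coordinates(fm, [grid_r.ravel(), grid_c.ravel()],
                                   order=1, mode="nearest")
            out[bi, bj] = vals.mean()
    return out


def finite_difference_grads(loss_fn, params, h=1e-6):
    """Central finite differences of a scalar loss over a list of arrays."""
    grads = []
    for p in params:
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + h
            l1 = loss_fn()
            p[idx] = orig - h
            l2 = loss_fn()
            p[idx] = orig
            g[idx] = (l1 - l2) / (2 * h)
        grads.append(g)
    return grads
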