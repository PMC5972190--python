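"""Independent brute-force oracles used to verify the fast implementations.

Each oracle enumerates windows/offsets directly and shares nothing with the
implementation path it checks beyond the stated padding convention.
"""

import numpy as np
from scipy import ndimage as ndi


def guided_filter_brute(data: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Direct per-window guided filter: enumerate every (2r+1)^3 window of the
    reflect-padded input, compute its mean/variance and linear coefficients,
    then average coefficients over the windows containing each voxel."""
    data = np.asarray(data, dtype=np.float64)
    nz, ny, nx = data.shape
    P = np.pad(data, 2 * r, mode="symmetric")
    w = 2 * r + 1
    # window centers live on the grid padded by r on each side
    csz, csy, csx = nz + 2 * r, ny + 2 * r, nx + 2 * r
    a = np.empty((csz, csy, csx))
    b = np.empty((csz, csy, csx))
    for i in range(csz):
        for j in range(csy):
            for k in range(csx):
                win = P[i:i + w, j:j + w, k:k + w]
                m = win.mean()
                v = win.var()
                a[i, j, k] = v / (v + eps)
                b[i, j, k] = (1.0 - a[i, j, k]) * m
    out = np.empty_like(data)
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                A = a[i:i + w, j:j + w, k:k + w].mean()
                B = b[i:i + w, j:j + w, k:k + w].mean()
                out[i, j, k] = A * data[i, j, k] + B
    return np.clip(out, 0.0, 1.0)


def bilateral_filter_brute(data: np.ndarray, sigma: float, mu: float,
                           support_radius: int) -> np.ndarray:
    """Direct triple-loop bilateral filter over the reflect-padded cube."""
    data = np.asarray(data, dtype=np.float64)
    R = support_radius
    P = np.pad(data, R, mode="symmetric")
    nz, ny, nx = data.shape
    out = np.empty_like(data)
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                center = data[i, j, k]
                num = 0.0
                den = 0.0
                for dz in range(-R, R + 1):
                    for dy in range(-R, R + 1):
                        for dx in range(-R, R + 1):
                            val = P[R + i + dz, R + j + dy, R + k + dx]
                            wgt = np.exp(
                                -(dz * dz + dy * dy + dx * dx) / (2 * sigma ** 2)
                            ) * np.exp(-(center - val) ** 2 / (2 * mu))
                            num += wgt * val
                            den += wgt
                out[i, j, k] = num / den
    return out


def truncated_gaussian_blur(data: np.ndarray, sigma: float,
                            support_radius: int) -> np.ndarray:
    """Normalised truncated-Gaussian convolution (the large-mu limit of the
    bilateral filter), via direct correlation with reflect padding."""
    R = support_radius
    zz, yy, xx = np.mgrid[-R:R + 1, -R:R + 1, -R:R + 1]
    k = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / (2.0 * sigma ** 2))
    k /= k.sum()
    return ndi.correlate(np.asarray(data, dtype=np.float64), k, mode="reflect")


def erode_enum(data: np.ndarray, offsets: np.ndarray, binary: bool) -> np.ndarray:
    """Erosion by direct offset enumeration.

    Grayscale pads by edge replication; binary pads with background 0.
    Exact min over shifted copies, so results are bit-comparable.
    """
    return _minmax_enum(data, offsets, binary, op="min")


def dilate_enum(data: np.ndarray, offsets: np.ndarray, binary: bool) -> np.ndarray:
    """Dilation by direct enumeration of the (symmetric) SE offsets."""
    return _minmax_enum(data, offsets, binary, op="max")


def _minmax_enum(data, offsets, binary, op):
    data = np.asarray(data)
    r = int(np.abs(offsets).max()) if len(offsets) else 0
    if binary:
        P = np.pad(data.astype(np.uint8), r, mode="constant", constant_values=0)
    else:
        P = np.pad(data, r, mode="edge")
    nz, ny, nx = data.shape
    shifted = [
        P[r + dz:r + dz + nz, r + dy:r + dy + ny, r + dx:r + dx + nx]
        for dz, dy, dx in offsets
    ]
    red = np.minimum if op == "min" else np.maximum
    out = red.reduce(shifted)
    return out.astype(bool) if binary else out


def random_blob_mask(shape, seed, density=0.5, smooth=1.5):
    """Random blobby binary mask: thresholded smoothed noise."""
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    thr = np.quantile(field, 1.0 - density)
    return field > thr
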