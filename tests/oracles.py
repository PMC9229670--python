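"""Independent brute-force oracles used across the test suite.

These are deliberately naive re-derivations (sliding-window morphology,
set-based Dice, index-mapping resize) kept separate from the package so they
can disagree with it.
"""

import numpy as np


def brute_force_dilate(binary: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window maximum with zero padding outside the image."""
    r = k // 2
    padded = np.pad(binary.astype(bool), r, constant_values=False)
    out = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + k, j : j + k].any()
    return out


def brute_force_erode(binary: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window minimum with one padding outside the image."""
    r = k // 2
    padded = np.pad(binary.astype(bool), r, constant_values=True)
    out = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + k, j : j + k].all()
    return out


def brute_force_closure(binary: np.ndarray, k: int) -> np.ndarray:
    return brute_force_erode(brute_force_dilate(binary, k), k)


def set_dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """2|A∩B| / (|A|+|B|) from explicit pixel index sets."""
    sa = {tuple(ix) for ix in np.argwhere(np.asarray(a, dtype=bool))}
    sb = {tuple(ix) for ix in np.argwhere(np.asarray(b, dtype=bool))}
    if not sa and not sb:
        return None
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def nearest_resize(px: np.ndarray, target: int) -> np.ndarray:
    """Top-left convention: output (i, j) reads source (i*h//t, j*w//t)."""
    h, w = px.shape
    return np.array(
        [[px[(i * h) // target, (j * w) // target] for j in range(target)] for i in range(target)]
    )


def global_equalize(px: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Plain histogram equalization of a [0,1] image via its empirical CDF."""
    hist, edges = np.histogram(px.ravel(), bins=nbins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(float)
    cdf /= cdf[-1]
    centers = (edges[:-1] + edges[1:]) / 2
    return np.interp(px.ravel(), centers, cdf).reshape(px.shape)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
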