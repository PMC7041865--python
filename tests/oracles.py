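"""Brute-force reference implementations used by multiple test modules.

These stay deliberately naive (per-pixel loops, explicit sums) so they are
independent of the library code paths they check.
"""

import numpy as np
from skimage.morphology import disk


def histogram_equalize_oracle(values: np.ndarray) -> np.ndarray:
    """Plain histogram equalization: out = P(X <= x) over the pixel sample."""
    flat = values.ravel()
    order = np.sort(flat)
    return np.searchsorted(order, flat, side="right").reshape(values.shape) / flat.size


def erode_oracle(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    fh, fw = footprint.shape
    ph, pw = fh // 2, fw // 2
    padded = np.pad(image.astype(float), ((ph, ph), (pw, pw)), constant_values=np.inf)
    out = np.empty_like(image, dtype=float)
    offs = [(i, j) for i in range(fh) for j in range(fw) if footprint[i, j]]
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = min(padded[r + i, c + j] for i, j in offs)
    return out


def dilate_oracle(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    fh, fw = footprint.shape
    ph, pw = fh // 2, fw // 2
    padded = np.pad(image.astype(float), ((ph, ph), (pw, pw)), constant_values=-np.inf)
    out = np.empty_like(image, dtype=float)
    offs = [(i, j) for i in range(fh) for j in range(fw) if footprint[i, j]]
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = max(padded[r + i, c + j] for i, j in offs)
    return out


def tophat_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    fp = disk(radius)
    return image - dilate_oracle(erode_oracle(image, fp), fp)


def nearest_nucleus_oracle(labels: np.ndarray, tissue_mask: np.ndarray):
    """Per-pixel loop: distance to the nearest nucleus pixel and its label."""
    coords = np.argwhere(labels > 0)
    lab_of = labels[coords[:, 0], coords[:, 1]]
    dist = np.zeros(labels.shape)
    assign = np.zeros(labels.shape, dtype=int)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if not tissue_mask[r, c]:
                continue
            d = np.hypot(coords[:, 0] - r, coords[:, 1] - c)
            k = int(np.argmin(d))
            dist[r, c] = d[k]
            assign[r, c] = lab_of[k]
    return assign, dist


def anova_oracle(groups) -> float:
    """Textbook one-way ANOVA F from the sums-of-squares decomposition."""
    all_vals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g, dtype=float) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)
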