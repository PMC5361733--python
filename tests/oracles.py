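"""Independent brute-force oracles used by the unit and acceptance suites.

Everything here is deliberately naive — loops, fixpoint iteration, direct
formulas — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def brute_two_level_otsu(hist) -> tuple[int, int]:
    """Exhaustive search over all cut pairs for the 3-class split maximising
    between-class variance; smallest (i, j) wins ties."""
    h = np.asarray(hist, dtype=float)
    n = h.size
    total = h.sum()
    p = h / total
    centers = np.arange(n, dtype=float)
    mu_total = float((p * centers).sum())
    best = None
    best_v = -math.inf
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            classes = (p[:i + 1], p[i + 1:j + 1], p[j + 1:])
            cents = (centers[:i + 1], centers[i + 1:j + 1], centers[j + 1:])
            v = 0.0
            ok = True
            for pc, cc in zip(classes, cents):
                w = pc.sum()
                if w <= 0:
                    ok = False
                    break
                m = float((pc * cc).sum()) / w
                v += w * (m - mu_total) ** 2
            if ok and (best is None
                       or v > best_v + 1e-9 * max(1.0, abs(best_v))):
                best_v = v
                best = (i, j)
    if best is None:
        raise ValueError("no valid 3-class split")
    return best


def brute_otsu_1d(hist) -> int:
    """Exhaustive 2-class Otsu cut on a histogram; smallest cut wins ties."""
    h = np.asarray(hist, dtype=float)
    p = h / h.sum()
    centers = np.arange(h.size, dtype=float)
    best, best_v = None, -math.inf
    for k in range(h.size - 1):
        w0 = p[:k + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        m0 = float((p[:k + 1] * centers[:k + 1]).sum()) / w0
        m1 = float((p[k + 1:] * centers[k + 1:]).sum()) / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if best is None or v > best_v + 1e-9 * max(1.0, abs(best_v)):
            best_v, best = v, k
    return best


def brute_reconstruction_by_dilation(seed: np.ndarray, mask: np.ndarray
                                     ) -> np.ndarray:
    """Greyscale reconstruction of ``seed`` under ``mask``: iterate
    26-connected dilation capped by the mask until fixpoint."""
    rec = np.minimum(np.asarray(seed, float), np.asarray(mask, float))
    while True:
        new = np.minimum(ndi.grey_dilation(rec, footprint=STRUCT_26,
                                           mode="constant", cval=-np.inf),
                         mask)
        if np.array_equal(new, rec):
            return rec
        rec = new


def brute_regional_maxima(volume: np.ndarray) -> np.ndarray:
    """Plateau-by-plateau regional maxima: a connected constant-value set all
    of whose outside 26-neighbours are strictly lower."""
    v = np.asarray(volume, float)
    out = np.zeros(v.shape, bool)
    for val in np.unique(v):
        lab, n = ndi.label(v == val, structure=STRUCT_26)
        for k in range(1, n + 1):
            comp = lab == k
            ring = ndi.binary_dilation(comp, structure=STRUCT_26) & ~comp
            if not ring.any() or v[ring].max() < val:
                out |= comp
    return out


def brute_extended_maxima_mask(volume: np.ndarray, h: float) -> np.ndarray:
    """Extended maxima as regional maxima of the h-maxima transform, the
    transform itself computed by fixpoint reconstruction."""
    v = np.asarray(volume, float)
    hmax = brute_reconstruction_by_dilation(v - h, v)
    return brute_regional_maxima(hmax)


def pooled_t(a, b) -> tuple[float, float]:
    """Long-hand pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def hand_anova_f(groups) -> float:
    """Long-hand one-way ANOVA table: SSB/SSW -> F."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def two_pass_mean_sem(values) -> tuple[float, float]:
    """Naive two-pass mean and SD/sqrt(n)."""
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    if n == 1:
        return mean, 0.0
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    return mean, sd / math.sqrt(n)
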