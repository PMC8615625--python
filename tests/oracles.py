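"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: distances by explicit
minimisation over vessel pixels, prominences by repeated superlevel-set
labeling, medians by enumeration of all pairs, permutation p-values by
exhaustive enumeration.
"""

import itertools

import numpy as np
from scipy import ndimage

_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity structure


def brute_force_distance_map(vessel: np.ndarray, pixel_size: float) -> np.ndarray:
    """Min-over-vessel-pixels Euclidean distance between pixel centers (µm)."""
    vy, vx = np.nonzero(vessel)
    h, w = vessel.shape
    out = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = np.sqrt(((vy - y) ** 2 + (vx - x) ** 2).min())
    return out * pixel_size


def exhaustive_prominent_maxima(values: np.ndarray, mask: np.ndarray,
                                threshold: float) -> list[tuple[float, float]]:
    """All maxima with prominence >= threshold, by superlevel-set descent.

    A maximum is a plateau (8-connected equal-value region) all of whose
    neighbours are lower.  Maxima are ranked by (value descending, centroid
    (y, x) ascending).  Scanning unique image values from high to low, the
    saddle of a maximum is the highest level at which its superlevel
    component contains a higher-ranked maximum; with no higher-ranked
    maximum in its mask component, the saddle is the component minimum.
    Returns plateau centroids sorted by (-value, centroid).
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []

    # plateau decomposition: label equal-valued connected regions
    plateaus = []  # (value, centroid, pixel boolean mask)
    for v in np.unique(values[mask]):
        lab, n = ndimage.label((values == v) & mask, structure=_S8)
        for i in range(1, n + 1):
            region = lab == i
            ys, xs = np.nonzero(region)
            plateaus.append({"value": float(v),
                             "centroid": (float(ys.mean()), float(xs.mean())),
                             "region": region})

    # a plateau is a maximum iff no neighbouring in-mask pixel is higher
    maxima = []
    for p in plateaus:
        dil = ndimage.binary_dilation(p["region"], structure=_S8.astype(bool))
        ring = dil & ~p["region"] & mask
        is_max = (not ring.any()) or (not np.any(values[ring] > p["value"]))
        if is_max:
            maxima.append(p)
    maxima.sort(key=lambda p: (-p["value"], p["centroid"]))
    seeds = []
    for m in maxima:
        ys, xs = np.nonzero(m["region"])
        seeds.append((int(ys[0]), int(xs[0])))

    levels = np.unique(values[mask])[::-1]
    labels_by_level = {float(lv): ndimage.label((values >= lv) & mask, structure=_S8)[0]
                       for lv in levels}
    mask_lab, _ = ndimage.label(mask, structure=_S8)

    kept = []
    for rank, m in enumerate(maxima):
        saddle = None
        seed = seeds[rank]
        for lv in levels:
            if lv > m["value"]:
                continue
            comp_lab = labels_by_level[float(lv)]
            cid = comp_lab[seed]
            if any(comp_lab[seeds[r2]] == cid for r2 in range(rank)):
                saddle = float(lv)
                break
        if saddle is None:
            comp = mask_lab == mask_lab[seed]
            saddle = float(values[comp].min())
        if m["value"] - saddle >= threshold:
            kept.append(m["centroid"])
    return kept


def brute_force_median_pairwise(points: np.ndarray) -> float | None:
    """Median of all pairwise Euclidean distances; None for < 2 points."""
    n = len(points)
    if n < 2:
        return None
    d = [float(np.hypot(*(points[i] - points[j])))
         for i, j in itertools.combinations(range(n), 2)]
    return float(np.median(d))


def exhaustive_permutation_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided difference-of-means p-value over ALL label assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(a.mean() - b.mean())
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(combo)] = True
        diff = abs(pooled[sel].mean() - pooled[~sel].mean())
        if diff >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
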