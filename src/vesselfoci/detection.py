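"""γH2AX focus detection and per-nucleus foci metrics.

The detector reproduces the behaviour of a noise-tolerance maximum finder:
a local maximum is reported iff its *prominence* — its height above the
highest saddle connecting it to higher terrain — reaches a user-set
threshold.  Prominence is computed exactly by a descending flood over the
nucleus: pixels are merged into components from the brightest down, and a
maximum "dies" at the level where its component first touches a component
holding a higher maximum.  Plateaus (connected pixels of equal value)
collapse to a single candidate at the plateau centroid.

Equal-valued maxima need a tie rule for "higher": we order maxima by
(intensity descending, plateau centroid (y, x) ascending); the earlier
maximum of a tied pair survives a merge, the later one dies with zero
prominence at the tie level.  The global maximum of a nucleus has
prominence equal to its height above the nucleus minimum, so a perfectly
flat nucleus yields no foci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

from .geometry import assign_distance_category
from .io import PlaneImage

__all__ = [
    "NucleusRecord",
    "FocusRecord",
    "FociMetrics",
    "prominence_maxima",
    "detect_foci",
    "focus_size",
    "measure_focus_sizes",
    "mutual_foci_distance",
    "category_mean_area",
    "corrected_foci",
]

# 8-connectivity offsets
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class NucleusRecord:
    """One segmented nucleus and its per-cell covariates."""

    nucleus_id: int
    centroid: tuple[float, float]  # (y, x) px
    area: float  # µm²
    distance: float  # µm to nearest perfused vessel
    category: str = ""
    section_id: str = ""
    tumor_id: str = ""
    arm_id: str = ""
    roi_id: int = 0
    mean_dapi: float = float("nan")
    marker_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.area > 0):
            raise ValueError(f"nucleus area must be positive, got {self.area}")
        if not self.category:
            self.category = assign_distance_category(self.distance)


@dataclass
class FocusRecord:
    """One detected focus inside a nucleus."""

    nucleus_id: int
    peak: tuple[float, float]     # (y, x) px, plateau centroid
    peak_intensity: float
    prominence: float
    size: float = float("nan")    # µm², filled by measure_focus_sizes
    rep_pixel: tuple[int, int] = (0, 0)  # a max-valued pixel of the plateau


@dataclass
class FociMetrics:
    """Per-nucleus derived quantities."""

    nucleus_id: int
    n_foci: int
    cfoci: float
    median_mutual_distance: float | None  # µm, None when < 2 foci
    mean_area_used: float  # µm², the stratum mean behind cfoci


def prominence_maxima(values: np.ndarray, mask: np.ndarray
                      ) -> list[tuple[tuple[float, float], tuple[int, int], float, float]]:
    """All local maxima of ``values`` within ``mask`` with exact prominences.

    Returns a list of ``(centroid_yx, rep_pixel_yx, value, prominence)``,
    one per maximum plateau, unordered.  The prominence of the highest
    maximum of each connected mask component is its height above the
    component minimum.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if not mask.any():
        return []

    idx = np.flatnonzero(mask)
    h, w = values.shape
    flat = values.ravel()

    # --- plateau labeling: connected components of equal value (8-conn) ---
    parent = {int(i): int(i) for i in idx}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in idx:
        y, x = divmod(int(i), w)
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                j = ny * w + nx
                if mask[ny, nx] and flat[j] == flat[i]:
                    union(int(i), j)

    plateau_of: dict[int, int] = {}
    plateaus: list[dict] = []
    for i in idx:
        r = find(int(i))
        if r not in plateau_of:
            plateau_of[r] = len(plateaus)
            plateaus.append({"value": float(flat[r]), "pixels": []})
        plateaus[plateau_of[r]]["pixels"].append(int(i))

    pixel_plateau = {}
    for pi, p in enumerate(plateaus):
        ys = np.array([q // w for q in p["pixels"]])
        xs = np.array([q % w for q in p["pixels"]])
        p["centroid"] = (float(ys.mean()), float(xs.mean()))
        # representative pixel: lexicographically smallest (y, x)
        order = np.lexsort((xs, ys))
        p["rep"] = (int(ys[order[0]]), int(xs[order[0]]))
        for q in p["pixels"]:
            pixel_plateau[q] = pi

    # plateau adjacency
    adjacency: list[set[int]] = [set() for _ in plateaus]
    for i in idx:
        pi = pixel_plateau[int(i)]
        y, x = divmod(int(i), w)
        for dy, dx in _NEIGHBORS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                pj = pixel_plateau[ny * w + nx]
                if pj != pi:
                    adjacency[pi].add(pj)

    # --- descending flood over plateaus ---
    # rank: value descending, centroid (y, x) ascending; rank 0 is "highest"
    order = sorted(range(len(plateaus)),
                   key=lambda p: (-plateaus[p]["value"], plateaus[p]["centroid"]))
    rank = {p: r for r, p in enumerate(order)}

    comp_parent = list(range(len(plateaus)))

    def cfind(a: int) -> int:
        root = a
        while comp_parent[root] != root:
            root = comp_parent[root]
        while comp_parent[a] != root:
            comp_parent[a], a = root, comp_parent[a]
        return root

    active = [False] * len(plateaus)
    birth: dict[int, int] = {}      # component root -> birth maximum plateau
    comp_min = [np.inf] * len(plateaus)
    prominence: dict[int, float] = {}  # maximum plateau -> prominence
    maxima: list[int] = []

    for p in order:
        v = plateaus[p]["value"]
        active[p] = True
        birth[p] = p
        comp_min[p] = v
        roots = {cfind(q) for q in adjacency[p] if active[q]}
        if not roots:
            maxima.append(p)  # all neighbours are lower: a local maximum plateau
        # merge p's component with all active neighbour components
        for r in roots:
            rp = cfind(p)
            if r == rp:
                continue
            # survivor: component whose birth maximum has the smaller rank
            if rank[birth[r]] < rank[birth[rp]]:
                surv, dead = r, rp
            else:
                surv, dead = rp, r
            dead_birth = birth[dead]
            # the dead component's maximum dies at the current (saddle) level
            prominence[dead_birth] = plateaus[dead_birth]["value"] - v
            comp_parent[dead] = surv
            comp_min[surv] = min(comp_min[surv], comp_min[dead], v)

    # survivors: one per connected mask component
    seen = set()
    for p in range(len(plateaus)):
        r = cfind(p)
        if r in seen:
            continue
        seen.add(r)
        b = birth[r]
        prominence[b] = plateaus[b]["value"] - comp_min[r]

    out = []
    for m in maxima:
        p = plateaus[m]
        out.append((p["centroid"], p["rep"], p["value"], float(prominence[m])))
    return out


def detect_foci(image: PlaneImage, nucleus_mask: np.ndarray, prominence: float,
                nucleus_id: int = 0) -> list[FocusRecord]:
    """Detect foci in one nucleus as local maxima of prominence ≥ ``prominence``.

    Records are ordered by descending peak intensity, ties broken by (y, x)
    of the plateau centroid.  The detector is invariant to adding a constant
    to the image: only relative heights matter.
    """
    if not (prominence > 0):
        raise ValueError(f"prominence must be positive, got {prominence}")
    mask = np.asarray(nucleus_mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("nucleus mask and image shapes differ")
    if not mask.any():
        return []
    # crop to the mask bounding box to keep the flood cheap
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = image.pixels[y0:y1, x0:x1]
    mcrop = mask[y0:y1, x0:x1]
    records = []
    for centroid, rep, value, prom in prominence_maxima(crop, mcrop):
        if prom >= prominence:
            records.append(FocusRecord(
                nucleus_id=nucleus_id,
                peak=(centroid[0] + y0, centroid[1] + x0),
                peak_intensity=float(value),
                prominence=float(prom),
                rep_pixel=(rep[0] + y0, rep[1] + x0),
            ))
    records.sort(key=lambda f: (-f.peak_intensity, f.peak))
    return records


def measure_focus_sizes(image: PlaneImage, foci: list[FocusRecord],
                        nucleus_mask: np.ndarray, prominence: float) -> None:
    """Fill ``size`` (µm²) on each focus record in place.

    The raw region of a focus is the connected set of mask pixels with
    intensity ≥ (peak − prominence) containing its peak.  Where raw regions
    overlap, each contested pixel goes to the nearest peak (ties to the
    brighter, then earlier-ordered focus), so a focus never swallows a
    brighter neighbour's territory.
    """
    if not foci:
        return
    mask = np.asarray(nucleus_mask, dtype=bool)
    px_area = image.pixel_size ** 2
    regions = []
    for f in foci:
        thr = f.peak_intensity - prominence
        above = mask & (image.pixels >= thr)
        lab, _ = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
        regions.append(lab == lab[f.rep_pixel])
    n = len(foci)
    claim_count = np.sum(regions, axis=0)
    peaks = np.array([f.peak for f in foci])
    counts = np.zeros(n, dtype=int)
    for i, reg in enumerate(regions):
        sole = reg & (claim_count == 1)
        counts[i] += int(sole.sum())
    contested = claim_count > 1
    if contested.any():
        cy, cx = np.nonzero(contested)
        for y, x in zip(cy, cx):
            claimants = [i for i in range(n) if regions[i][y, x]]
            d2 = [(peaks[i][0] - y) ** 2 + (peaks[i][1] - x) ** 2 for i in claimants]
            best = claimants[int(np.lexsort((claimants, d2))[0])]
            counts[best] += 1
    for f, c in zip(foci, counts):
        f.size = float(max(c, 1)) * px_area


def focus_size(image: PlaneImage, focus: FocusRecord, prominence: float,
               nucleus_mask: np.ndarray,
               other_foci: list[FocusRecord] = ()) -> float:
    """Size (µm²) of one focus; see :func:`measure_focus_sizes` for the rule."""
    foci = [focus, *[f for f in other_foci if f is not focus]]
    measure_focus_sizes(image, foci, nucleus_mask, prominence)
    return focus.size


def mutual_foci_distance(foci: list[FocusRecord], pixel_size: float) -> float | None:
    """Median Euclidean distance (µm) over all focus pairs; None when < 2 foci.

    With n foci there are n·(n−1)/2 pairs; the median is over all of them.
    A small value indicates spatially clustered (complex) damage.
    """
    if len(foci) < 2:
        return None
    pts = np.array([f.peak for f in foci], dtype=float) * pixel_size
    return float(np.median(pdist(pts)))


def category_mean_area(areas_um2) -> float:
    """Arithmetic mean nucleus area of one (tumor, distance-category) stratum."""
    areas = np.asarray(list(areas_um2), dtype=float)
    if areas.size == 0:
        raise ValueError("empty stratum: mean nucleus area (and hence cfoci) undefined")
    if np.any(areas <= 0):
        raise ValueError("nucleus areas must be positive")
    return float(areas.mean())


def corrected_foci(n_foci: int, nucleus_area: float, mean_area: float) -> float:
    """Size-corrected foci count: ``mean_area × (n_foci / nucleus_area)``.

    The correction rescales each count to a nucleus of the stratum-average
    size, removing the bias that larger nuclei intersect more damage in a
    2-D section.
    """
    if not (nucleus_area > 0) or not (mean_area > 0):
        raise ValueError("nucleus_area and mean_area must be positive")
    if n_foci < 0:
        raise ValueError("n_foci must be non-negative")
    return mean_area * (n_foci / nucleus_area)
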