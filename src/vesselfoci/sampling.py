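"""ROI eligibility and random per-category cell sampling.

An ROI enters the foci analysis only if it contains a single perfused
vessel that is pimonidazole-negative (i.e. oxygenated) and is surrounded
by BrdU-positive (proliferating) cells.  The qualitative criteria are made
operational with explicit, configurable thresholds; within each distance
category a fixed number of analyzable cells is then drawn uniformly at
random for enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask

__all__ = [
    "EligibilityParams",
    "EligibilityFlags",
    "ROISpec",
    "SamplingPlan",
    "AnalyzableRule",
    "check_roi_eligibility",
    "count_analyzable_cells",
    "sample_cells",
]


@dataclass
class EligibilityParams:
    """Operational thresholds for the qualitative ROI criteria.

    r_pimo_um: radius around the vessel in which pimonidazole positivity is
        assessed; f_pimo_max: maximum tolerated pimonidazole-positive pixel
        fraction within that radius for the vessel to count as perfused;
    r_brdu_um / n_brdu_min: the vessel must have at least ``n_brdu_min``
        BrdU-positive cells (connected components) within ``r_brdu_um``.
    """

    r_pimo_um: float = 25.0
    f_pimo_max: float = 0.05
    r_brdu_um: float = 50.0
    n_brdu_min: int = 10


@dataclass
class EligibilityFlags:
    single_vessel: bool
    pimo_negative_vessel: bool
    brdu_positive_surround: bool

    @property
    def eligible(self) -> bool:
        return self.single_vessel and self.pimo_negative_vessel and self.brdu_positive_surround


@dataclass
class ROISpec:
    """One candidate region of interest within a section."""

    section_id: str
    roi_id: int
    bounds: tuple[int, int, int, int]  # (y0, x0, y1, x1) px, half-open
    flags: EligibilityFlags | None = None


@dataclass
class SamplingPlan:
    """How many cells to enumerate per distance category, and with what seed."""

    k_per_category: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_category < 1:
            raise ValueError("k_per_category must be >= 1")


@dataclass
class AnalyzableRule:
    """A nucleus is analyzable if it is fully inside the ROI, does not merge
    with a neighbour, and has a plausible single-nucleus area."""

    area_min_um2: float = 20.0
    area_max_um2: float = 400.0

    def __call__(self, *, area_um2: float, touches_border: bool, overlaps: bool) -> bool:
        return (not touches_border and not overlaps
                and self.area_min_um2 <= area_um2 <= self.area_max_um2)


def check_roi_eligibility(vessel_mask: BinaryMask, pimo_mask: BinaryMask,
                          brdu_mask: BinaryMask,
                          params: EligibilityParams | None = None) -> EligibilityFlags:
    """Evaluate the three ROI criteria on co-registered masks of one ROI.

    single_vessel: exactly one connected vessel component in the ROI.
    pimo_negative_vessel: the pimonidazole-positive pixel fraction within
    ``r_pimo_um`` of the vessel stays below ``f_pimo_max`` (monotone: adding
    pimonidazole signal near the vessel can only revoke eligibility).
    brdu_positive_surround: at least ``n_brdu_min`` BrdU-positive connected
    components lie (partly) within ``r_brdu_um`` of the vessel.
    """
    params = params or EligibilityParams()
    if not (vessel_mask.pixels.shape == pimo_mask.pixels.shape == brdu_mask.pixels.shape):
        raise ValueError("vessel, pimonidazole and BrdU masks must share one shape")
    if not (vessel_mask.pixel_size == pimo_mask.pixel_size == brdu_mask.pixel_size):
        raise ValueError("masks must share one pixel size")

    structure = np.ones((3, 3), dtype=int)
    _, n_vessels = ndimage.label(vessel_mask.pixels, structure=structure)
    single_vessel = n_vessels == 1

    if n_vessels == 0:
        return EligibilityFlags(False, False, False)

    dist_um = ndimage.distance_transform_edt(~vessel_mask.pixels) * vessel_mask.pixel_size

    near = dist_um <= params.r_pimo_um
    f_pimo = float(np.mean(pimo_mask.pixels[near])) if near.any() else 0.0
    pimo_negative = f_pimo < params.f_pimo_max

    brdu_labels, n_brdu_all = ndimage.label(brdu_mask.pixels, structure=structure)
    surround = dist_um <= params.r_brdu_um
    near_ids = np.unique(brdu_labels[surround & (brdu_labels > 0)])
    brdu_ok = near_ids.size >= params.n_brdu_min

    return EligibilityFlags(single_vessel, pimo_negative, brdu_ok)


def count_analyzable_cells(nuclei, category: str,
                           rule: AnalyzableRule | None = None,
                           flags: dict[int, dict] | None = None) -> int:
    """Number of analyzable nuclei in one distance category.

    ``flags`` maps nucleus_id to ``{"touches_border": bool, "overlaps": bool}``;
    nuclei missing from it are assumed clean.
    """
    rule = rule or AnalyzableRule()
    flags = flags or {}
    n = 0
    for nuc in nuclei:
        if nuc.category != category:
            continue
        f = flags.get(nuc.nucleus_id, {})
        if rule(area_um2=nuc.area,
                touches_border=bool(f.get("touches_border", False)),
                overlaps=bool(f.get("overlaps", False))):
            n += 1
    return n


def sample_cells(nuclei: list, plan: SamplingPlan) -> list:
    """Draw ``min(k, n)`` nuclei uniformly without replacement, reproducibly.

    The input list must already be restricted to analyzable nuclei of one
    category.  With fewer than k candidates, all are returned.  The output
    preserves the input order of the chosen nuclei so downstream tables are
    deterministic.
    """
    if plan.k_per_category < 1:
        raise ValueError("k_per_category must be >= 1")
    n = len(nuclei)
    k = min(plan.k_per_category, n)
    if k == n:
        return list(nuclei)
    rng = np.random.default_rng(plan.seed)
    chosen = rng.choice(n, size=k, replace=False)
    chosen_set = set(int(c) for c in chosen)
    return [nuc for i, nuc in enumerate(nuclei) if i in chosen_set]
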