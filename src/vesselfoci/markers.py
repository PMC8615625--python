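"""Immunofluorescence intensity classification of marker-positive cells.

Used for markers such as p21 or cleaved caspase-3: each segmented cell's
mean marker intensity is compared against thresholds derived from a
reference (untreated control) population stained in the same batch —
exposure is assumed constant within a batch, so intensities are comparable
across its sections but not across batches.  Positive cells are split into
low / intermediate / high, and the positive fraction is the positive count
over the total cell count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityThresholds",
    "ClassifiedCounts",
    "derive_thresholds",
    "classify_cells",
    "classify_intensities",
]

_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


@dataclass
class IntensityThresholds:
    """Positivity and low/intermediate/high split points for one channel.

    ``reference_population`` names the batch/arm the thresholds were derived
    from; classifying cells from a different batch against them is refused
    unless the caller opts in.
    """

    t_pos: float
    t_mid: float
    t_high: float
    method: str = "median+2*1.4826*MAD; positive range split at p50/p90"
    reference_population: str = ""

    def __post_init__(self) -> None:
        if not (self.t_pos <= self.t_mid < self.t_high):
            raise ValueError(
                f"thresholds must satisfy t_pos <= t_mid < t_high, got "
                f"({self.t_pos}, {self.t_mid}, {self.t_high})"
            )


@dataclass
class ClassifiedCounts:
    n_total: int
    n_low: int
    n_mid: int
    n_high: int

    @property
    def n_positive(self) -> int:
        return self.n_low + self.n_mid + self.n_high

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_total if self.n_total else 0.0


def derive_thresholds(mean_intensities, reference_population: str = "",
                      min_cells: int = 20) -> IntensityThresholds:
    """Derive classification thresholds from a reference intensity sample.

    The positivity threshold is a robust upper bound of the reference
    (mostly-negative) distribution, ``median + 2·1.4826·MAD``; values in the
    sample above it are treated as the positive tail, and its 50th and 90th
    percentiles split positives into low / intermediate / high.  When the
    positive tail is empty the splits fall back to 1.5× and 2× the
    positivity threshold above the median.
    """
    x = np.asarray(list(mean_intensities), dtype=float)
    if x.size < min_cells:
        raise ValueError(f"reference population too small: {x.size} < {min_cells} cells")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        raise ValueError("degenerate reference: zero intensity spread (constant values)")
    sigma = _MAD_SCALE * mad
    t_pos = med + 2.0 * sigma
    tail = x[x > t_pos]
    if tail.size >= 2:
        t_mid = float(np.percentile(tail, 50))
        t_high = float(np.percentile(tail, 90))
    else:
        t_mid = med + 3.0 * sigma
        t_high = med + 4.0 * sigma
    if t_high <= t_mid:  # flat tail: force a strict split
        t_high = np.nextafter(t_mid, np.inf)
    t_mid = max(t_mid, t_pos)
    return IntensityThresholds(t_pos=t_pos, t_mid=t_mid, t_high=t_high,
                               reference_population=reference_population)


def classify_intensities(intensities, thresholds: IntensityThresholds) -> ClassifiedCounts:
    """Classify a vector of per-cell mean intensities.

    A cell is positive iff intensity ≥ t_pos; positives land in
    low = [t_pos, t_mid), intermediate = [t_mid, t_high), high = [t_high, ∞).
    Every cell falls in exactly one of {negative, low, intermediate, high}.
    """
    x = np.asarray(list(intensities), dtype=float)
    pos = x >= thresholds.t_pos
    low = pos & (x < thresholds.t_mid)
    mid = pos & (x >= thresholds.t_mid) & (x < thresholds.t_high)
    high = x >= thresholds.t_high
    return ClassifiedCounts(
        n_total=int(x.size),
        n_low=int(low.sum()),
        n_mid=int(mid.sum()),
        n_high=int(high.sum()),
    )


def classify_cells(cells, channel: str, thresholds: IntensityThresholds,
                   batch: str | None = None,
                   allow_cross_batch: bool = False) -> ClassifiedCounts:
    """Classify nucleus records by their mean intensity in ``channel``.

    ``batch`` (when given) must match the thresholds' reference population
    unless ``allow_cross_batch`` is set: thresholds are only valid within
    the staining batch whose exposure they were derived under.
    """
    if (batch is not None and thresholds.reference_population
            and batch != thresholds.reference_population and not allow_cross_batch):
        raise ValueError(
            f"thresholds derived from batch {thresholds.reference_population!r} "
            f"cannot classify batch {batch!r}; pass allow_cross_batch=True to override"
        )
    vals = []
    for c in cells:
        if channel not in c.marker_means:
            raise ValueError(f"nucleus {c.nucleus_id} has no intensity for channel {channel!r}")
        vals.append(c.marker_means[channel])
    return classify_intensities(vals, thresholds)
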