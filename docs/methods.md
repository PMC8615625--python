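# Methods

This note records the models, conventions and numerical choices behind
`vesselfoci`, in the spirit of a methods supplement: what is computed, which
parameters matter, what the phantom does and does not emulate, and where a
genuinely open design point was decided one way rather than another.

## Projection and geometry

A γH2AX acquisition is a calibrated z-stack (default 17 slices, 0.25 µm
apart). The extended-depth-of-focus image is the pixelwise maximum over z:
for punctate signals, the in-focus slice carries the brightest value, so the
maximum keeps every focus regardless of its focal plane. A side effect
matters for detection (below): the projected *noise* is the maximum of
17 draws per pixel, i.e. extreme-value distributed — shifted upward and
heavier-tailed than single-slice noise.

Vessel distance is the exact Euclidean distance transform of the
perfused-vessel mask complement (`scipy.ndimage.distance_transform_edt`),
scaled to µm. Coordinates are pixel centers; a nucleus's distance is read at
its centroid pixel. The centroid (rather than the nearest nucleus boundary
pixel) was chosen because it is deterministic under segmentation jitter and
matches a per-cell scalar covariate. Distance categories partition
[0, ∞) as **[0, 50) / [50, 100] / (100, ∞) µm**: the printed form of the
middle interval ("50–100") is taken literally as closed, so 50 µm and
100 µm both belong to the middle bin; the tests pin this boundary behavior
to ±1 ulp.

## ROI eligibility and cell sampling

The qualitative ROI criteria — a *single* vessel, *pimonidazole-negative*
(perfused), *surrounded by BrdU-positive cells* — are made operational with
explicit thresholds, all configurable (`EligibilityParams`):

| parameter | default | meaning |
|---|---|---|
| `r_pimo_um` | 25 µm | radius around the vessel where hypoxia staining is assessed |
| `f_pimo_max` | 5 % | max tolerated pimonidazole-positive pixel fraction in that zone |
| `r_brdu_um` | 50 µm | perivascular shell for the proliferation criterion |
| `n_brdu_min` | 10 | min BrdU-positive cells (connected components) in the shell |

Eligibility is monotone by construction: adding hypoxia signal near a vessel
can only revoke, never confer, perfused status.

"Analyzable" nuclei are non-border, non-overlapping, with area in
[20, 400] µm² (excludes debris and merged nuclei; configurable via
`AnalyzableRule`). Within each distance category, `k` analyzable cells
(default 5) are drawn uniformly without replacement from a seeded generator;
with fewer than `k` candidates all are taken and flagged. The seed is
mandatory in the CLI and recorded in the output, making the historically
manual random choice reproducible.

## Focus detection

`detect_foci` implements a noise-tolerance maximum finder with exact
prominences: pixels are flooded from the brightest down (union-find over
plateau-collapsed nodes, 8-connectivity); a maximum dies where its component
first meets a component holding a higher maximum, and its prominence is its
height above that saddle. The highest maximum of a connected mask component
gets its height above the component minimum, so a flat nucleus yields no
foci. Plateaus (connected equal-valued pixels) yield one candidate at the
plateau centroid. Equal-valued maxima are totally ordered by
(intensity desc, centroid (y, x) asc); the later one of a tied pair dies
with zero prominence. The unit and acceptance suites verify this detector
against an independent superlevel-set enumeration on hundreds of random
integer-valued images, where plateaus and ties are common.

### Pipeline detection defaults and why they look the way they do

The section pipeline wraps the raw detector with three conventions, each
forced by the statistics of max-projected stacks and calibrated on the
phantom:

1. **Pre-smoothing, Gaussian σ = 0.7 px.** Single-pixel extremes of the
   projected noise field otherwise masquerade as foci. Sub-pixel smoothing
   suppresses them while broadening a Nyquist-sampled focus (σ ≈ 1 px) only
   ~20 %.
2. **Noise scale from the lower tail.** The per-nucleus noise σ is
   `(Q30 − Q10) / 0.7576` of the smoothed within-nucleus intensities
   (the divisor is the corresponding standard-normal quantile distance),
   computed on a mask eroded by `⌈2σ_smooth⌉+1` px. Foci only add *bright*
   pixels, so low quantiles stay on the background distribution even when
   foci cover a third of the nucleus — a median/MAD estimate inflates there
   and can triple the threshold, silently erasing counts exactly in the
   high-dose nuclei of interest. The erosion keeps the estimate clear of the
   rim, where smoothing bleeds in the darker extra-nuclear background.
3. **Prominence 3 σ plus a baseline filter at Q30 + 6 σ.** Two separate
   criteria, deliberately decoupled: the low prominence threshold keeps
   close focus pairs separable (their saddles are high, so their
   prominences are modest), while the baseline peak-height filter removes
   noise maxima — including the one per empty nucleus whose prominence
   (height above the nucleus minimum) no pure-prominence cut can reject.

With the phantom's default conditions (SNR 6 foci on a 17-slice max
projection) these defaults recover per-arm mean counts at planted rates
λ = 2/10/25 to within 2 %/1 %/8 %, with ~0.07 spurious foci per empty
nucleus. That residual false-positive rate is the price of keeping
λ = 25 nuclei within 10 %: raising the baseline filter by one σ halves the
false positives but drops dense-nucleus recovery below 90 %. Exact
per-nucleus agreement for well-separated foci is ~93–95 %, bounded by the
same trade-off. A user with brighter staining should simply pass
`--prominence` explicitly, which bypasses the per-nucleus estimate (the
baseline filter then uses the estimated background level with the same
factors).

Focus *size* has no agreed operator definition; ours is the connected
region above (peak − prominence) around the peak, clipped to the nucleus,
with contested pixels going to the nearest peak (ties to the brighter one).
It behaves monotonically in the true spot width and equals the plateau/disk
area in the obvious special cases, which is what the tests pin.

The **median mutual distance** is the median over all n(n−1)/2 pairwise
peak-to-peak distances in µm, reported as missing for n < 2.

### cfoci

`cfoci = Ā · n / A` with Ā the arithmetic mean nucleus area of the
(tumor × category) stratum. By default Ā is computed over the *enumerated*
nuclei of the stratum (only those were measured in the manual workflow);
`mean_area_scope="analyzable"` switches to all analyzable nuclei. An empty
stratum is an error, not a silent NaN.

## Marker-intensity classification

Thresholds derive from a reference population — the untreated arm of the
same staining batch, since exposure is constant only within a batch
(cross-batch classification is refused unless explicitly overridden):
`t_pos = median + 2·1.4826·MAD`; the sample's positive tail is split at its
50th and 90th percentiles into low/intermediate/high. Constant references
(zero spread) and references under 20 cells are rejected. Classification is
scale-invariant: multiplying intensities and thresholds by a common factor
leaves every count unchanged.

## The phantom

The generator produces, per ROI: a central perfused vessel (disk, radius
8 µm), pimonidazole positivity only beyond 50 µm (speckled), BrdU-positive
cells concentrated within 50 µm (and topped up to ≥ 12 so a sparse field
still qualifies), non-overlapping log-normal nuclei (median 140 µm²,
σ_log 0.25 — large, aneuploid-carcinoma-scale nuclei; a 2-D section must
physically hold up to ~40 resolvable foci), and per-nucleus focus counts
drawn from `Poisson(λ_ext + λ_emitter·e^{−d/τ})` at the true
centroid-to-vessel distance. A single exponential is the simplest shape
consistent with a one-scale crossfire gradient; the generator is a test
harness, not a dosimetry model.

Foci render as Gaussian spots (σ 0.325 µm = 1 px at the default
0.325 µm/px), each sharp in one random z-slice with a 0.4 µm axial
amplitude falloff, on a diffuse nuclear background of 80 counts with
Poisson shot noise and σ = 2 read noise; focus amplitude is SNR 6 × the
nuclear noise σ. Foci sit on the pixel grid with ≥ 1.3 µm pairwise spacing
(breaks closer than a chromatin-domain diameter are optically one focus);
crowded draws relax the spacing per point, never wholesale, so the realised
count always equals the Poisson draw. Between-tumor variability in
`generate_experiment` is a shared log-normal multiplier on both rate terms
(σ default 0.3), the random effect a mixed model would absorb.

What the phantom does **not** emulate — and therefore what passing tests do
not certify on real data: sub-pixel focus positions and genuinely
unresolvable focus pairs (real high-dose nuclei undercount), non-circular
and touching nuclei, intra-nucleus background texture (chromatin,
nucleoli), staining gradients across a section, autofluorescence with heavy
(log-normal) tails — the marker model uses a bounded background
(uniform 80–120 counts) against N(200, 20²) positives, so threshold
calibration on real stainings must be checked per batch — and any real
point-spread function or axial blooming. Segmentation on real DAPI will be
harder than on the phantom's clean disks; the pipeline accepts external
label masks for exactly that reason.

## Statistics and reporting

Transforms are √cfoci and natural-log area (the log base is recorded in the
table metadata). Summaries are per (arm, tumor, category): n, mean and SD of
counts, cfoci, transformed values, area and mutual distance; the SD of a
single observation is reported missing; rows are ordered lexicographically
by the grouping keys for byte-stable output. Inferential modeling
(mixed-effects, ANOVA with multiplicity correction) is intentionally out of
scope — the tables are the interface to external statistics software. The
built-in comparison is a two-sided difference-of-means permutation test with
the add-one estimator `p = (1 + #{|Δ*| ≥ |Δ|}) / (n_perm + 1)`; it is
seeded, matches exhaustive enumeration on small groups, holds its nominal
5 % level on null phantoms (a discreteness-induced slight conservatism is
expected with count data), and is a convenience, not a substitute for the
hierarchical model.

## Determinism

Every stochastic step — phantom generation, cell sampling, permutation —
takes an explicit seed, and the CLI requires one. Two runs with identical
inputs, configuration and seed produce byte-identical CSVs, YAML and TIFFs;
this is enforced by a test and re-measured by the acceptance script.

## Problem sizes used in validation

The acceptance checks run at: 200 random 64×64 masks (distance oracle),
500 random 32×32 integer images (prominence oracle), 10⁵ random triples
(cfoci algebra), 1000 random point sets (mutual distance), ~520 rendered
nuclei per arm at λ ∈ {2, 10, 25} (count recovery), ~2000 rendered nuclei
(decay-length recovery, 700² px fields), ~1000 placed nuclei
(category recovery, 768² px fields), ~1000 cells per arm (marker
fractions), 1000 null simulations × 500 permutations (type-I error), and
two full CLI runs (determinism). These sizes were chosen to bring each
Monte-Carlo standard error comfortably inside the corresponding tolerance.
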