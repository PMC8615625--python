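"""Synthetic tumor-section phantoms with ground truth.

The generator emulates the statistical structure the vessel-referenced
foci analysis assumes, so every pipeline stage can be verified without
real acquisitions:

* a single perfused vessel per ROI, with a pimonidazole-negative zone
  within 50 µm of it and BrdU-positive (proliferating) cells concentrated
  perivascularly;
* nuclei placed without overlap out to 250 µm from the vessel, with
  log-normal areas (scaled up under emitter arms);
* per-nucleus focus counts drawn from
  ``Poisson(lambda_ext + lambda_emitter · exp(−d/tau))`` where ``d`` is the
  true centroid-to-vessel distance — a baseline external-beam term plus an
  exponentially decaying radionuclide crossfire term;
* foci rendered as diffraction-limited Gaussian spots, each sharp in one
  z-slice of a 17-slice stack, on top of diffuse nuclear background with
  Poisson shot noise and Gaussian read noise.

Generation is bit-reproducible for a fixed seed.  The phantom is a test
harness with the right statistical shape, not a dosimetry or optics model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import assign_distance_category
from .io import BinaryMask, ZStack

__all__ = [
    "ArmConfig",
    "SectionGeometry",
    "NoiseParams",
    "PhantomSection",
    "generate_section",
    "generate_experiment",
    "simulate_foci_counts",
]


@dataclass
class ArmConfig:
    """Foci-rate and morphology parameters of one treatment arm.

    ``lambda_ext`` is the distance-independent mean foci per nucleus
    (external-beam component); ``lambda_emitter`` the additional mean at the
    vessel wall from the vessel-borne emitter, decaying with length scale
    ``tau_um``.  ``area_scale`` multiplies nucleus areas (≥ 1 under emitter
    arms, which enlarge nuclei); ``frac_pos_marker`` is the planted
    marker-positive cell fraction.
    """

    arm_id: str
    lambda_ext: float = 2.0
    lambda_emitter: float = 0.0
    tau_um: float = 50.0
    area_scale: float = 1.0
    frac_pos_marker: float = 0.03

    def __post_init__(self) -> None:
        if self.lambda_ext < 0 or self.lambda_emitter < 0:
            raise ValueError("foci rates must be non-negative")
        if not (self.tau_um > 0):
            raise ValueError("tau_um must be positive")
        if not (self.area_scale > 0):
            raise ValueError("area_scale must be positive")
        if not (0.0 <= self.frac_pos_marker <= 1.0):
            raise ValueError("frac_pos_marker must be in [0, 1]")

    def mean_foci(self, distance_um) -> np.ndarray:
        """Expected foci count at a vessel distance (µm)."""
        d = np.asarray(distance_um, dtype=float)
        return self.lambda_ext + self.lambda_emitter * np.exp(-d / self.tau_um)


@dataclass
class SectionGeometry:
    """Field geometry and morphology of one simulated ROI."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.325       # µm/px, typical 40x camera sampling
    n_slices: int = 17
    z_step: float = 0.25            # µm
    vessel_radius_um: float = 8.0
    max_distance_um: float = 250.0  # nuclei placed no farther from the vessel
    n_nuclei: int = 150
    nucleus_area_median_um2: float = 140.0
    nucleus_area_sigma_log: float = 0.25  # sigma of log-normal areas
    focus_sigma_um: float = 0.325   # in-plane Gaussian sigma of a focus
    focus_min_sep_um: float = 1.3   # megabase chromatin-domain scale
    defocus_sigma_um: float = 0.4   # axial falloff of focus amplitude


@dataclass
class NoiseParams:
    """Photon and camera noise of the rendered channels (counts)."""

    background: float = 20.0          # extracellular γH2AX background
    nucleus_background: float = 80.0  # diffuse nuclear γH2AX
    snr: float = 6.0                  # focus amplitude over nuclear noise sigma
    read_sigma: float = 2.0           # Gaussian read noise
    shot_noise: bool = True
    dapi_level: float = 400.0
    marker_neg_range: tuple[float, float] = (80.0, 120.0)  # bounded background
    marker_pos_mean: float = 200.0
    marker_pos_sigma: float = 20.0

    @property
    def nuclear_sigma(self) -> float:
        """Noise sigma on the diffuse nuclear background."""
        shot = self.nucleus_background if self.shot_noise else 0.0
        return float(np.sqrt(shot + self.read_sigma ** 2))

    @property
    def focus_amplitude(self) -> float:
        return self.snr * self.nuclear_sigma


@dataclass
class PhantomSection:
    """One rendered ROI: channels, label mask and per-nucleus ground truth."""

    gamma_h2ax: ZStack
    dapi: ZStack
    vessel: BinaryMask
    pimo: BinaryMask
    brdu: BinaryMask
    labels: np.ndarray            # int32, 0 = background
    truth: pd.DataFrame           # one row per nucleus
    arm: ArmConfig
    geometry: SectionGeometry
    noise: NoiseParams
    seed: int
    truth_foci: pd.DataFrame | None = None  # one row per planted focus


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, shape[0])
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sub = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = sub
    return out


def _place_nuclei(rng: np.random.Generator, geom: SectionGeometry, arm: ArmConfig,
                  dist_um: np.ndarray, vessel: np.ndarray) -> list[dict]:
    """Non-overlapping nucleus centers/radii, uniform over the allowed zone."""
    h, w = geom.shape
    mu = np.log(geom.nucleus_area_median_um2 * arm.area_scale)
    areas = rng.lognormal(mean=mu, sigma=geom.nucleus_area_sigma_log, size=geom.n_nuclei)
    radii_px = np.sqrt(areas / np.pi) / geom.pixel_size

    max_r = radii_px.max()
    allowed = (~vessel) & (dist_um <= geom.max_distance_um)
    # keep whole nuclei inside the frame and off the vessel lumen
    allowed[: int(max_r) + 1, :] = False
    allowed[-(int(max_r) + 1):, :] = False
    allowed[:, : int(max_r) + 1] = False
    allowed[:, -(int(max_r) + 1):] = False
    cand = np.flatnonzero(allowed)
    if cand.size == 0:
        raise ValueError("no room for nuclei: allowed placement zone is empty")

    placed: list[dict] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    attempts_per = 400
    for i in range(geom.n_nuclei):
        r = radii_px[i]
        ok = False
        for _ in range(attempts_per):
            pos = int(rng.choice(cand))
            cy, cx = divmod(pos, w)
            # jitter within the pixel for subpixel centers
            cy = cy + rng.uniform(-0.5, 0.5)
            cx = cx + rng.uniform(-0.5, 0.5)
            if centers.shape[0]:
                d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
                if np.any(d < radii + r + 1.0):
                    continue
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not place nucleus {i + 1}/{geom.n_nuclei} without overlap; "
                "reduce n_nuclei or enlarge the field"
            )
        centers = np.vstack([centers, [cy, cx]])
        radii = np.append(radii, r)
        placed.append({"cy": cy, "cx": cx, "r_px": r})
    return placed


def _place_foci(rng: np.random.Generator, n: int, r_px: float, min_sep_px: float
                ) -> np.ndarray:
    """Integer-pixel focus offsets (dy, dx) inside a nucleus disk.

    Foci sit on the pixel grid (truth positions are then exact pixel
    centers) and keep a minimum pairwise spacing — two breaks closer than a
    chromatin-domain diameter are one focus optically, so the generator
    does not plant unresolvable pairs.  The spacing is relaxed stepwise
    only if an unusually high count cannot be packed, so the realised count
    equals the Poisson draw.
    """
    if n == 0:
        return np.empty((0, 2))
    margin = min(2.0, 0.35 * r_px)
    r_eff = max(r_px - margin, 0.5)
    pts: list[tuple[float, float]] = []
    # per-point relaxation: only the overflow foci of a crowded nucleus are
    # allowed closer, never the whole set
    for sep in (min_sep_px, 0.75 * min_sep_px, 1.01):
        for _ in range(800 * n):
            if len(pts) == n:
                break
            ang = rng.uniform(0, 2 * np.pi)
            rad = r_eff * np.sqrt(rng.uniform())
            p = (round(rad * np.sin(ang)), round(rad * np.cos(ang)))
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= sep ** 2 for q in pts):
                pts.append(p)
        if len(pts) == n:
            break
    if not pts:
        return np.zeros((n, 2))
    while len(pts) < n:  # pathological overfill: duplicate (counts stay truthful)
        pts.append(pts[-1])
    return np.array(pts, dtype=float)


def _add_gaussian(plane: np.ndarray, cy: float, cx: float, sigma: float,
                  amplitude: float) -> None:
    if amplitude <= 0:
        return
    h, w = plane.shape
    r = int(np.ceil(4 * sigma))
    y0 = max(int(np.floor(cy)) - r, 0)
    y1 = min(int(np.ceil(cy)) + r + 1, h)
    x0 = max(int(np.floor(cx)) - r, 0)
    x1 = min(int(np.ceil(cx)) + r + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


def generate_section(arm: ArmConfig,
                     geometry: SectionGeometry | None = None,
                     noise: NoiseParams | None = None,
                     seed: int = 0,
                     render: bool = True) -> PhantomSection:
    """Generate one ROI: channels, label mask and per-nucleus truth.

    With ``render=False`` the image channels contain noiseless ideal
    intensity (no shot/read noise is drawn), which is faster and sufficient
    for geometry/bookkeeping tests; the truth table is identical either way.
    """
    geom = geometry or SectionGeometry()
    noi = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    h, w = geom.shape
    px = geom.pixel_size

    # --- vessel and distance geometry ---
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    vessel = _disk_mask(geom.shape, cy, cx, geom.vessel_radius_um / px)
    dist_um = ndimage.distance_transform_edt(~vessel) * px

    # --- microenvironment masks ---
    # pimonidazole stains hypoxic tissue beyond the oxygenated 50 µm cuff
    pimo = dist_um > 50.0
    # speckle it so it looks like staining, not a geometric ring
    pimo &= rng.random(geom.shape) < 0.6

    # --- nuclei ---
    placed = _place_nuclei(rng, geom, arm, dist_um, vessel)
    labels = np.zeros(geom.shape, dtype=np.int32)
    for i, nuc in enumerate(placed, start=1):
        m = _disk_mask(geom.shape, nuc["cy"], nuc["cx"], nuc["r_px"])
        labels[m] = i
        nuc["label"] = i
        nuc["area_px"] = int(m.sum())

    # BrdU-positive cells cluster perivascularly (S-phase cells near oxygen)
    brdu = np.zeros(geom.shape, dtype=bool)
    n_brdu_seeds = 0
    for nuc in placed:
        d = float(dist_um[int(round(nuc["cy"])), int(round(nuc["cx"]))])
        p = 0.8 if d <= 50.0 else 0.05
        if rng.random() < p:
            brdu |= _disk_mask(geom.shape, nuc["cy"], nuc["cx"], 0.6 * nuc["r_px"])
            if d <= 50.0:
                n_brdu_seeds += 1
    # guarantee a BrdU-positive surround even in sparse fields
    near_px = np.flatnonzero((dist_um <= 45.0) & ~vessel)
    while n_brdu_seeds < 12 and near_px.size:
        pos = int(rng.choice(near_px))
        by, bx = divmod(pos, w)
        brdu |= _disk_mask(geom.shape, by, bx, 3.0 / px)
        n_brdu_seeds += 1

    # --- per-nucleus truth draws ---
    rows = []
    foci_world: list[tuple[float, float, int]] = []  # (y, x, nucleus label)
    for nuc in placed:
        d = float(dist_um[int(round(nuc["cy"])), int(round(nuc["cx"]))])
        lam = float(arm.mean_foci(d))
        n_foci = int(rng.poisson(lam))
        offsets = _place_foci(rng, n_foci, nuc["r_px"], geom.focus_min_sep_um / px)
        base_y, base_x = round(nuc["cy"]), round(nuc["cx"])  # keep foci on the grid
        for dy, dx in offsets:
            foci_world.append((base_y + dy, base_x + dx, nuc["label"]))
        marker_pos = bool(rng.random() < arm.frac_pos_marker)
        if marker_pos:
            intensity = float(rng.normal(noi.marker_pos_mean, noi.marker_pos_sigma))
        else:
            intensity = float(rng.uniform(*noi.marker_neg_range))
        rows.append({
            "nucleus_id": nuc["label"],
            "center_y_px": nuc["cy"],
            "center_x_px": nuc["cx"],
            "area_um2": nuc["area_px"] * px ** 2,
            "distance_um": d,
            "category": assign_distance_category(d),
            "n_foci": n_foci,
            "marker_positive": marker_pos,
            "marker_intensity": intensity,
            "arm_id": arm.arm_id,
        })
    truth = pd.DataFrame(rows)

    # --- render channels ---
    gamma_ideal = np.full(geom.shape, noi.background, dtype=float)
    gamma_ideal[labels > 0] = noi.nucleus_background
    gstack = np.repeat(gamma_ideal[None, :, :], geom.n_slices, axis=0)
    amp = noi.focus_amplitude
    sig_px = geom.focus_sigma_um / px
    for fy, fx, _lab in foci_world:
        z0 = int(rng.integers(0, geom.n_slices))
        for z in range(geom.n_slices):
            fall = np.exp(-0.5 * ((z - z0) * geom.z_step / geom.defocus_sigma_um) ** 2)
            if fall < 0.02:
                continue
            _add_gaussian(gstack[z], fy, fx, sig_px, amp * fall)

    dapi_plane = np.full(geom.shape, noi.background, dtype=float)
    dapi_plane[labels > 0] = noi.dapi_level
    dapi_plane = ndimage.gaussian_filter(dapi_plane, sigma=1.0)
    dstack = np.repeat(dapi_plane[None, :, :], geom.n_slices, axis=0)

    if render:
        if noi.shot_noise:
            gstack = rng.poisson(gstack).astype(float)
            dstack = rng.poisson(dstack).astype(float)
        gstack = np.clip(gstack + rng.normal(0, noi.read_sigma, gstack.shape), 0, None)
        dstack = np.clip(dstack + rng.normal(0, noi.read_sigma, dstack.shape), 0, None)

    return PhantomSection(
        gamma_h2ax=ZStack(gstack, z_step=geom.z_step, pixel_size=px, channel_name="gamma_h2ax"),
        dapi=ZStack(dstack, z_step=geom.z_step, pixel_size=px, channel_name="dapi"),
        vessel=BinaryMask(vessel, pixel_size=px, semantics="vessel_perfused"),
        pimo=BinaryMask(pimo, pixel_size=px, semantics="pimonidazole_pos"),
        brdu=BinaryMask(brdu, pixel_size=px, semantics="brdu_pos"),
        labels=labels,
        truth=truth,
        truth_foci=pd.DataFrame(foci_world, columns=["y_px", "x_px", "nucleus_id"]),
        arm=arm,
        geometry=geom,
        noise=noi,
        seed=seed,
    )


def generate_experiment(arms: list[ArmConfig],
                        n_tumors_per_arm: int,
                        n_rois: int,
                        seed: int = 0,
                        geometry: SectionGeometry | None = None,
                        noise: NoiseParams | None = None,
                        sigma_tumor: float = 0.3,
                        render: bool = True) -> tuple[list[dict], pd.DataFrame]:
    """A hierarchical experiment: arm → tumor → ROI sections with truth.

    Between-tumor variability is a shared log-normal multiplier (sigma of
    log = ``sigma_tumor``) applied to both foci-rate components of the
    tumor's arm, emulating the tumor-level random effect a mixed-effects
    analysis would absorb.  Returns (packets, truth): one packet dict per
    ROI (`arm_id`, `tumor_id`, `roi_id`, `section`) and the concatenated
    per-nucleus truth table.
    """
    if n_tumors_per_arm < 1:
        raise ValueError("n_tumors_per_arm must be >= 1")
    master = np.random.default_rng(seed)
    packets: list[dict] = []
    tables = []
    for arm in arms:
        for t in range(n_tumors_per_arm):
            tumor_id = f"{arm.arm_id}-T{t + 1}"
            mult = float(np.exp(master.normal(0.0, sigma_tumor))) if sigma_tumor > 0 else 1.0
            tumor_arm = ArmConfig(
                arm_id=arm.arm_id,
                lambda_ext=arm.lambda_ext * mult,
                lambda_emitter=arm.lambda_emitter * mult,
                tau_um=arm.tau_um,
                area_scale=arm.area_scale,
                frac_pos_marker=arm.frac_pos_marker,
            )
            for r in range(n_rois):
                roi_seed = int(master.integers(0, 2 ** 31 - 1))
                section = generate_section(tumor_arm, geometry, noise,
                                           seed=roi_seed, render=render)
                truth = section.truth.copy()
                truth.insert(0, "roi_id", r + 1)
                truth.insert(0, "tumor_id", tumor_id)
                packets.append({"arm_id": arm.arm_id, "tumor_id": tumor_id,
                                "roi_id": r + 1, "section": section})
                tables.append(truth)
    return packets, pd.concat(tables, ignore_index=True)


def simulate_foci_counts(arm: ArmConfig, n_nuclei: int, seed: int = 0,
                         max_distance_um: float = 250.0) -> pd.DataFrame:
    """Truth-level per-nucleus counts without rendering any image.

    Distances are drawn with density proportional to radius (area-weighted
    around a point-like vessel), counts from the arm's Poisson model.  Used
    for statistical calibration runs where imaging is irrelevant.
    """
    rng = np.random.default_rng(seed)
    d = max_distance_um * np.sqrt(rng.uniform(size=n_nuclei))
    lam = arm.mean_foci(d)
    counts = rng.poisson(lam)
    return pd.DataFrame({
        "distance_um": d,
        "category": [assign_distance_category(x) for x in d],
        "n_foci": counts,
        "arm_id": arm.arm_id,
    })
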