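"""Digital mouse-thorax projection phantoms and transplant-cohort sampling.

The phantom stands in for the animals of a single-left-lung transplantation
study imaged with a Talbot-Lau interferometer.  It provides, on one pixel
grid, the three ground-truth maps the forward model consumes (transmission,
dark-field extinction, fringe-phase shift) together with labelled anatomy:

* an elliptical thorax with spine column and curved rib bands (high
  absorption, no small-angle scattering),
* two lung fields whose parenchyma carries the calibrated absorption and
  dark-field signals (healthy aerated lung scatters strongly at alveolar
  walls, hence a high dark-field signal),
* trachea and both main bronchi as air-filled tubes whose walls imprint the
  bipolar edge signature in the differential-phase map,
* a cuff marker on the left main bronchus (the transplant anastomosis), and
* the large-airway pathologies of interest: stenosis at the cuff, truncation
  distal to the cuff, and left-sided pneumothorax.

Signal calibration is the closed-form inverse of the retrieval definitions:
an absorption target ``A`` and dark-field target ``D`` are realised by
``transmission = exp(-A)`` and ``extinction = D``, so a noiseless forward
simulation followed by retrieval returns the targets exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import expit

__all__ = [
    "PhantomMaps",
    "PathologySpec",
    "CohortParams",
    "AnimalRecord",
    "GeometryParams",
    "HEALTHY_LUNG",
    "AIRLESS_TISSUE",
    "calibrate_parenchyma",
    "severity_from_darkfield",
    "targets_from_severity",
    "build_thorax_phantom",
    "make_tube_phantom",
    "sample_cohort",
    "sample_longitudinal_subgroup",
    "cohort_manifest",
    "tp1_preset",
    "tp2_subgroup_presets",
]

# Calibration endpoints (absorption, dark-field) of the parenchyma model.
# Healthy aerated lung uses the control-lung cohort means at the first time
# point; airless (fully atelectatic) tissue is the opposite endpoint of the
# severity interpolation.
HEALTHY_LUNG = (0.788, 1.475)
AIRLESS_TISSUE = (1.05, 0.10)

SOFT_TISSUE_ABSORPTION = 1.25
BONE_ABSORPTION = 2.5
CUFF_ABSORPTION = 2.2
PNEUMOTHORAX_ABSORPTION = 0.05

_LABELS = ("body", "left_lung", "right_lung", "bone", "bronchus_left", "bronchus_right", "cuff")


@dataclass(frozen=True)
class PathologySpec:
    """Large-airway pathology of the transplanted (left) lung.

    ``atelectasis_severity`` scales the dependent parenchyma from healthy
    aerated lung (0) toward airless tissue (1).  ``stenosis_fraction`` is the
    remaining fraction of lumen diameter at the cuff and is defined only for
    ``kind='stenosis'``; ``distal_diameter_mm`` is the calibre of the bronchus
    distal to the cuff.
    """

    kind: str = "none"  # none | stenosis | truncation | pneumothorax
    stenosis_fraction: float | None = None
    atelectasis_severity: float = 0.0
    distal_diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "stenosis", "truncation", "pneumothorax"):
            raise ValueError(f"unknown pathology kind {self.kind!r}")
        if self.kind == "stenosis":
            if self.stenosis_fraction is None or not (0.0 < self.stenosis_fraction < 1.0):
                raise ValueError("stenosis requires stenosis_fraction in (0, 1)")
        elif self.stenosis_fraction is not None:
            raise ValueError("stenosis_fraction is defined only for kind='stenosis'")
        if not (0.0 <= self.atelectasis_severity <= 1.0):
            raise ValueError("atelectasis_severity must lie in [0, 1]")
        if self.distal_diameter_mm <= 0:
            raise ValueError("distal_diameter_mm must be positive")


@dataclass(frozen=True)
class GeometryParams:
    """Raster and anatomical layout of the thorax projection.

    All landmark coordinates are expressed on a 512 x 512 reference raster and
    scaled to ``shape``; physical calibres are given in millimetres and
    converted through ``pixel_size_um``.  The default raster (512 px at 29 um)
    covers a ~15 mm field of view.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 29.0
    proximal_diameter_mm: float = 1.0
    edge_softness_px: float = 1.5
    phase_edge_amplitude: float = 0.8  # rad, peak for an x-normal tube wall
    airway_absorption_drop: float = 0.8
    texture_rel_amplitude: float = 0.10
    texture_scale_px: float = 12.0
    cuff_halfwindow_px: float = 14.0
    edge_cutoff_px: float = 12.0

    def __post_init__(self) -> None:
        if min(self.shape) < 32 or self.pixel_size_um <= 0:
            raise ValueError("invalid raster")
        if self.proximal_diameter_mm <= 0:
            raise ValueError("proximal_diameter_mm must be positive")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0


@dataclass
class PhantomMaps:
    """Ground-truth per-pixel maps and labelled anatomy of one projection."""

    transmission_map: np.ndarray
    extinction_map: np.ndarray
    phase_map: np.ndarray
    pixel_size_um: float
    anatomy_masks: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.transmission_map.shape, self.extinction_map.shape, self.phase_map.shape}
        shapes |= {m.shape for m in self.anatomy_masks.values()}
        if len(shapes) != 1:
            raise ValueError("all maps and masks must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.transmission_map <= 0) or np.any(self.transmission_map > 1):
            raise ValueError("transmission map must lie in (0, 1]")
        if np.any(self.extinction_map < 0):
            raise ValueError("extinction map must be non-negative")
        lungs = self.anatomy_masks.get("left_lung", False) | self.anatomy_masks.get("right_lung", False)
        if np.any(lungs & self.anatomy_masks.get("bone", False)):
            raise ValueError("lung masks must be disjoint from the bone mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission_map.shape


def calibrate_parenchyma(target_absorption: float, target_darkfield: float) -> tuple[float, float]:
    """Invert the retrieval definitions: signal targets -> physical maps.

    Returns ``(transmission, extinction)`` such that a noiseless forward
    simulation followed by retrieval reproduces the targets exactly.
    """
    if target_absorption < 0 or target_darkfield < 0:
        raise ValueError("signal targets must be non-negative")
    return float(np.exp(-target_absorption)), float(target_darkfield)


def severity_from_darkfield(darkfield_target: float) -> float:
    """Atelectasis severity implied by a dark-field target.

    Linear position of the target between the healthy-lung and
    airless-tissue calibration endpoints, clipped to [0, 1].
    """
    lo, hi = AIRLESS_TISSUE[1], HEALTHY_LUNG[1]
    return float(np.clip((hi - darkfield_target) / (hi - lo), 0.0, 1.0))


def targets_from_severity(severity: float) -> tuple[float, float]:
    """(absorption, dark-field) targets interpolated by atelectasis severity."""
    a = HEALTHY_LUNG[0] + severity * (AIRLESS_TISSUE[0] - HEALTHY_LUNG[0])
    d = HEALTHY_LUNG[1] + severity * (AIRLESS_TISSUE[1] - HEALTHY_LUNG[1])
    return float(a), float(d)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _resample_centerline(points: np.ndarray, spacing: float):
    """Cubic-spline centerline through control points, ~arclength sampled."""
    pts = np.asarray(points, dtype=np.float64)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    cs_y = CubicSpline(chord, pts[:, 0])
    cs_x = CubicSpline(chord, pts[:, 1])
    u = np.arange(0.0, chord[-1], 0.25)
    dense = np.column_stack([cs_y(u), cs_x(u)])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, s_dense[-1], spacing)
    cl = np.column_stack([np.interp(s, s_dense, dense[:, 0]), np.interp(s, s_dense, dense[:, 1])])
    return cl, s, chord


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _render_tube(shape, centerline, radii, softness, cutoff):
    """Soft tube indicator ``g``, hard lumen mask, and affected region.

    ``g`` is a logistic profile of the distance to the centerline,
    ``expit((r - dist)/softness)``, truncated to zero beyond
    ``dist > r + cutoff`` so the tube's footprint has strictly bounded
    support (ROI masks exclude it exactly).
    """
    H, W = shape
    g = np.zeros(shape)
    lumen = np.zeros(shape, dtype=bool)
    region = np.zeros(shape, dtype=bool)
    keep = radii > 0
    if not np.any(keep):
        return g, lumen, region
    cl = centerline[keep]
    r = radii[keep]
    pad = float(r.max() + cutoff + 2.0)
    y0 = max(int(np.floor(cl[:, 0].min() - pad)), 0)
    y1 = min(int(np.ceil(cl[:, 0].max() + pad)) + 1, H)
    x0 = max(int(np.floor(cl[:, 1].min() - pad)), 0)
    x1 = min(int(np.ceil(cl[:, 1].max() + pad)) + 1, W)
    if y0 >= y1 or x0 >= x1:
        return g, lumen, region
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    dist, idx = cKDTree(cl).query(pts, k=1)
    r_near = r[idx]
    gs = expit((r_near - dist) / softness)
    inside = dist <= (r_near + cutoff)
    gs[~inside] = 0.0
    g[y0:y1, x0:x1] = gs.reshape(yy.shape)
    lumen[y0:y1, x0:x1] = (dist <= r_near).reshape(yy.shape)
    region[y0:y1, x0:x1] = inside.reshape(yy.shape)
    return g, lumen, region


def _lumen_radius_profile(s, s_cuff, r_prox, r_dist, pathology: PathologySpec, halfwin, pixel_size_mm):
    """Lumen radius (px) along arclength, with pathology applied at the cuff."""
    r = np.full_like(s, r_prox)
    # calibre transition distal to the cuff
    trans = 20.0
    post = s > s_cuff
    r[post] = r_prox + (r_dist - r_prox) * _smoothstep((s[post] - s_cuff) / trans)
    if pathology.kind == "stenosis":
        f = pathology.stenosis_fraction
        d = np.abs(s - s_cuff)
        win = d < halfwin
        dip = f + (1.0 - f) * 0.5 * (1.0 - np.cos(np.pi * d[win] / halfwin))
        r[win] = r[win] * dip
        if 2.0 * f * r_prox < 2.0:
            raise ValueError(
                "stenosis not renderable: residual lumen "
                f"{2 * f * r_prox * pixel_size_mm:.3f} mm spans < 2 pixels at this resolution"
            )
    elif pathology.kind == "truncation":
        taper = np.clip((s_cuff - s) / halfwin, 0.0, 1.0)
        r = r_prox * np.sqrt(taper)
    if np.any((r > 0) & (r * 2.0 < 2.0)) and pathology.kind == "stenosis":
        raise ValueError("lumen narrower than 2 pixels; raise the resolution")
    return r


def _standardized_texture(rng, shape, sigma, mask):
    """Smooth random field with exactly zero mean / unit SD over ``mask``."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    vals = f[mask]
    if vals.size < 2 or vals.std() == 0:
        return np.zeros(shape)
    return (f - vals.mean()) / vals.std()


# ---------------------------------------------------------------------------
# thorax phantom
# ---------------------------------------------------------------------------

def build_thorax_phantom(
    geometry: GeometryParams,
    pathology: PathologySpec,
    seed: int,
    lung_targets: dict | None = None,
) -> PhantomMaps:
    """Render one thorax projection phantom.

    ``lung_targets`` maps ``'left'``/``'right'`` (anatomical; the left lung is
    the transplanted one) to ``(absorption, darkfield)`` signal targets.  When
    omitted, the right lung uses the healthy calibration and the left lung the
    severity interpolation of ``pathology.atelectasis_severity``.  Images are
    stored supine with the anatomical left lung on the viewer's right; x is
    the grating-stepping direction.
    """
    H, W = geometry.shape
    sy, sx = H / 512.0, W / 512.0
    sc = 0.5 * (sy + sx)
    rng = np.random.default_rng(seed)
    px_mm = geometry.pixel_size_mm

    if lung_targets is None:
        lung_targets = {
            "left": targets_from_severity(pathology.atelectasis_severity),
            "right": HEALTHY_LUNG,
        }
    for lung in ("left", "right"):
        a, d = lung_targets[lung]
        calibrate_parenchyma(a, d)  # validates non-negativity

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    def P(y, x):  # reference-raster point -> actual raster
        return (y * sy, x * sx)

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy * sy) / (ry * sy)) ** 2 + ((xx - cx * sx) / (rx * sx)) ** 2 <= 1.0

    body = ellipse(256, 256, 250, 245)
    spine = body & (np.abs(xx - 256 * sx) <= 12 * sx)
    rib_y = yy - 0.0005 * (xx - 256 * sx) ** 2 / sx
    ribs = np.zeros_like(body)
    for yc in np.arange(68, 432, 44):
        ribs |= np.abs(rib_y - yc * sy) <= 6 * sy
    ribs &= body
    bone = spine | ribs

    mediastinum = np.abs(xx - 256 * sx) <= 42 * sx
    lung_l_raw = ellipse(250, 368, 135, 78) & body & ~mediastinum
    lung_r_raw = ellipse(250, 144, 135, 78) & body & ~mediastinum

    # --- airways ---------------------------------------------------------
    r_prox = 0.5 * geometry.proximal_diameter_mm / px_mm
    r_dist = 0.5 * pathology.distal_diameter_mm / px_mm
    halfwin = geometry.cuff_halfwindow_px * sc
    soft = geometry.edge_softness_px
    cutoff = geometry.edge_cutoff_px

    left_pts = np.array([P(148, 256), P(190, 298), P(232, 330), P(292, 345), P(368, 350)])
    right_pts = np.array([P(148, 256), P(190, 214), P(232, 182), P(292, 167), P(368, 162)])
    trachea_pts = np.array([P(64, 256), P(148, 256)])

    cl_l, s_l, chord_l = _resample_centerline(left_pts, spacing=0.75)
    cl_r, s_r, _ = _resample_centerline(right_pts, spacing=0.75)
    cl_t = np.column_stack([
        np.linspace(trachea_pts[0, 0], trachea_pts[1, 0], 120),
        np.linspace(trachea_pts[0, 1], trachea_pts[1, 1], 120),
    ])

    s_cuff = chord_l[2]
    cuff_xy = cl_l[np.argmin(np.abs(s_l - s_cuff))]

    r_left = _lumen_radius_profile(s_l, s_cuff, r_prox, r_dist, pathology, halfwin, px_mm)
    if pathology.kind == "truncation":
        keep = s_l < s_cuff
        cl_left, r_left_kept = cl_l[keep], r_left[keep]
    else:
        cl_left, r_left_kept = cl_l, r_left
    r_right = np.full(len(cl_r), r_prox)
    r_tr = np.full(len(cl_t), r_prox)

    g_l, lumen_l, region_l = _render_tube((H, W), cl_left, r_left_kept, soft, cutoff)
    g_r, lumen_r, region_r = _render_tube((H, W), cl_r, r_right, soft, cutoff)
    g_t, lumen_t, region_t = _render_tube((H, W), cl_t, r_tr, soft, cutoff)
    g_total = np.maximum(np.maximum(g_l, g_r), g_t)
    airway_region = region_l | region_r | region_t

    # cuff marker: two dense blobs flanking the lumen at the anastomosis
    tangent = cl_l[min(len(cl_l) - 1, np.argmin(np.abs(s_l - s_cuff)) + 4)] - \
        cl_l[max(0, np.argmin(np.abs(s_l - s_cuff)) - 4)]
    tangent = tangent / np.linalg.norm(tangent)
    normal = np.array([-tangent[1], tangent[0]])
    cuff = np.zeros((H, W), dtype=bool)
    for sign in (-1.0, 1.0):
        c = cuff_xy + sign * (r_prox + 6.0 * sc) * normal
        cuff |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= (4.0 * sc) ** 2

    # --- labelled anatomy ------------------------------------------------
    excl = binary_dilation(airway_region | cuff, iterations=1)
    left_lung = lung_l_raw & ~bone & ~excl
    right_lung = lung_r_raw & ~bone & ~excl
    # bone label excludes the airway footprint: in projection an air lumen in
    # front of spine or rib dominates the pixel, which is rendered as airway
    bone_label = bone & body & (g_total < 0.15)
    masks = {
        "body": body,
        "left_lung": left_lung,
        "right_lung": right_lung,
        "bone": bone_label,
        "bronchus_left": lumen_l,
        "bronchus_right": lumen_r,
        "cuff": cuff,
    }

    # --- signal maps ------------------------------------------------------
    A_l, D_l = lung_targets["left"]
    A_r, D_r = lung_targets["right"]
    tex_sigma = geometry.texture_scale_px * sc
    amp = geometry.texture_rel_amplitude
    fA_l = _standardized_texture(rng, (H, W), tex_sigma, left_lung)
    fD_l = _standardized_texture(rng, (H, W), tex_sigma, left_lung)
    fA_r = _standardized_texture(rng, (H, W), tex_sigma, right_lung)
    fD_r = _standardized_texture(rng, (H, W), tex_sigma, right_lung)

    A = np.zeros((H, W))
    A[body] = SOFT_TISSUE_ABSORPTION
    A[lung_l_raw] = A_l * (1.0 + amp * fA_l[lung_l_raw])
    A[lung_r_raw] = A_r * (1.0 + amp * fA_r[lung_r_raw])

    D = np.zeros((H, W))
    D[lung_l_raw] = D_l * (1.0 + amp * fD_l[lung_l_raw])
    D[lung_r_raw] = D_r * (1.0 + amp * fD_r[lung_r_raw])

    if pathology.kind == "pneumothorax":
        # air fills the left pleural space: hyper-transparent, no scatter
        hemi = body & (xx > 256 * sx + 42 * sx)
        A[hemi] = PNEUMOTHORAX_ABSORPTION
        D[hemi] = 0.0

    A[masks["bone"]] = BONE_ABSORPTION
    D[masks["bone"]] = 0.0
    A *= 1.0 - geometry.airway_absorption_drop * g_total
    D *= 1.0 - g_total
    A[cuff] = CUFF_ABSORPTION
    D[cuff] = 0.0
    D = np.clip(D, 0.0, None)

    phase = geometry.phase_edge_amplitude * 4.0 * soft * np.gradient(g_total, axis=1)

    seed_idx = int(np.argmin(np.abs(s_l - 0.4 * s_cuff)))
    seed_tangent = cl_l[min(seed_idx + 4, len(cl_l) - 1)] - cl_l[max(seed_idx - 4, 0)]
    seed_tangent = seed_tangent / np.linalg.norm(seed_tangent)

    meta = {
        "pathology": pathology,
        "lung_targets": {k: tuple(map(float, v)) for k, v in lung_targets.items()},
        "centerline_left": cl_l,
        "arclength_left": s_l,
        "radius_left_px": r_left,
        "cuff_arclength": float(s_cuff),
        "cuff_xy": tuple(map(float, cuff_xy)),
        "seed_point": tuple(map(float, cl_l[seed_idx])),
        "seed_direction": tuple(map(float, seed_tangent)),
        "proximal_diameter_mm": geometry.proximal_diameter_mm,
    }

    return PhantomMaps(
        transmission_map=np.exp(-A),
        extinction_map=D,
        phase_map=phase,
        pixel_size_um=geometry.pixel_size_um,
        anatomy_masks=masks,
        meta=meta,
    )


def make_tube_phantom(
    diameter_mm: float,
    *,
    shape: tuple[int, int] = (240, 160),
    pixel_size_um: float = 29.0,
    angle_deg: float = 4.0,
    background_absorption: float = 1.0,
    edge_softness_px: float = 1.5,
    phase_edge_amplitude: float = 0.8,
) -> PhantomMaps:
    """Straight air-filled tube in soft tissue — a metrology phantom.

    Used to validate lumen-diameter measurement: the differential-phase
    cross-profile of the tube shows one positive and one negative edge
    extremum whose separation equals the lumen diameter.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    H, W = shape
    px_mm = pixel_size_um / 1000.0
    r = 0.5 * diameter_mm / px_mm
    if 2.0 * r < 2.0:
        raise ValueError("lumen spans fewer than 2 pixels at this resolution")
    t = np.tan(np.deg2rad(angle_deg))
    y = np.arange(-4.0, H + 4.0, 0.75)
    x = W / 2.0 + (y - H / 2.0) * t
    cl = np.column_stack([y, x])
    g, lumen, region = _render_tube((H, W), cl, np.full(len(cl), r), edge_softness_px, 8.0 * edge_softness_px)
    A = np.full((H, W), background_absorption) * (1.0 - 0.8 * g)
    phase = phase_edge_amplitude * 4.0 * edge_softness_px * np.gradient(g, axis=1)
    masks = {"body": np.ones((H, W), dtype=bool), "left_lung": np.zeros((H, W), bool),
             "right_lung": np.zeros((H, W), bool), "bone": np.zeros((H, W), bool),
             "bronchus_left": lumen, "bronchus_right": np.zeros((H, W), bool),
             "cuff": np.zeros((H, W), bool)}
    mid = len(cl) // 2
    tangent = cl[mid + 4] - cl[mid - 4]
    tangent = tangent / np.linalg.norm(tangent)
    meta = {
        "diameter_mm": float(diameter_mm),
        "centerline_left": cl,
        "seed_point": tuple(map(float, cl[len(cl) // 4])),
        "seed_direction": tuple(map(float, tangent)),
    }
    return PhantomMaps(
        transmission_map=np.exp(-A),
        extinction_map=np.zeros((H, W)),
        phase_map=phase,
        pixel_size_um=pixel_size_um,
        anatomy_masks=masks,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Calibration of one imaging time point of the transplant cohort.

    Signal parameters are ``(mean, sd)`` pairs of the per-animal lung-wide
    ROI targets; counts fix how many animals carry each pathology or
    exclusion.  ``analysable`` animals are those without pneumothorax or
    death.
    """

    n_recipients: int
    transplanted_absorption: tuple[float, float]
    transplanted_darkfield: tuple[float, float]
    control_absorption: tuple[float, float]
    control_darkfield: tuple[float, float]
    n_pneumothorax: int = 0
    n_death: int = 0
    n_stenosis: int = 0
    n_truncation: int = 0
    n_decreased_ventilation: int = 0
    n_improved_tp2: int = 0
    n_resolved_tp2: int = 0
    timepoint: str = "TP1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transplanted_absorption", "transplanted_darkfield",
                     "control_absorption", "control_darkfield"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
        if self.timepoint not in ("TP1", "TP2"):
            raise ValueError("timepoint must be 'TP1' or 'TP2'")
        if self.n_pneumothorax + self.n_death > self.n_recipients:
            raise ValueError("exclusion counts exceed cohort size")
        analysable = self.n_analysable
        if self.n_stenosis + self.n_truncation > self.n_decreased_ventilation:
            raise ValueError("airway-pathology counts exceed decreased-ventilation count")
        if self.n_decreased_ventilation > analysable:
            raise ValueError("decreased-ventilation count exceeds analysable animals")

    @property
    def n_analysable(self) -> int:
        return self.n_recipients - self.n_pneumothorax - self.n_death


def tp1_preset(seed: int = 0) -> CohortParams:
    """The 51-recipient cohort at the first time point (shortly post-op)."""
    return CohortParams(
        n_recipients=51,
        transplanted_absorption=(0.943, 0.078),
        transplanted_darkfield=(0.681, 0.215),
        control_absorption=(0.788, 0.069),
        control_darkfield=(1.475, 0.184),
        n_pneumothorax=4,
        n_death=1,
        n_stenosis=4,
        n_truncation=10,
        n_decreased_ventilation=24,
        timepoint="TP1",
        seed=seed,
    )


def tp2_subgroup_presets(seed: int = 0) -> tuple[CohortParams, CohortParams]:
    """The rescanned 27-animal subgroup: (its TP1 calibration, its TP2 one).

    The subgroup's own TP1 distributions differ slightly from the full-cohort
    ones; pathology counts at TP1 are a proportional share of the cohort's
    4 stenosis / 10 truncation / 24 decreased-ventilation animals.  At TP2,
    8 animals improve their ventilation and 6 of those show resolving
    bronchial irregularities.  The transplanted-lung TP2 absorption mean is
    set slightly below TP1 (a non-significant decrease).
    """
    tp1 = CohortParams(
        n_recipients=27,
        transplanted_absorption=(0.943, 0.078),
        transplanted_darkfield=(0.656, 0.234),
        control_absorption=(0.789, 0.075),
        control_darkfield=(1.507, 0.168),
        n_stenosis=2,
        n_truncation=6,
        n_decreased_ventilation=14,
        timepoint="TP1",
        seed=seed,
    )
    tp2 = CohortParams(
        n_recipients=27,
        transplanted_absorption=(0.927, 0.080),
        transplanted_darkfield=(0.722, 0.251),
        control_absorption=(0.836, 0.067),
        control_darkfield=(1.442, 0.263),
        n_improved_tp2=8,
        n_resolved_tp2=6,
        timepoint="TP2",
        seed=seed,
    )
    return tp1, tp2


@dataclass
class AnimalRecord:
    """One recipient animal across the imaging time points."""

    animal_id: str
    pathology: dict  # timepoint -> PathologySpec
    excluded_reason: str = "none"  # none | pneumothorax | death
    decreased_ventilation: bool = False
    targets: dict = field(default_factory=dict)  # tp -> {"transplanted": (A,D), "control": (A,D)}
    severity: dict = field(default_factory=dict)  # tp -> float
    seed: int = 0
    # filled by the pipeline
    phantoms: dict = field(default_factory=dict)
    modalities: dict = field(default_factory=dict)
    roi_means: dict = field(default_factory=dict)
    bronchus_call: dict = field(default_factory=dict)
    pneumothorax_detected: dict = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return self.excluded_reason != "none"


def _draw_targets(rng, params: CohortParams, n: int):
    """Per-animal (absorption, darkfield) target draws, floored above zero."""
    out = {}
    for arm, (akey, dkey) in {
        "transplanted": ("transplanted_absorption", "transplanted_darkfield"),
        "control": ("control_absorption", "control_darkfield"),
    }.items():
        am, asd = getattr(params, akey)
        dm, dsd = getattr(params, dkey)
        a = np.clip(rng.normal(am, asd, size=n), 0.02, None)
        d = np.clip(rng.normal(dm, dsd, size=n), 0.02, None)
        out[arm] = (a, d)
    return out


def _assign_pathologies(records: list[AnimalRecord], params: CohortParams, rng, timepoint: str) -> None:
    """Rank analysable animals by severity and hand out airway pathologies.

    Truncation goes to the most severe (near-airless) transplanted lungs,
    stenosis to the next tier, matching the observation that truncated
    bronchi come with (sub)total atelectasis while stenotic ones show
    constrained but present ventilation.
    """
    analysable = [r for r in records if not r.excluded]
    order = sorted(analysable, key=lambda r: -r.severity[timepoint])
    k = 0
    for r in order[:params.n_truncation]:
        r.pathology[timepoint] = PathologySpec(kind="truncation", atelectasis_severity=1.0)
        r.decreased_ventilation = True
    k += params.n_truncation
    for r in order[k:k + params.n_stenosis]:
        r.pathology[timepoint] = PathologySpec(
            kind="stenosis",
            stenosis_fraction=float(rng.uniform(0.3, 0.5)),
            atelectasis_severity=r.severity[timepoint],
            distal_diameter_mm=float(rng.uniform(1.1, 1.5)),
        )
        r.decreased_ventilation = True
    k += params.n_stenosis
    for r in order[k:params.n_decreased_ventilation]:
        r.pathology[timepoint] = PathologySpec(kind="none", atelectasis_severity=r.severity[timepoint])
        r.decreased_ventilation = True
    for r in order[params.n_decreased_ventilation:]:
        r.pathology[timepoint] = PathologySpec(kind="none", atelectasis_severity=r.severity[timepoint])


def sample_cohort(params: CohortParams) -> list[AnimalRecord]:
    """Draw one deterministic cohort of recipient animals.

    Per-animal lung-wide signal targets are drawn from the configured normal
    distributions; pneumothorax/death exclusions and airway pathologies are
    assigned to exactly the configured counts.  The same seed reproduces the
    cohort byte-identically (see :func:`cohort_manifest`).
    """
    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(params.n_recipients)]
    tp = params.timepoint

    n = params.n_recipients
    draws = _draw_targets(rng, params, n)
    excl = np.array(["none"] * n, dtype=object)
    idx = rng.permutation(n)
    for i in idx[:params.n_pneumothorax]:
        excl[i] = "pneumothorax"
    for i in idx[params.n_pneumothorax:params.n_pneumothorax + params.n_death]:
        excl[i] = "death"

    records = []
    for i in range(n):
        a_t, d_t = draws["transplanted"][0][i], draws["transplanted"][1][i]
        a_c, d_c = draws["control"][0][i], draws["control"][1][i]
        sev = severity_from_darkfield(d_t)
        if excl[i] == "pneumothorax":
            patho = PathologySpec(kind="pneumothorax")
        else:
            patho = PathologySpec(kind="none", atelectasis_severity=sev)
        records.append(AnimalRecord(
            animal_id=f"M{i + 1:03d}",
            pathology={tp: patho},
            excluded_reason=str(excl[i]),
            targets={tp: {"transplanted": (float(a_t), float(d_t)), "control": (float(a_c), float(d_c))}},
            severity={tp: sev},
            seed=child_seeds[i],
        ))

    _assign_pathologies(records, params, rng, tp)
    return records


def sample_longitudinal_subgroup(
    params_tp1: CohortParams,
    params_tp2: CohortParams,
    correlation: float = 0.8,
) -> list[AnimalRecord]:
    """Sample the rescanned subgroup with correlated TP1/TP2 targets.

    Each signal is drawn from a bivariate normal whose marginals are the two
    time points' calibrations and whose between-timepoint correlation is
    ``correlation``; both cohort means and SDs are therefore preserved.
    Improvement at TP2 (``n_improved_tp2`` animals, ``n_resolved_tp2`` of
    them with resolving bronchial pathology) is assigned from the largest
    dark-field gains.
    """
    if params_tp1.n_recipients != params_tp2.n_recipients:
        raise ValueError("both time points must describe the same subgroup size")
    ss = np.random.SeedSequence(params_tp1.seed)
    rng = np.random.default_rng(ss)
    n = params_tp1.n_recipients
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]

    def bivariate(p1, p2):
        z = rng.standard_normal(n)
        w = rng.standard_normal(n)
        x1 = p1[0] + p1[1] * z
        x2 = p2[0] + p2[1] * (correlation * z + np.sqrt(1 - correlation**2) * w)
        return np.clip(x1, 0.02, None), np.clip(x2, 0.02, None)

    at1, at2 = bivariate(params_tp1.transplanted_absorption, params_tp2.transplanted_absorption)
    dt1, dt2 = bivariate(params_tp1.transplanted_darkfield, params_tp2.transplanted_darkfield)
    ac1, ac2 = bivariate(params_tp1.control_absorption, params_tp2.control_absorption)
    dc1, dc2 = bivariate(params_tp1.control_darkfield, params_tp2.control_darkfield)

    records = []
    for i in range(n):
        sev1 = severity_from_darkfield(dt1[i])
        sev2 = severity_from_darkfield(dt2[i])
        records.append(AnimalRecord(
            animal_id=f"M{i + 1:03d}",
            pathology={"TP1": PathologySpec(kind="none", atelectasis_severity=sev1)},
            targets={
                "TP1": {"transplanted": (float(at1[i]), float(dt1[i])), "control": (float(ac1[i]), float(dc1[i]))},
                "TP2": {"transplanted": (float(at2[i]), float(dt2[i])), "control": (float(ac2[i]), float(dc2[i]))},
            },
            severity={"TP1": sev1, "TP2": sev2},
            seed=child_seeds[i],
        ))
    _assign_pathologies(records, params_tp1, rng, "TP1")

    # TP2 evolution: improvers are the largest dark-field gains, preferring
    # animals that carried a visible airway pathology (their recovery is the
    # observable event); resolved pathologies reopen the distal lumen.
    gain = dt2 - dt1
    with_patho = [r for r in records if r.pathology["TP1"].kind in ("stenosis", "truncation")]
    without = [r for r in records if r.pathology["TP1"].kind not in ("stenosis", "truncation")]
    with_patho.sort(key=lambda r: -gain[int(r.animal_id[1:]) - 1])
    without.sort(key=lambda r: -gain[int(r.animal_id[1:]) - 1])
    n_res = min(params_tp2.n_resolved_tp2, len(with_patho))
    improved = with_patho[:n_res] + without[:max(0, params_tp2.n_improved_tp2 - n_res)]
    resolved = set(r.animal_id for r in with_patho[:n_res])

    for r in records:
        tp1_patho = r.pathology["TP1"]
        if r.animal_id in resolved:
            if tp1_patho.kind == "truncation":
                # distal lumen visible again, mild residual narrowing
                tp2_patho = PathologySpec(kind="stenosis", stenosis_fraction=0.85,
                                          atelectasis_severity=r.severity["TP2"],
                                          distal_diameter_mm=1.1)
            else:
                tp2_patho = PathologySpec(kind="none", atelectasis_severity=r.severity["TP2"],
                                          distal_diameter_mm=1.1)
        elif tp1_patho.kind == "stenosis":
            tp2_patho = replace(tp1_patho, atelectasis_severity=r.severity["TP2"])
        elif tp1_patho.kind == "truncation":
            tp2_patho = PathologySpec(kind="truncation", atelectasis_severity=1.0)
        else:
            tp2_patho = PathologySpec(kind="none", atelectasis_severity=r.severity["TP2"])
        r.pathology["TP2"] = tp2_patho
    return records


def cohort_manifest(records: list[AnimalRecord]) -> str:
    """Deterministic JSON manifest of a sampled cohort (reproducibility key)."""
    payload = []
    for r in records:
        payload.append({
            "animal_id": r.animal_id,
            "excluded_reason": r.excluded_reason,
            "decreased_ventilation": r.decreased_ventilation,
            "seed": r.seed,
            "pathology": {
                tp: {
                    "kind": p.kind,
                    "stenosis_fraction": p.stenosis_fraction,
                    "atelectasis_severity": p.atelectasis_severity,
                    "distal_diameter_mm": p.distal_diameter_mm,
                } for tp, p in r.pathology.items()
            },
            "targets": r.targets,
            "severity": r.severity,
        })
    return json.dumps(payload, sort_keys=True, indent=1)
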