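"""Synthetic confocal phantoms with ground truth.

Eight breast phenotypes are emulated on a 750 x 750 um^2 field (1000 x
1000 px at 0.75 um/px): adipose tissue (nuclei scattered on adipocyte
boundaries), fibrous tissue (sparse uniform nuclei), lobules (acinar
clusters plus sparse stroma), IDC (dense, regularly packed sheets), ILC
(single-file strands), and three duct phenotypes rendered as a bright
ductal wall with enclosed lumens: a thin-walled normal duct and a
thick-walled hyperplastic duct with one lumen each, and DCIS as an
expanded duct whose wall is perforated by several lumens (cribriform
pattern).

Nuclei are rendered as flat-top bright disks with a soft 1 px edge over a
noisy background modulated by a smooth illumination field; each site
records its truth nucleus mask and centers, and duct sites additionally a
truth wall/lumen geometry, the ROI polygon and the binarization threshold
a user would have chosen.

The malignant phenotypes are dense or single-file, so their inter-nuclear
distances are tight and regular (dispersion well below the published
6.83 um StdIND cutoff), while benign phenotypes are sparse or clustered
with dispersed spacing (well above it); DCIS carries benign-like sparse
surroundings but >= 2 lumens.  This is the "easy" preset under which the
two-rule decision model is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .calibration import CalibratedImage, PixelCalibration
from .ductseg import DuctGeometry
from .io import DIAGNOSES, PolygonROI, SiteRecord, class_label_for

__all__ = [
    "PhantomSpec",
    "SyntheticSite",
    "TABLE1_COMPOSITION",
    "spec_for",
    "sample_spec",
    "render_nuclei",
    "generate_site",
    "generate_cohort",
]

#: cohort composition of the reference study (sites per diagnosis)
TABLE1_COMPOSITION: dict[str, int] = {
    "adipose": 42,
    "fibrous": 31,
    "lobules": 82,
    "normal_duct": 20,
    "hyperplastic_duct": 4,
    "dcis": 26,
    "idc": 37,
    "ilc": 17,
}

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic site.

    Geometric quantities are in um; intensities on the 8-bit scale.  The
    per-phenotype defaults produced by :func:`spec_for` are the study
    conditions; ``seed`` drives every random choice.
    """

    phenotype: str
    seed: int = 0
    image_size: tuple[int, int] = (1000, 1000)
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    background: float = 30.0
    noise_sd: float = 6.0
    illumination_amplitude: float = 0.10
    nucleus_peak: float = 185.0
    # diameter cap below min separation minus the soft render edge, so
    # neighboring nuclei never fuse into one segmented region
    nucleus_diameter_um: tuple[float, float] = (7.0, 10.0)
    min_separation_um: float = 12.0
    # scattered-nuclei phenotypes
    nuclear_density_mm2: float = 250.0
    cluster_count: int = 0
    cluster_radius_um: tuple[float, float] = (18.0, 26.0)
    cluster_spacing_um: float = 12.0
    strand_count: int = 0
    strand_length: int = 30
    strand_spacing_um: float = 12.0
    strand_spacing_jitter_um: float = 0.4
    adipocyte_radius_um: tuple[float, float] = (35.0, 65.0)
    adipocyte_count: int = 12
    nuclei_per_adipocyte: tuple[int, int] = (5, 9)
    # duct phenotypes
    duct_outer_radius_um: float = 0.0
    wall_thickness_um: float = 0.0
    n_lumens: int = 0
    lumen_radius_um: tuple[float, float] = (10.0, 18.0)
    wall_intensity: float = 130.0
    duct_threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phenotype not in DIAGNOSES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.n_lumens < 0:
            raise ValueError("n_lumens must be >= 0")
        if self.duct_outer_radius_um and self.n_lumens:
            if max(self.lumen_radius_um) >= self.duct_outer_radius_um:
                raise ValueError("lumen radius must be smaller than duct radius")

    @property
    def is_duct(self) -> bool:
        return self.duct_outer_radius_um > 0


@dataclass
class SyntheticSite:
    """A rendered phantom with its ground truth."""

    image: CalibratedImage
    truth_mask: np.ndarray           # labeled truth nuclei
    truth_centers_px: np.ndarray     # (n, 2) row/col
    diagnosis: str
    spec: PhantomSpec
    truth_n_lumens: int = 0
    truth_geometry: Optional[DuctGeometry] = None
    roi: Optional[PolygonROI] = None
    overlap_warning: bool = False

    @property
    def class_label(self) -> str:
        return class_label_for(self.diagnosis)

    @property
    def site_id(self) -> str:
        return self.image.site_id

    def site_record(self, patient_id: str = "p0") -> SiteRecord:
        return SiteRecord(
            site_id=self.site_id,
            patient_id=patient_id,
            diagnosis=self.diagnosis,
            duct_threshold=self.spec.duct_threshold if self.spec.is_duct else None,
        )


def sample_spec(
    phenotype: str, seed: int, param_rng: np.random.Generator, **overrides
) -> PhantomSpec:
    """Spec with per-site biological variation drawn from ``param_rng``.

    Site-to-site ranges make nuclear density and area fraction overlap
    between the denser benign phenotypes (lobules) and the sparser
    malignant ones (ILC), as they do in tissue; inter-nuclear spacing
    regularity remains the discriminating signal.
    """
    draws: dict = {}
    if phenotype == "adipose":
        draws = dict(
            adipocyte_count=int(param_rng.integers(8, 17)),
            nuclear_density_mm2=float(param_rng.uniform(50, 150)),
        )
    elif phenotype == "fibrous":
        draws = dict(nuclear_density_mm2=float(param_rng.uniform(150, 400)))
    elif phenotype == "lobules":
        draws = dict(
            cluster_count=int(param_rng.integers(10, 31)),
            nuclear_density_mm2=float(param_rng.uniform(100, 250)),
        )
    elif phenotype == "idc":
        draws = dict(nuclear_density_mm2=float(param_rng.uniform(1800, 3000)))
    elif phenotype == "ilc":
        draws = dict(strand_count=int(param_rng.integers(8, 21)))
    elif phenotype in ("normal_duct", "hyperplastic_duct", "dcis"):
        lo, hi = {
            "normal_duct": ((50, 70), (15, 25)),
            "hyperplastic_duct": ((75, 95), (38, 50)),
            "dcis": ((100, 130), (95, 99)),
        }[phenotype]
        draws = dict(
            duct_outer_radius_um=float(param_rng.uniform(*lo)),
            wall_thickness_um=float(param_rng.uniform(*hi)),
            nuclear_density_mm2=float(param_rng.uniform(150, 350)),
            duct_threshold=int(np.clip(round(param_rng.normal(107, 8)), 90, 125)),
        )
        if phenotype == "dcis":
            draws["n_lumens"] = int(param_rng.integers(2, 7))
    draws.update(overrides)
    return spec_for(phenotype, seed=seed, **draws)


def spec_for(phenotype: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Default (study-condition) spec of a phenotype, with overrides."""
    base: dict = {}
    if phenotype == "adipose":
        base = dict(nuclear_density_mm2=0.0)
    elif phenotype == "fibrous":
        base = dict(nuclear_density_mm2=250.0)
    elif phenotype == "lobules":
        base = dict(nuclear_density_mm2=100.0, cluster_count=8)
    elif phenotype == "idc":
        base = dict(nuclear_density_mm2=2500.0)
    elif phenotype == "ilc":
        # single-file cells are small and evenly spaced; keeping the strand
        # step above the diameter range prevents neighbor fusion
        base = dict(
            nuclear_density_mm2=0.0,
            strand_count=14,
            nucleus_diameter_um=(6.5, 9.0),
        )
    elif phenotype == "normal_duct":
        base = dict(
            nuclear_density_mm2=250.0,
            duct_outer_radius_um=60.0,
            wall_thickness_um=20.0,
            n_lumens=1,
            duct_threshold=107,
        )
    elif phenotype == "hyperplastic_duct":
        base = dict(
            nuclear_density_mm2=250.0,
            duct_outer_radius_um=85.0,
            wall_thickness_um=45.0,
            n_lumens=1,
            duct_threshold=107,
        )
    elif phenotype == "dcis":
        base = dict(
            nuclear_density_mm2=250.0,
            duct_outer_radius_um=115.0,
            wall_thickness_um=97.0,  # mostly filled; lumens perforate it
            n_lumens=4,
            duct_threshold=107,
        )
    base.update(overrides)
    return PhantomSpec(phenotype=phenotype, seed=seed, **base)


# ---------------------------------------------------------------------------
# point processes (coordinates in um within the field)
# ---------------------------------------------------------------------------

def _hardcore_points(
    rng: np.random.Generator,
    n_target: int,
    field_um: tuple[float, float],
    min_sep: float,
    existing: Optional[np.ndarray] = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Sequential-rejection (hard-core) uniform points with min separation."""
    pts: list[np.ndarray] = [] if existing is None else [p for p in existing]
    accepted: list[np.ndarray] = []
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    cell = max(min_sep, 1e-6)

    def key(p):
        return (int(p[0] // cell), int(p[1] // cell))

    def ok(p):
        kr, kc = key(p)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for q in grid.get((kr + dr, kc + dc), ()):
                    if np.hypot(*(p - q)) < min_sep:
                        return False
        return True

    for p in pts:
        grid.setdefault(key(p), []).append(p)
    lo = np.array([1.0, 1.0])
    hi = np.array([field_um[0] - 1.0, field_um[1] - 1.0])
    tries = 0
    while len(accepted) < n_target and tries < max_tries * max(n_target, 1):
        p = rng.uniform(lo, hi)
        tries += 1
        if ok(p):
            grid.setdefault(key(p), []).append(p)
            accepted.append(p)
    return np.asarray(accepted) if accepted else np.empty((0, 2))


def _ring_points(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    spacing: float,
    radial_jitter: float = 1.5,
    gap_scale: float = 0.6,
    max_n: Optional[int] = None,
) -> np.ndarray:
    """Points around a circle with irregular arc gaps (>= ``spacing``).

    Gaps are ``spacing`` plus an exponential excess, emulating the uneven
    cell placement of real acinar/adipocyte boundaries; the worst-case
    inward radial jitter is accounted for so neighbors never come closer
    than ``spacing``.
    """
    r_eff = max(radius - 2 * radial_jitter, 1.0)
    start = rng.uniform(0, 2 * math.pi)
    angles = []
    total = 0.0
    while True:
        angles.append(start + total)
        step = (spacing + rng.exponential(gap_scale * spacing)) / r_eff
        total += step
        if total > 2 * math.pi - spacing / r_eff:
            break
        if max_n is not None and len(angles) >= max_n:
            break
    angles = np.asarray(angles)
    rr = radius + rng.normal(0, radial_jitter, len(angles))
    return np.column_stack(
        (center[0] + rr * np.sin(angles), center[1] + rr * np.cos(angles))
    )


def _strand_points(
    rng: np.random.Generator,
    field_um: tuple[float, float],
    length: int,
    spacing: float,
    jitter: float,
) -> np.ndarray:
    """Single-file nuclei along a smoothly turning path."""
    p = rng.uniform((0.1 * field_um[0], 0.1 * field_um[1]),
                    (0.9 * field_um[0], 0.9 * field_um[1]))
    theta = rng.uniform(0, 2 * math.pi)
    pts = [p.copy()]
    for _ in range(length - 1):
        theta += rng.normal(0, 0.25)
        step = spacing + rng.normal(0, jitter)
        for _attempt in range(4):  # turn away from the field edge
            q = p + step * np.array([math.sin(theta), math.cos(theta)])
            if 1 <= q[0] < field_um[0] - 1 and 1 <= q[1] < field_um[1] - 1:
                break
            theta += math.pi / 2
        else:
            break  # cornered: end the strand, spacing is never violated
        p = q
        pts.append(p.copy())
    return np.asarray(pts)


def _scatter_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Truth nucleus centers (um) for one phenotype."""
    H, W = spec.image_size
    pitch = spec.calibration.pitch_um
    field = (H * pitch, W * pitch)
    area_mm2 = field[0] * field[1] / 1e6
    sep = spec.min_separation_um
    pts: list[np.ndarray] = []

    if spec.phenotype == "adipose":
        centers = _hardcore_points(
            rng, spec.adipocyte_count, field, 2 * min(spec.adipocyte_radius_um)
        )
        for c in centers:
            r = rng.uniform(*spec.adipocyte_radius_um)
            k = int(rng.integers(*spec.nuclei_per_adipocyte))
            pts.append(_ring_points(rng, c, r, spacing=18.0, max_n=k))
    elif spec.phenotype == "lobules":
        centers = _hardcore_points(
            rng, spec.cluster_count, field, 3 * max(spec.cluster_radius_um)
        )
        for c in centers:
            r = rng.uniform(*spec.cluster_radius_um)
            pts.append(_ring_points(rng, c, r, spacing=spec.cluster_spacing_um))
    elif spec.phenotype == "ilc":
        # strands stay single-file: a strand ends where it would run into
        # an already-placed strand (no crossings, no nucleus fusion)
        accepted: list[np.ndarray] = []
        for _ in range(spec.strand_count):
            cand = _strand_points(
                rng, field, spec.strand_length,
                spec.strand_spacing_um, spec.strand_spacing_jitter_um,
            )
            kept: list[np.ndarray] = []
            for j, p in enumerate(cand):
                others = accepted + kept[: max(len(kept) - 1, 0)]
                if others and min(
                    float(np.hypot(*(p - q))) for q in others
                ) < 11.0:
                    break
                kept.append(p)
            accepted.extend(kept)
            if kept:
                pts.append(np.asarray(kept))

    existing = np.concatenate(pts) if pts else None
    n_scatter = int(round(spec.nuclear_density_mm2 * area_mm2))
    if n_scatter > 0:
        scattered = _hardcore_points(rng, n_scatter, field, sep, existing=existing)
        pts.append(scattered)
    if not pts:
        return np.empty((0, 2))
    out = np.concatenate([p for p in pts if p.size])
    inb = (out[:, 0] >= 1) & (out[:, 0] < field[0] - 1) \
        & (out[:, 1] >= 1) & (out[:, 1] < field[1] - 1)
    return out[inb]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_nuclei(
    centers_px: np.ndarray,
    diameters_px: np.ndarray,
    shape: tuple[int, int],
    peak: float,
    rng: np.random.Generator,
    max_overlap_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Render flat-top nucleus disks; returns (canvas, truth labels, warn).

    Each nucleus is a disk of its truth radius at ``peak`` intensity (with
    ~8% per-nucleus brightness jitter) falling to zero over a ~1 px soft
    edge; overlapping contributions combine by maximum.  ``warn`` is set
    when more than ``max_overlap_fraction`` of truth pixels are claimed by
    two or more nuclei.
    """
    H, W = shape
    canvas = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    claimed = np.zeros(shape, dtype=bool)
    overlap_px = 0
    total_px = 0
    for k, (c, d) in enumerate(zip(centers_px, diameters_px), start=1):
        r0 = d / 2.0
        amp = peak * rng.uniform(0.92, 1.05)
        r_lo = max(int(math.floor(c[0] - r0 - 2)), 0)
        r_hi = min(int(math.ceil(c[0] + r0 + 2)) + 1, H)
        c_lo = max(int(math.floor(c[1] - r0 - 2)), 0)
        c_hi = min(int(math.ceil(c[1] + r0 + 2)) + 1, W)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dist = np.hypot(rr - c[0], cc - c[1])
        profile = np.clip((r0 + 1.0 - dist) / 2.0, 0.0, 1.0)
        canvas[r_lo:r_hi, c_lo:c_hi] = np.maximum(
            canvas[r_lo:r_hi, c_lo:c_hi], amp * profile
        )
        disk = dist <= r0
        overlap_px += int((disk & claimed[r_lo:r_hi, c_lo:c_hi]).sum())
        total_px += int(disk.sum())
        claimed[r_lo:r_hi, c_lo:c_hi] |= disk
        labels[r_lo:r_hi, c_lo:c_hi][disk] = k
    warn = total_px > 0 and overlap_px / total_px > max_overlap_fraction
    return canvas, labels, warn


def _illumination_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative illumination/staining variation around 1."""
    coarse = rng.normal(0.0, 1.0, (8, 8))
    f = ndimage.zoom(coarse, (shape[0] / 8, shape[1] / 8), order=3)
    f = f[: shape[0], : shape[1]]
    sd = f.std() or 1.0
    return 1.0 + amplitude * f / sd


def _duct_truth(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, PolygonROI]:
    """Truth wall mask, lumen labels, duct center/radius and ROI polygon."""
    H, W = spec.image_size
    pitch = spec.calibration.pitch_um
    r_out = spec.duct_outer_radius_um / pitch
    wall_t = spec.wall_thickness_um / pitch
    margin = r_out + 30.0 / pitch
    cr = rng.uniform(margin, H - margin)
    cc = rng.uniform(margin, W - margin)
    rr, ccg = np.mgrid[:H, :W]
    dist = np.hypot(rr - cr, ccg - cc)
    outer = dist <= r_out
    inner_r = r_out - wall_t
    wall = outer & (dist > inner_r) if inner_r > 0 else outer.copy()

    lumen_labels = np.zeros((H, W), dtype=np.int32)
    if spec.n_lumens == 0:
        wall = outer.copy()  # solid: no cavity at all
    elif inner_r > 0 and spec.n_lumens == 1 and spec.phenotype != "dcis":
        # the central cavity is the single lumen
        lumen_labels[dist <= inner_r] = 1
    elif spec.n_lumens > 0:
        # cribriform: carve n_lumens holes out of a (mostly) filled duct
        wall = outer.copy()
        placed = 0
        holes = []
        guard = 0
        edge_margin = 12.0 / pitch
        while placed < spec.n_lumens and guard < 3000:
            guard += 1
            lr = rng.uniform(*spec.lumen_radius_um) / pitch
            max_off = r_out - edge_margin - lr
            if max_off <= 0:
                continue
            ang = rng.uniform(0, 2 * math.pi)
            off = math.sqrt(rng.uniform(0, 1)) * max_off
            hr = cr + off * math.sin(ang)
            hc = cc + off * math.cos(ang)
            if any(
                np.hypot(hr - h[0], hc - h[1]) < lr + h[2] + 6.0 / pitch
                for h in holes
            ):
                continue
            holes.append((hr, hc, lr))
            placed += 1
        if placed < spec.n_lumens:
            raise ValueError("could not place the requested number of lumens")
        for k, (hr, hc, lr) in enumerate(holes, start=1):
            hole = np.hypot(rr - hr, ccg - hc) <= lr
            wall &= ~hole
            lumen_labels[hole] = k

    # octagonal ROI around the duct with a margin
    m = r_out + 15.0 / pitch
    angs = np.arange(8) * math.pi / 4
    verts = tuple(
        (float(cc + m * 1.08 * math.cos(a)), float(cr + m * 1.08 * math.sin(a)))
        for a in angs
    )
    return wall, lumen_labels, np.array([cr, cc, r_out]), PolygonROI(verts)


def generate_site(spec: PhantomSpec) -> SyntheticSite:
    """Render one synthetic site with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    pitch = spec.calibration.pitch_um

    wall = lumens = None
    roi = None
    duct_info = None
    if spec.is_duct:
        wall, lumens, duct_info, roi = _duct_truth(spec, rng)

    centers_um = _scatter_centers(spec, rng)
    centers_px = centers_um / pitch
    # keep scattered nuclei off the duct (wall and lumens)
    if spec.is_duct and centers_px.size:
        cr, cc, r_out = duct_info
        d = np.hypot(centers_px[:, 0] - cr, centers_px[:, 1] - cc)
        centers_px = centers_px[d > r_out + 8.0 / pitch]

    diameters_px = rng.uniform(*spec.nucleus_diameter_um, len(centers_px)) / pitch
    canvas, labels, warn = render_nuclei(
        centers_px, diameters_px, (H, W), spec.nucleus_peak, rng
    )

    if spec.is_duct:
        soft = ndimage.gaussian_filter(wall.astype(float), 2.0)
        canvas = np.maximum(canvas, spec.wall_intensity * np.clip(soft * 1.4, 0, 1))

    base = spec.background * _illumination_field((H, W), spec.illumination_amplitude, rng)
    img = base + canvas + rng.normal(0.0, spec.noise_sd, (H, W))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    geometry = None
    n_lumens = 0
    if spec.is_duct:
        filled = wall | (lumens > 0)
        geometry = DuctGeometry(
            wall_mask=wall, filled_mask=filled, lumen_labels=lumens
        )
        n_lumens = int(lumens.max())

    return SyntheticSite(
        image=CalibratedImage(
            img, spec.calibration, site_id=f"{spec.phenotype}_{spec.seed}"
        ),
        truth_mask=labels,
        truth_centers_px=centers_px,
        diagnosis=spec.phenotype,
        spec=spec,
        truth_n_lumens=n_lumens,
        truth_geometry=geometry,
        roi=roi,
        overlap_warning=warn,
    )


def generate_cohort(
    composition: dict[str, int] | None = None,
    seed: int = 0,
    **spec_overrides,
) -> list[SyntheticSite]:
    """Generate a cohort of synthetic sites (default: the 259-site
    reference composition).  Per-site seeds are the master seed plus the
    site index; DCIS sites draw 2-6 lumens from their site seed."""
    composition = dict(composition or TABLE1_COMPOSITION)
    sites = []
    idx = 0
    for phenotype in DIAGNOSES:
        for _ in range(composition.get(phenotype, 0)):
            param_rng = np.random.default_rng((seed, idx))
            spec = sample_spec(
                phenotype, seed=seed + idx, param_rng=param_rng, **spec_overrides
            )
            site = generate_site(spec)
            site.image.site_id = f"site{idx:03d}_{phenotype}"
            sites.append(site)
            idx += 1
    return sites
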